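#!/usr/bin/env python
"""Rank predicted drugs and combinations against the evidence tables.

Aggregates in-vitro potency (median IC50 across cell lines, µM),
viability, CSF bioavailability (LogBB), xenograft growth reduction
and two-arm clinical outcomes into effective/ineffective/untested
tier calls, drops cofactor/proliferation-flagged drugs with an audit
trail, and emits the lexicographic ranking (effective tiers, DDI
severity, potency, LogBB).
"""

import logging
from pathlib import Path

import pandas as pd

from gliomagem.drugs import read_drug_catalog
from gliomagem.ranking import compute_potency, rank_candidates, read_evidence

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"


def main() -> None:
    # context models legitimately drop exchanges for unused medium
    # nutrients; silence the per-model orphan warnings here
    logging.getLogger("gliomagem.network").setLevel(logging.ERROR)
    catalog = read_drug_catalog(STUDY / "inputs" / "drug_catalog.tsv")
    evidence = read_evidence(STUDY / "inputs" / "evidence")

    singles = {}
    for path in sorted(STUDY.glob("drugs_single_S*.tsv")):
        singles[path.stem] = pd.read_csv(path, sep="\t", index_col=0)
    hit_singles = sorted({d for df in singles.values() for d in df.index[df["hit"]]})
    combos = pd.read_csv(STUDY / "drug_combinations.tsv", sep="\t")
    hit_pairs = combos[combos["hit"]][["drug_a", "drug_b"]].drop_duplicates()
    combo_members = {f"{r.drug_a}+{r.drug_b}": (r.drug_a, r.drug_b)
                     for r in hit_pairs.itertuples()}

    potency = compute_potency(evidence)
    antibc = [d.id for d in catalog.of_category("AntiBC")]
    ref = float(potency[potency.index.isin(antibc)].median())
    print(f"reference AntiBC median potency: {ref:g} µM")

    ranking, audit = rank_candidates(
        hit_singles + sorted(combo_members), evidence,
        reference_potency=ref, combo_members=combo_members,
    )
    ranking.to_csv(STUDY / "drug_ranking.tsv", sep="\t", index=False)
    pd.DataFrame.from_records(audit).to_csv(
        STUDY / "ranking_audit.tsv", sep="\t", index=False)

    print("final ranking (tiers = in vitro / xenograft / clinical):")
    for _, row in ranking.iterrows():
        rank = "unranked" if pd.isna(row["rank"]) else f"#{int(row['rank'])}"
        print(f"  {rank:>9} {row['candidate']:>24} "
              f"[{row['in_vitro']}/{row['xenograft']}/{row['clinical']}] "
              f"DDI={row['ddi_severity']} potency={row['potency_um']} "
              f"LogBB={row['logbb']}")
    for entry in audit:
        print(f"  audit: {entry['drug']} {entry['action']} ({entry['reasons']})")


if __name__ == "__main__":
    main()
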