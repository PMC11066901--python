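"""Evidence aggregation and drug prioritization.

Predicted drugs and combinations are confronted with curated evidence
tables — in-vitro potency (IC50 across brain-cancer cell lines) and
viability reduction, CSF bioavailability (LogBB, the log10
CSF-to-plasma concentration ratio), xenograft growth reduction,
two-arm clinical-trial outcomes and drug–drug interaction (DDI)
severity — and classified per tier into effective / ineffective /
untested.  Candidates are then ranked lexicographically: more
effective tiers first, then milder DDI, then stronger potency (lower
median IC50), then better CSF bioavailability (higher LogBB), ties
broken by id.  All thresholds live in a replaceable rules config; the
defaults are explicit stand-ins chosen to be auditable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EvidenceTable",
    "RulesConfig",
    "compute_potency",
    "apply_exclusions",
    "classify_tiers",
    "rank_candidates",
    "read_evidence",
    "write_evidence",
]

TIERS = ("in_vitro", "xenograft", "clinical")
DDI_ORDER = {"none": 0, "minor": 1, "major": 2, "unknown": 1}
ABC_RELATIONS = {"substrate", "inhibitor", "inducer", "none", "unknown"}
_PHASE_RANK = {"I": 1.0, "I/II": 1.5, "II": 2.0, "II/III": 2.5, "III": 3.0, "IV": 4.0}


@dataclass
class RulesConfig:
    """Effectiveness thresholds (all boundaries inclusive)."""

    viability_min_pct: float = 50.0  # in-vitro effective if median reduction >= this
    xenograft_min_pct: float = 25.0  # xenograft effective if median growth reduction >= this
    clinical_min_phase: float = 1.5  # two-arm phase >= I/II with improved primary outcome
    prefer_logbb_over_bbb: bool = True

    @classmethod
    def from_file(cls, path) -> "RulesConfig":
        """Plain ``key = value`` file; unknown keys rejected."""
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown rules key {key!r}")
            typ = cls.__dataclass_fields__[key].type
            kwargs[key] = value.strip() in {"1", "true", "True"} if typ == "bool" else float(value)
        return cls(**kwargs)


@dataclass
class EvidenceTable:
    """Curated per-drug evidence records (long format frames).

    ic50: drug, cell_line, ic50_um (µM, > 0)
    viability: drug, reduction_pct ([−100, 100]; negative = proliferation)
    pk: drug, logbb, bbb_permeable, abc_transporter
    xenograft: drug, growth_reduction_pct
    clinical: drug, phase, arms, outcome ∈ {improved, no_change, worse}
    ddi: drug_a, drug_b, severity ∈ {none, minor, major, unknown}
    exclusions: drug, cofactor_of_target, induces_proliferation
    """

    ic50: pd.DataFrame
    viability: pd.DataFrame
    pk: pd.DataFrame
    xenograft: pd.DataFrame
    clinical: pd.DataFrame
    ddi: pd.DataFrame
    exclusions: pd.DataFrame

    def __post_init__(self):
        bad = self.ic50[self.ic50["ic50_um"] <= 0]
        if len(bad):
            logger.warning("rejected %d non-positive IC50 records: %s",
                           len(bad), sorted(bad["drug"].unique()))
            self.ic50 = self.ic50[self.ic50["ic50_um"] > 0].reset_index(drop=True)
        for frame, col in ((self.viability, "reduction_pct"),
                           (self.xenograft, "growth_reduction_pct")):
            if len(frame) and not frame[col].between(-100, 100).all():
                raise ValueError(f"{col} outside [-100, 100]")
        if len(self.pk):
            bad_abc = set(self.pk["abc_transporter"]) - ABC_RELATIONS
            if bad_abc:
                raise ValueError(f"unknown ABC-transporter relations: {sorted(bad_abc)}")

    def ddi_severity(self, drug_a: str, drug_b: str) -> str:
        key = tuple(sorted((drug_a, drug_b)))
        for _, row in self.ddi.iterrows():
            if tuple(sorted((row["drug_a"], row["drug_b"]))) == key:
                return str(row["severity"])
        return "unknown"

    def logbb(self, drug: str) -> float:
        rows = self.pk[self.pk["drug"] == drug]
        vals = rows["logbb"].dropna()
        return float(vals.median()) if len(vals) else math.nan


def compute_potency(evidence: EvidenceTable) -> pd.Series:
    """Median IC50 (µM) across cell lines per drug.

    Duplicate (drug, cell line) records are averaged before the median
    so over-sampled cell lines do not dominate.  Drugs without any
    positive IC50 record are absent from the result (potency missing).
    """
    if not len(evidence.ic50):
        return pd.Series(dtype=float, name="potency_um")
    per_line = evidence.ic50.groupby(["drug", "cell_line"])["ic50_um"].mean()
    potency = per_line.groupby("drug").median()
    potency.name = "potency_um"
    return potency


def apply_exclusions(
    predicted: Iterable[str], evidence: EvidenceTable
) -> Tuple[List[str], List[Dict[str, str]]]:
    """Drop drugs flagged as proliferation-inducing in vitro or as
    cofactors of their own targets; every drop is logged with all its
    reasons (a drug with both flags is dropped once, two reasons)."""
    flags = evidence.exclusions.set_index("drug") if len(evidence.exclusions) else None
    retained, log = [], []
    for drug in sorted(set(predicted)):
        reasons = []
        if flags is not None and drug in flags.index:
            row = flags.loc[drug]
            if bool(row.get("cofactor_of_target", False)):
                reasons.append("cofactor_of_target")
            if bool(row.get("induces_proliferation", False)):
                reasons.append("induces_proliferation")
        if reasons:
            log.append({"drug": drug, "action": "excluded", "reasons": ";".join(reasons)})
        else:
            retained.append(drug)
    return retained, log


def _majority_call(calls: List[str], audit: List[Dict], drug: str, tier: str) -> str:
    eff = calls.count("effective")
    ineff = calls.count("ineffective")
    if eff > ineff:
        return "effective"
    if ineff > eff:
        return "ineffective"
    audit.append({"drug": drug, "action": "tie", "reasons": f"{tier}: {eff}v{ineff} -> ineffective"})
    return "ineffective"


def classify_tiers(
    drug: str,
    evidence: EvidenceTable,
    rules: Optional[RulesConfig] = None,
    potency: Optional[pd.Series] = None,
    reference_potency: Optional[float] = None,
    audit: Optional[List[Dict]] = None,
) -> Dict[str, str]:
    """Per-tier effective / ineffective / untested calls for one drug.

    in_vitro: effective iff the median viability reduction meets the
    threshold, or the drug's potency is at least as good (median IC50
    at most) as the reference AntiBC median; untested when neither
    IC50 nor viability records exist.  xenograft: median growth
    reduction against the 25% threshold.  clinical: any two-arm record
    of phase ≥ I/II with an improved primary survival outcome;
    contradictory records resolve by majority, ties conservatively to
    ineffective (logged).
    """
    rules = rules or RulesConfig()
    audit = audit if audit is not None else []
    if potency is None:
        potency = compute_potency(evidence)
    calls: Dict[str, str] = {}

    # in vitro
    via = evidence.viability[evidence.viability["drug"] == drug]["reduction_pct"]
    pot = potency.get(drug, math.nan)
    if via.empty and math.isnan(pot):
        calls["in_vitro"] = "untested"
    else:
        effective = False
        if len(via):
            effective = effective or float(via.median()) >= rules.viability_min_pct
        if not math.isnan(pot) and reference_potency is not None:
            effective = effective or pot <= reference_potency
        calls["in_vitro"] = "effective" if effective else "ineffective"

    # xenograft
    xg = evidence.xenograft[evidence.xenograft["drug"] == drug]["growth_reduction_pct"]
    if xg.empty:
        calls["xenograft"] = "untested"
    else:
        calls["xenograft"] = (
            "effective" if float(xg.median()) >= rules.xenograft_min_pct else "ineffective"
        )

    # clinical
    cl = evidence.clinical[evidence.clinical["drug"] == drug]
    if cl.empty:
        calls["clinical"] = "untested"
    else:
        per_record = []
        for _, row in cl.iterrows():
            phase = _PHASE_RANK.get(str(row["phase"]), 0.0)
            qualified = phase >= rules.clinical_min_phase and int(row["arms"]) >= 2
            improved = str(row["outcome"]) == "improved"
            per_record.append("effective" if (qualified and improved) else "ineffective")
        if "effective" in per_record and "ineffective" in per_record:
            calls["clinical"] = _majority_call(per_record, audit, drug, "clinical")
        else:
            calls["clinical"] = per_record[0]
    return calls


def rank_candidates(
    candidates: Sequence[str],
    evidence: EvidenceTable,
    rules: Optional[RulesConfig] = None,
    reference_potency: Optional[float] = None,
    combo_members: Optional[Mapping[str, Tuple[str, str]]] = None,
) -> Tuple[pd.DataFrame, List[Dict]]:
    """Deterministic total order over retained candidates.

    ``candidates`` are drug ids or combination ids; ``combo_members``
    maps a combination id to its two member drug ids (evidence for a
    combination is pooled over both members; DDI severity applies to
    combinations only).  Sort keys, in order: number of effective
    tiers (desc), DDI severity (none < minor/unknown < major), potency
    (asc, missing last), LogBB (desc, missing last), candidate id.
    Candidates with no tested tier at all are listed last and flagged;
    they carry no rank.  Returns (ranking table, audit log).
    """
    rules = rules or RulesConfig()
    combo_members = combo_members or {}
    audit: List[Dict] = []
    potency = compute_potency(evidence)

    retained, excl_log = apply_exclusions(
        [d for c in candidates for d in combo_members.get(c, (c,))], evidence
    )
    audit.extend(excl_log)
    excluded_drugs = {e["drug"] for e in excl_log}

    rows = []
    for cand in sorted(set(candidates)):
        members = combo_members.get(cand, (cand,))
        dropped = [m for m in members if m in excluded_drugs]
        if dropped:
            audit.append({"drug": cand, "action": "dropped_candidate",
                          "reasons": "excluded member: " + ";".join(dropped)})
            continue
        member_tiers = [
            classify_tiers(m, evidence, rules, potency, reference_potency, audit)
            for m in members
        ]
        tiers = {}
        for tier in TIERS:
            calls = [t[tier] for t in member_tiers]
            if "effective" in calls:
                tiers[tier] = "effective"
            elif "ineffective" in calls:
                tiers[tier] = "ineffective"
            else:
                tiers[tier] = "untested"
        pots = [potency.get(m, math.nan) for m in members]
        pots = [p for p in pots if not math.isnan(p)]
        cand_potency = min(pots) if pots else math.nan
        bbs = [evidence.logbb(m) for m in members]
        bbs = [b for b in bbs if not math.isnan(b)]
        cand_logbb = max(bbs) if bbs else math.nan
        if len(members) == 2:
            ddi = evidence.ddi_severity(*members)
        else:
            ddi = "none"
        n_eff = sum(1 for t in TIERS if tiers[t] == "effective")
        untested_overall = all(tiers[t] == "untested" for t in TIERS)
        rows.append({
            "candidate": cand,
            "is_combination": len(members) == 2,
            "in_vitro": tiers["in_vitro"],
            "xenograft": tiers["xenograft"],
            "clinical": tiers["clinical"],
            "n_effective_tiers": n_eff,
            "ddi_severity": ddi,
            "potency_um": cand_potency,
            "logbb": cand_logbb,
            "untested_overall": untested_overall,
        })

    frame = pd.DataFrame.from_records(rows, columns=[
        "candidate", "is_combination", "in_vitro", "xenograft", "clinical",
        "n_effective_tiers", "ddi_severity", "potency_um", "logbb", "untested_overall",
    ])
    if not len(frame):
        frame["rank"] = pd.Series(dtype=float)
        return frame, audit

    def sort_key(row) -> tuple:
        pot = row["potency_um"]
        bb = row["logbb"]
        return (
            row["untested_overall"],
            -row["n_effective_tiers"],
            DDI_ORDER.get(row["ddi_severity"], 1),
            pot if not math.isnan(pot) else math.inf,
            -bb if not math.isnan(bb) else math.inf,
            row["candidate"],
        )

    order = sorted(frame.index, key=lambda i: sort_key(frame.loc[i]))
    frame = frame.loc[order].reset_index(drop=True)
    ranks = []
    next_rank = 1
    for _, row in frame.iterrows():
        if row["untested_overall"]:
            ranks.append(math.nan)
        else:
            ranks.append(next_rank)
            next_rank += 1
    frame["rank"] = ranks
    return frame, audit


# ---------------------------------------------------------------------------
# I/O

_EVIDENCE_FILES = {
    "ic50": ["drug", "cell_line", "ic50_um"],
    "viability": ["drug", "reduction_pct"],
    "pk": ["drug", "logbb", "bbb_permeable", "abc_transporter"],
    "xenograft": ["drug", "growth_reduction_pct"],
    "clinical": ["drug", "phase", "arms", "outcome"],
    "ddi": ["drug_a", "drug_b", "severity"],
    "exclusions": ["drug", "cofactor_of_target", "induces_proliferation"],
}


def read_evidence(directory) -> EvidenceTable:
    """Read the seven per-tier TSVs (``<name>.tsv``) from a directory;
    missing files load as empty tables."""
    directory = Path(directory)
    frames = {}
    for name, cols in _EVIDENCE_FILES.items():
        path = directory / f"{name}.tsv"
        if path.exists():
            frames[name] = pd.read_csv(path, sep="\t")
        else:
            frames[name] = pd.DataFrame(columns=cols)
    return EvidenceTable(**frames)


def write_evidence(evidence: EvidenceTable, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _EVIDENCE_FILES:
        getattr(evidence, name).to_csv(directory / f"{name}.tsv", sep="\t", index=False)
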