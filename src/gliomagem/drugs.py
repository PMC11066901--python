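"""In-silico drug and drug-combination screening on metabolic models.

A drug is modelled as the joint knockout of its target genes; its
effect is the growth reduction E = 1 − grRatio.  Pairwise combinations
are scored against the Bliss-independence expectation
E_exp = E_A + E_B − E_A·E_B: excess over it (beyond a tolerance δ) is
synergy, deficit is antagonism.  Candidate pairs combine FDA-approved
drugs that are not lethal on their own — a drug already shutting down
biomass alone gives no information in combination — with approved
anti-brain-tumor chemotherapies (AntiBC) and investigational
anti-glioma drugs (IAG).  A healthy-control model guards against
combinations that would also abolish ATP production or biomass
maintenance in normal tissue.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .lp import TAU_FEAS, LinearProblem, fba
from .network import MediumDefinition, MetabolicNetwork, apply_medium

logger = logging.getLogger(__name__)

__all__ = [
    "Drug",
    "DrugCatalog",
    "screen_single_drugs",
    "screen_combinations",
    "classify_bliss",
    "safety_check",
    "subtype_specificity",
    "read_drug_catalog",
    "write_drug_catalog",
    "HIT_CUTOFF_DEFAULT",
    "BLISS_TOL_DEFAULT",
    "SAFETY_ETA_DEFAULT",
]

HIT_CUTOFF_DEFAULT = 0.5
BLISS_TOL_DEFAULT = 0.05
SAFETY_ETA_DEFAULT = 0.05

CATEGORIES = {"FDA", "AntiBC", "IAG"}


@dataclass(frozen=True)
class Drug:
    id: str
    name: str
    targets: FrozenSet[str]
    categories: FrozenSet[str]
    cofactor_of_target: bool = False
    induces_proliferation: bool = False

    def __post_init__(self):
        if not self.targets:
            raise ValueError(f"drug {self.id!r} has an empty target set")
        bad = self.categories - CATEGORIES
        if bad:
            raise ValueError(f"drug {self.id!r} has unknown categories {sorted(bad)}")


@dataclass
class DrugCatalog:
    drugs: Dict[str, Drug]

    def __iter__(self):
        return iter(self.drugs.values())

    def of_category(self, category: str) -> List[Drug]:
        return [d for d in self.drugs.values() if category in d.categories]

    def __len__(self):
        return len(self.drugs)


def _mapped_targets(drug: Drug, model_genes: FrozenSet[str]) -> FrozenSet[str]:
    mapped = drug.targets & model_genes
    orphans = drug.targets - model_genes
    if orphans:
        logger.debug("drug %s: %d targets not in model (%s)", drug.id, len(orphans),
                     ", ".join(sorted(orphans)))
    return mapped


def _knockout_effect(
    network: MetabolicNetwork, problem: LinearProblem, z_wt: float, genes: FrozenSet[str]
) -> float:
    from .essentiality import knockout_growth

    if not genes:
        return 0.0
    z_ko = knockout_growth(network, genes, problem=problem)
    ratio = min(max(z_ko / z_wt, 0.0), 1.0)
    return 1.0 - ratio


def screen_single_drugs(
    model: MetabolicNetwork,
    medium: Optional[MediumDefinition],
    catalog: DrugCatalog,
    cutoff: float = HIT_CUTOFF_DEFAULT,
) -> pd.DataFrame:
    """Effect E = 1 − grRatio of each drug's joint target knockout.

    Drugs with no target mapping to the model's genes get E = 0.  The
    hit flag is inclusive at the cutoff ("at least 50%" growth
    reduction); lethal means growth is abolished within solver
    tolerance.
    """
    network = apply_medium(model, medium) if medium is not None else model
    problem = LinearProblem(network)
    wt = fba(network, problem=problem)
    if not wt.optimal or wt.objective_value <= TAU_FEAS:
        raise ValueError(f"model {model.id!r} does not grow; cannot screen drugs")
    z_wt = wt.objective_value
    model_genes = network.genes

    records = []
    for drug in sorted(catalog, key=lambda d: d.id):
        mapped = _mapped_targets(drug, model_genes)
        effect = _knockout_effect(network, problem, z_wt, mapped)
        records.append(
            {
                "drug": drug.id,
                "model": model.id,
                "n_targets": len(drug.targets),
                "n_mapped_targets": len(mapped),
                "effect": effect,
                "grRatio": 1.0 - effect,
                "hit": effect >= cutoff,
                "lethal": effect >= 1.0 - TAU_FEAS,
            }
        )
    return pd.DataFrame.from_records(records, columns=[
        "drug", "model", "n_targets", "n_mapped_targets", "effect", "grRatio", "hit", "lethal",
    ]).set_index("drug")


def classify_bliss(
    effect_a: float,
    effect_b: float,
    effect_ab: float,
    tol: float = BLISS_TOL_DEFAULT,
    form: str = "excess",
) -> str:
    """Bliss-independence class of a pair given single and joint effects.

    Expected joint effect under independence is
    E_exp = E_A + E_B − E_A·E_B.  In the default ``excess`` form the
    observed joint effect is synergistic above E_exp + δ, antagonistic
    below E_exp − δ, additive within the band.  The ``ratio`` form
    classifies the combination index E_AB / E_exp against 1 ± δ
    instead (with E_exp = 0, any joint effect beyond δ is synergy).
    """
    for name, e in (("effect_a", effect_a), ("effect_b", effect_b), ("effect_ab", effect_ab)):
        if not (0.0 <= e <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {e}")
    expected = effect_a + effect_b - effect_a * effect_b
    if form == "excess":
        if effect_ab > expected + tol:
            return "synergistic"
        if effect_ab < expected - tol:
            return "antagonistic"
        return "additive"
    if form == "ratio":
        if expected <= tol:
            return "synergistic" if effect_ab > tol else "additive"
        index = effect_ab / expected
        if index > 1.0 + tol:
            return "synergistic"
        if index < 1.0 - tol:
            return "antagonistic"
        return "additive"
    raise ValueError(f"unknown Bliss form {form!r}")


def screen_combinations(
    models: Sequence[MetabolicNetwork],
    medium: Optional[MediumDefinition],
    catalog: DrugCatalog,
    cutoff: float = HIT_CUTOFF_DEFAULT,
    tol: float = BLISS_TOL_DEFAULT,
    single_results: Optional[Mapping[str, pd.DataFrame]] = None,
) -> pd.DataFrame:
    """Pairwise screen: (non-lethal FDA drugs) × (AntiBC ∪ IAG drugs).

    A drug lethal as a single agent in any screened model is excluded
    from every pair (complete biomass shutdown leaves nothing for a
    partner to add).  The joint effect E_AB deletes the union of both
    target sets; overlapping target sets are allowed (union semantics)
    and logged.  Pairs are ordered (FDA partner first, then partner id)
    for determinism.  All candidate pairs are returned; downstream
    reporting filters on ``hit`` (E_AB ≥ cutoff).
    """
    if single_results is None:
        single_results = {
            m.id: screen_single_drugs(m, medium, catalog, cutoff) for m in models
        }

    lethal_anywhere = set()
    for res in single_results.values():
        lethal_anywhere |= set(res.index[res["lethal"]])

    fda = [d for d in sorted(catalog.of_category("FDA"), key=lambda d: d.id)
           if d.id not in lethal_anywhere]
    partners = sorted(
        {d.id: d for d in catalog.of_category("AntiBC") + catalog.of_category("IAG")}.values(),
        key=lambda d: d.id,
    )

    records = []
    for model in models:
        network = apply_medium(model, medium) if medium is not None else model
        problem = LinearProblem(network)
        z_wt = fba(network, problem=problem).objective_value
        model_genes = network.genes
        singles = single_results[model.id]
        for drug_a, drug_b in itertools.product(fda, partners):
            if drug_a.id == drug_b.id:
                continue
            overlap = drug_a.targets & drug_b.targets
            if overlap:
                logger.debug("pair %s+%s target overlap: %s", drug_a.id, drug_b.id,
                             sorted(overlap))
            e_a = float(singles.loc[drug_a.id, "effect"])
            e_b = float(singles.loc[drug_b.id, "effect"])
            union = _mapped_targets(drug_a, model_genes) | _mapped_targets(drug_b, model_genes)
            e_ab = _knockout_effect(network, problem, z_wt, union)
            expected = e_a + e_b - e_a * e_b
            records.append(
                {
                    "drug_a": drug_a.id,
                    "drug_b": drug_b.id,
                    "model": model.id,
                    "effect_a": e_a,
                    "effect_b": e_b,
                    "effect_ab": e_ab,
                    "bliss_expected": expected,
                    "bliss_excess": e_ab - expected,
                    "bliss_class": classify_bliss(e_a, e_b, e_ab, tol),
                    "hit": e_ab >= cutoff,
                }
            )
    return pd.DataFrame.from_records(records, columns=[
        "drug_a", "drug_b", "model", "effect_a", "effect_b", "effect_ab",
        "bliss_expected", "bliss_excess", "bliss_class", "hit",
    ])


def safety_check(
    control_model: MetabolicNetwork,
    medium: Optional[MediumDefinition],
    target_genes: Iterable[str],
    eta: float = SAFETY_ETA_DEFAULT,
) -> Dict[str, object]:
    """Healthy-control check for a joint target knockout.

    Passes when both the maximal ATP-demand flux and the maximal
    biomass flux retain at least (1 − η) of their wild-type optima
    after the deletion.  The control model must declare an ATP-demand
    reaction.
    """
    if control_model.atp_demand_id is None:
        raise ValueError(
            f"control model {control_model.id!r} has no ATP-demand reaction configured"
        )
    network = apply_medium(control_model, medium) if medium is not None else control_model
    problem = LinearProblem(network)
    ratios = {}
    for label, objective in (("biomass", network.objective_id),
                             ("atp", network.atp_demand_id)):
        wt = fba(network, objective=objective, problem=problem)
        if not wt.optimal or wt.objective_value <= TAU_FEAS:
            raise ValueError(
                f"control model {control_model.id!r} has no wild-type {label} flux"
            )
        from .essentiality import reactions_disabled_by

        closed = {r: (0.0, 0.0)
                  for r in reactions_disabled_by(network, set(target_genes))}
        ko = fba(network, objective=objective, extra_bounds=closed, problem=problem)
        z_ko = ko.objective_value if ko.optimal else 0.0
        ratios[label] = min(max(z_ko / wt.objective_value, 0.0), 1.0)
    passed = all(r >= 1.0 - eta for r in ratios.values())
    return {
        "pass": passed,
        "biomass_ratio": ratios["biomass"],
        "atp_ratio": ratios["atp"],
        "eta": eta,
    }


def subtype_specificity(results: pd.DataFrame, key_columns: Sequence[str]) -> pd.DataFrame:
    """Label each drug/pair by the models in which it is a hit.

    ``pan``: hit in every screened model; ``specific:<model>``: hit in
    exactly one; otherwise the sorted list of hit models joined by
    '|' (or ``none``).
    """
    models = sorted(results["model"].unique())
    rows = []
    for key, group in results.groupby(list(key_columns), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        hit_models = sorted(group.loc[group["hit"], "model"].unique())
        if hit_models and set(hit_models) == set(models):
            label = "pan"
        elif len(hit_models) == 1:
            label = f"specific:{hit_models[0]}"
        elif hit_models:
            label = "|".join(hit_models)
        else:
            label = "none"
        row = dict(zip(key_columns, key))
        row["hit_models"] = "|".join(hit_models)
        row["specificity"] = label
        rows.append(row)
    return pd.DataFrame.from_records(rows, columns=[*key_columns, "hit_models", "specificity"])


# ---------------------------------------------------------------------------
# catalog I/O


def read_drug_catalog(path) -> DrugCatalog:
    """Catalog TSV: drug_id, name, categories (;-joined), targets
    (;-joined gene ids), cofactor_of_target, induces_proliferation."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    drugs = {}
    for _, row in df.iterrows():
        drug = Drug(
            id=row["drug_id"],
            name=row.get("name", row["drug_id"]),
            targets=frozenset(t for t in row["targets"].split(";") if t),
            categories=frozenset(c for c in row["categories"].split(";") if c),
            cofactor_of_target=row.get("cofactor_of_target", "") in {"1", "True", "true"},
            induces_proliferation=row.get("induces_proliferation", "") in {"1", "True", "true"},
        )
        drugs[drug.id] = drug
    return DrugCatalog(drugs)


def write_drug_catalog(catalog: DrugCatalog, path) -> None:
    rows = [
        {
            "drug_id": d.id,
            "name": d.name,
            "categories": ";".join(sorted(d.categories)),
            "targets": ";".join(sorted(d.targets)),
            "cofactor_of_target": int(d.cofactor_of_target),
            "induces_proliferation": int(d.induces_proliferation),
        }
        for d in sorted(catalog, key=lambda d: d.id)
    ]
    pd.DataFrame.from_records(rows).to_csv(path, sep="\t", index=False)
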