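"""Exchange-flux profiling: narrow-bounded (growth-critical) exchanges.

For each exchange reaction of a context-specific model the FVA range
at a fixed fraction of the biomass optimum is computed and compared
with the reaction's maximal attainable range (the same FVA with the
optimality constraint removed).  An exchange whose optimal-growth
range is at most 10% of its attainable range is "narrow-bounded": any
perturbation of that flux necessarily alters growth, which is what
makes such metabolites candidate vulnerabilities or biomarkers.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .lp import TAU_FEAS, LinearProblem, fba, fva
from .network import MediumDefinition, MetabolicNetwork, apply_medium

__all__ = [
    "profile_exchanges",
    "classify_narrow_bounded",
    "compare_exchange_profiles",
    "NARROW_RATIO_DEFAULT",
]

NARROW_RATIO_DEFAULT = 0.10


def _directionality(vmin: float, vmax: float, tol: float = TAU_FEAS) -> str:
    lo_zero = abs(vmin) <= tol
    hi_zero = abs(vmax) <= tol
    if lo_zero and hi_zero:
        return "blocked"
    if vmax <= tol:
        return "uptake-only"
    if vmin >= -tol:
        return "release-only"
    return "reversible"


def profile_exchanges(
    model: MetabolicNetwork,
    medium: MediumDefinition,
    fraction: float = 1.0,
    ratio_cutoff: float = NARROW_RATIO_DEFAULT,
    rmax_mode: str = "attainable",
) -> pd.DataFrame:
    """One record per exchange reaction: FVA range at ``fraction`` of the
    biomass optimum, attainable range, relative range r and flags.

    ``rmax_mode`` picks the denominator of r: ``attainable`` (default)
    uses the FVA range with the growth constraint removed, making r
    medium-aware; ``bounds`` uses the raw bound span of the constrained
    reaction.  Raises if the model cannot grow under the medium — a
    non-growing model indicates a broken extraction or a medium
    missing an essential nutrient, so profiling it would be
    meaningless.
    """
    if rmax_mode not in {"attainable", "bounds"}:
        raise ValueError(f"unknown rmax_mode {rmax_mode!r}")
    constrained = apply_medium(model, medium)
    growth = fba(constrained)
    if not growth.optimal or growth.objective_value <= TAU_FEAS:
        raise ValueError(
            f"model {model.id!r} does not grow under the medium "
            f"(status {growth.status}); check extraction and medium composition"
        )
    exchanges = sorted(constrained.exchange_ids)
    problem = LinearProblem(constrained)
    at_opt = fva(constrained, exchanges, fraction=fraction, problem=problem)
    attainable = fva(constrained, exchanges, fraction=None, problem=problem)

    records = []
    for rid in exchanges:
        vmin, vmax = at_opt.range_of(rid)
        if rmax_mode == "bounds":
            rxn = constrained.reactions[rid]
            amin, amax = rxn.lower_bound, rxn.upper_bound
        else:
            amin, amax = attainable.range_of(rid)
        r_max = amax - amin
        span = max(vmax - vmin, 0.0)
        # a reaction with no attainable range at all is fully fixed
        rel = min(span / r_max, 1.0) if r_max > TAU_FEAS else 0.0
        records.append(
            {
                "reaction": rid,
                "metabolite": constrained.exchange_metabolite(rid),
                "model": model.id,
                "minimum": vmin,
                "maximum": vmax,
                "attainable_min": amin,
                "attainable_max": amax,
                "r_max": r_max,
                "relative_range": rel,
                "directionality": _directionality(vmin, vmax),
                "narrow": rel <= ratio_cutoff,
                "fraction": at_opt.fraction,
            }
        )
    return pd.DataFrame.from_records(records).set_index("reaction")


def classify_narrow_bounded(
    profile: pd.DataFrame, ratio_cutoff: float = NARROW_RATIO_DEFAULT
) -> List[str]:
    """Exchanges with relative range ≤ cutoff (inclusive: a range of
    exactly 10% of the attainable range still counts as narrow)."""
    if not (0.0 < ratio_cutoff <= 1.0):
        raise ValueError(f"ratio_cutoff must be in (0, 1], got {ratio_cutoff}")
    mask = profile["relative_range"] <= ratio_cutoff
    return sorted(profile.index[mask])


def compare_exchange_profiles(profiles: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Long-format cross-model comparison of exchange behaviour.

    One row per (metabolite, model).  Metabolites carried by only some
    models are recorded as ``absent`` in the others — absence (the
    exchange never made it into the extracted model) is distinct from
    a present-but-blocked exchange.  A ``specificity`` column marks
    metabolites narrow in every model (``pan``) or in exactly one
    (``specific:<model>``).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two model profiles to compare")
    model_names = [str(p["model"].iloc[0]) for p in profiles]
    by_model: Dict[str, pd.DataFrame] = {
        name: p.reset_index().set_index("metabolite") for name, p in zip(model_names, profiles)
    }
    all_mets = sorted(set().union(*[set(p.index) for p in by_model.values()]))

    rows = []
    for met in all_mets:
        narrow_in = [m for m in model_names if met in by_model[m].index
                     and bool(by_model[m].loc[met, "narrow"])]
        present_in = [m for m in model_names if met in by_model[m].index]
        if narrow_in and set(narrow_in) == set(model_names):
            specificity = "pan"
        elif len(narrow_in) == 1:
            specificity = f"specific:{narrow_in[0]}"
        elif narrow_in:
            specificity = "shared:" + "|".join(narrow_in)
        else:
            specificity = "none"
        for m in model_names:
            if met not in by_model[m].index:
                rows.append({"metabolite": met, "model": m, "status": "absent",
                             "minimum": np.nan, "maximum": np.nan, "narrow": False,
                             "directionality": "absent", "uptake_rank": np.nan,
                             "specificity": specificity})
                continue
            rec = by_model[m].loc[met]
            rows.append({"metabolite": met, "model": m, "status": "present",
                         "minimum": float(rec["minimum"]), "maximum": float(rec["maximum"]),
                         "narrow": bool(rec["narrow"]),
                         "directionality": str(rec["directionality"]),
                         "uptake_rank": np.nan, "specificity": specificity})

    df = pd.DataFrame.from_records(rows)
    # rank uptake magnitude (most negative minimum = strongest uptake = rank 1)
    for met in all_mets:
        sel = (df["metabolite"] == met) & (df["status"] == "present")
        uptake = -df.loc[sel, "minimum"]
        df.loc[sel, "uptake_rank"] = uptake.rank(ascending=False, method="min")
    return df
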