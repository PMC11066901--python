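"""Single-gene deletion screening and essential-gene classification.

Deleting a gene disables every reaction whose GPR rule evaluates false
without it; growth is then re-optimized and the knockout-to-wild-type
growth ratio (grRatio) recorded.  A gene is essential when its
knockout reduces growth by at least the cutoff (default 50%,
inclusive) and lethal when growth collapses entirely.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set

import pandas as pd

from .lp import TAU_FEAS, LinearProblem, fba
from .network import MediumDefinition, MetabolicNetwork, apply_medium

__all__ = [
    "reactions_disabled_by",
    "knockout_growth",
    "single_gene_deletion",
    "classify_essential",
    "annotate_common_essentials",
    "ESSENTIALITY_CUTOFF_DEFAULT",
]

ESSENTIALITY_CUTOFF_DEFAULT = 0.5


def reactions_disabled_by(network: MetabolicNetwork, deleted: Set[str]) -> List[str]:
    """Reactions whose GPR evaluates false after deleting ``deleted``.

    Only reactions sharing a gene with the deletion set are re-evaluated;
    empty-GPR reactions are never disabled.
    """
    disabled = []
    for rxn in network.reactions.values():
        if rxn.gpr.is_empty or not (rxn.gpr.genes & deleted):
            continue
        if not rxn.gpr.evaluate(deleted):
            disabled.append(rxn.id)
    return disabled


def knockout_growth(
    network: MetabolicNetwork,
    deleted: Iterable[str],
    problem: Optional[LinearProblem] = None,
) -> float:
    """Optimal biomass flux after jointly deleting the given genes.

    Infeasible knockouts count as zero growth (the cell cannot reach
    any steady state); negative optima from solver noise are clipped
    to zero.
    """
    problem = problem or LinearProblem(network)
    closed = {rid: (0.0, 0.0) for rid in reactions_disabled_by(network, set(deleted))}
    sol = fba(network, extra_bounds=closed, problem=problem)
    if not sol.optimal:
        return 0.0
    return max(sol.objective_value, 0.0)


def single_gene_deletion(
    model: MetabolicNetwork,
    medium: Optional[MediumDefinition] = None,
    genes: Optional[Sequence[str]] = None,
    cutoff: float = ESSENTIALITY_CUTOFF_DEFAULT,
) -> pd.DataFrame:
    """Screen every gene (or a subset) by single knockout.

    Returns a table indexed by gene with wild-type growth, knockout
    growth, grRatio (clipped to [0, 1]) and essential/lethal flags.
    Bounds are restored between genes; results do not depend on gene
    order.  Raises when the wild-type model does not grow, since
    growth ratios would be undefined.
    """
    network = apply_medium(model, medium) if medium is not None else model
    problem = LinearProblem(network)
    wt = fba(network, problem=problem)
    if not wt.optimal or wt.objective_value <= TAU_FEAS:
        raise ValueError(
            f"wild-type model {model.id!r} does not grow (status {wt.status}); "
            "gene deletion ratios are undefined"
        )
    z_wt = wt.objective_value
    gene_list = sorted(genes) if genes is not None else sorted(network.genes)

    records = []
    for gene in gene_list:
        z_ko = knockout_growth(network, {gene}, problem=problem)
        ratio = min(max(z_ko / z_wt, 0.0), 1.0)
        records.append(
            {
                "gene": gene,
                "growth_wt": z_wt,
                "growth_ko": z_ko,
                "grRatio": ratio,
                "essential": ratio <= 1.0 - cutoff,
                "lethal": ratio <= TAU_FEAS,
            }
        )
    return pd.DataFrame.from_records(records).set_index("gene")


def classify_essential(
    results: pd.DataFrame, cutoff: float = ESSENTIALITY_CUTOFF_DEFAULT
) -> Set[str]:
    """Genes whose knockout reduces growth by at least ``cutoff``.

    The boundary is inclusive: grRatio exactly 1 − cutoff counts as
    essential ("at least 50%" growth reduction).
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    return set(results.index[results["grRatio"] <= 1.0 - cutoff])


def annotate_common_essentials(
    essential: Iterable[str], reference: Iterable[str]
) -> pd.DataFrame:
    """Mark which essential genes appear in a common-essentials
    reference list (e.g. pan-cancer CRISPR screens); duplicates in the
    reference are ignored."""
    import logging

    ref = set(reference)
    if not ref:
        logging.getLogger(__name__).warning("empty common-essentials reference list")
    rows = [{"gene": g, "common_essential": g in ref} for g in sorted(set(essential))]
    return pd.DataFrame.from_records(rows, columns=["gene", "common_essential"]).set_index("gene")


def read_gene_list(path) -> List[str]:
    """One gene id per line; blank lines and #-comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
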