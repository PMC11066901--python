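"""Context-specific model building from expression data.

The chain mirrors the FASTCORE-family workflow for RNA-seq-driven
model extraction: per-sample discretization of expression into
expressed / unknown / inactive calls (two-component Gaussian mixture
on log2(x+1)), GPR-based mapping of gene calls to reaction calls
(AND → min, OR → max), pooling of per-sample calls into a consensus
core/inactive assignment per sample group, and extraction of a
compact flux-consistent sub-network containing the core.

The extractor is the two-LP FASTCORE scheme: LP7 pushes as many core
reactions as possible above the flux threshold ε, LP10 then finds a
flux mode through those core reactions with minimal L1 weight on
non-core reactions; reversible core reactions that cannot be reached
forward are probed with flipped bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import coo_matrix, csr_matrix, eye_array, hstack

from .lp import EPSILON_FLUX, LinearProblem, SolverError, fba, find_consistent_subnetwork
from .network import MediumDefinition, MetabolicNetwork, apply_medium

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionProfile",
    "GeneCalls",
    "CoreAssignment",
    "ExtractionError",
    "discretize_expression",
    "map_calls_to_reactions",
    "fastcore_extract",
    "consensus_assignment",
    "build_consensus_model",
    "read_expression",
    "write_expression",
]

P_HI_DEFAULT = 0.9
P_LO_DEFAULT = 0.1
CONSENSUS_Q_DEFAULT = 0.9


class ExtractionError(RuntimeError):
    """Core reactions blocked, or no model can be assembled."""


@dataclass
class ExpressionProfile:
    """Gene × sample matrix of non-negative expression (TPM/FPKM-like)
    with a sample → group (subtype) labelling."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    subtypes: Dict[str, str]  # sample id -> subtype label

    def __post_init__(self):
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")

    def samples_of(self, subtype: str) -> List[str]:
        return [s for s in self.values.columns if self.subtypes.get(s) == subtype]

    @property
    def subtype_names(self) -> List[str]:
        seen = []
        for s in self.values.columns:
            lab = self.subtypes.get(s)
            if lab is not None and lab not in seen:
                seen.append(lab)
        return seen


@dataclass
class GeneCalls:
    """Ternary calls per gene × sample: +1 expressed, 0 unknown, −1 inactive."""

    calls: pd.DataFrame

    def column(self, sample: str) -> Dict[str, int]:
        return self.calls[sample].astype(int).to_dict()


@dataclass
class CoreAssignment:
    """Disjoint reaction sets for one sample or consensus group."""

    core: Set[str]
    inactive: Set[str]
    unknown: Set[str]

    def __post_init__(self):
        if self.core & self.inactive or self.core & self.unknown or self.inactive & self.unknown:
            raise ValueError("core/inactive/unknown sets must be disjoint")


# ---------------------------------------------------------------------------
# discretization


def discretize_expression(
    profile: ExpressionProfile,
    p_hi: float = P_HI_DEFAULT,
    p_lo: float = P_LO_DEFAULT,
    seed: int = 0,
) -> GeneCalls:
    """Ternary expressed/unknown/inactive calls per sample.

    Per sample, a two-component Gaussian mixture is fitted to
    log2(x+1) of the genes with nonzero expression; the component with
    the larger mean is "expressed".  A gene is called +1 when its
    posterior probability of the expressed component is ≥ ``p_hi``,
    −1 when ≤ ``p_lo``, 0 otherwise.  Zero-expression genes are −1.
    A degenerate sample (all nonzero values equal, or fewer than two
    distinct values) yields all-0 calls with a warning.
    """
    from sklearn.mixture import GaussianMixture

    out = {}
    for sample in profile.values.columns:
        x = profile.values[sample]
        calls = pd.Series(0, index=x.index, dtype=int)
        calls.loc[x.index[x == 0]] = -1  # no expression support at all
        nonzero = x[x > 0]
        logx = np.log2(nonzero + 1.0)
        if len(nonzero) == 0:
            out[sample] = calls
            continue
        if len(nonzero) < 2 or np.ptp(logx.values) < 1e-12:
            logger.warning(
                "sample %r has degenerate expression; nonzero calls unknown", sample
            )
            out[sample] = calls
            continue
        gm = GaussianMixture(n_components=2, random_state=seed, n_init=1)
        data = logx.values.reshape(-1, 1)
        gm.fit(data)
        hi_comp = int(np.argmax(gm.means_.ravel()))
        post_hi = gm.predict_proba(data)[:, hi_comp]
        nz_calls = np.where(post_hi >= p_hi, 1, np.where(post_hi <= p_lo, -1, 0))
        calls.loc[nonzero.index] = nz_calls
        out[sample] = calls
    return GeneCalls(pd.DataFrame(out, index=profile.values.index))


def map_calls_to_reactions(
    network: MetabolicNetwork, calls: GeneCalls, sample: str
) -> CoreAssignment:
    """Reaction-level calls via GPR (AND → min, OR → max over {−1,0,+1}).

    Score +1 → core, −1 → inactive, 0 or empty GPR → unknown.  Genes
    missing from the calls count as unknown.
    """
    gene_calls = calls.column(sample)
    core, inactive, unknown = set(), set(), set()
    for rxn in network.reactions.values():
        score = rxn.gpr.score(gene_calls)
        if score > 0:
            core.add(rxn.id)
        elif score < 0:
            inactive.add(rxn.id)
        else:
            unknown.add(rxn.id)
    return CoreAssignment(core, inactive, unknown)


# ---------------------------------------------------------------------------
# FASTCORE extraction


def _lp7_indices(S, lb, ub, targets: Sequence[int], epsilon: float) -> np.ndarray:
    n = S.shape[1]
    k = len(targets)
    if k == 0:
        return np.zeros(n)
    c = np.concatenate([np.zeros(n), -np.ones(k)])
    A_eq = hstack([S, csr_matrix((S.shape[0], k))])
    pick = csr_matrix(coo_matrix((np.ones(k), (np.arange(k), np.array(targets))), shape=(k, n)))
    A_ub = hstack([-pick, eye_array(k, format="csr")])
    bounds = np.column_stack(
        [np.concatenate([lb, np.zeros(k)]), np.concatenate([ub, np.full(k, epsilon)])]
    )
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]), A_ub=A_ub, b_ub=np.zeros(k),
                  bounds=bounds, method="highs")
    if res.status != 0:
        raise SolverError(f"LP7 failed: {res.message}")
    return res.x[:n]


def _lp10(S, lb, ub, hold: Sequence[int], penalty: Sequence[int], epsilon: float) -> np.ndarray:
    """Minimize Σ_{p∈penalty} |v_p| subject to v_k ≥ ε for k in hold."""
    n = S.shape[1]
    m = len(penalty)
    lb = lb.copy()
    for k in hold:
        lb[k] = max(lb[k], epsilon)
    if m == 0:
        c = np.zeros(n)
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=np.column_stack([lb, ub]), method="highs")
        if res.status != 0:
            raise SolverError(f"LP10 feasibility failed: {res.message}")
        return res.x
    c = np.concatenate([np.zeros(n), np.ones(m)])
    A_eq = hstack([S, csr_matrix((S.shape[0], m))])
    pick = csr_matrix(coo_matrix((np.ones(m), (np.arange(m), np.array(penalty))), shape=(m, n)))
    # v_p - a_p <= 0 and -v_p - a_p <= 0  (a_p >= |v_p|)
    from scipy.sparse import vstack as svstack

    A_ub = svstack([hstack([pick, -eye_array(m, format="csr")]),
                    hstack([-pick, -eye_array(m, format="csr")])])
    bigM = float(max(np.max(np.abs(lb)), np.max(np.abs(ub)), 1.0))
    bounds = np.column_stack(
        [np.concatenate([lb, np.zeros(m)]), np.concatenate([ub, np.full(m, bigM)])]
    )
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]),
                  A_ub=A_ub, b_ub=np.zeros(2 * m), bounds=bounds, method="highs")
    if res.status != 0:
        raise SolverError(f"LP10 failed: {res.message}")
    return res.x[:n]


def fastcore_extract(
    network: MetabolicNetwork,
    core: Iterable[str],
    epsilon: float = EPSILON_FLUX,
) -> Set[str]:
    """Compact flux-consistent reaction set A ⊇ core (two-LP FASTCORE).

    Pre-conditions: the network must already be flux-consistent (run
    :func:`find_consistent_subnetwork` first and drop the complement)
    and inactive reactions must have been closed beforehand.  Raises
    :class:`ExtractionError` listing any core reaction that cannot
    carry ε flux.  Deterministic: reactions are processed in sorted-id
    order.
    """
    core = sorted(set(core))
    missing = [r for r in core if r not in network.reactions]
    if missing:
        raise ExtractionError(f"core reactions not in network: {missing}")
    if not core:
        return set()

    problem = LinearProblem(network)
    order = problem.reaction_ids
    ridx = problem.index
    S, lb0, ub0 = problem.S, problem.lb.copy(), problem.ub.copy()
    support_tol = 0.99 * epsilon

    core_idx = [ridx(r) for r in core]
    rev = lb0 < 0
    irr_core = [j for j in core_idx if not rev[j]]
    n = len(order)
    sign = np.ones(n)

    def effective():
        # sign-flipped frame probes the backward direction of reversibles
        if (sign < 0).any():
            S_eff = csr_matrix(S.multiply(sign))
            lb = np.where(sign > 0, lb0, -ub0)
            ub = np.where(sign > 0, ub0, -lb0)
            return S_eff, lb, ub
        return S, lb0, ub0

    def sparse_mode(targets: List[int], penalty_set: Set[int],
                    singleton: bool) -> Set[int]:
        if not targets:
            return set()
        probe = targets[:1] if singleton else targets
        S_eff, lb, ub = effective()
        v = _lp7_indices(S_eff, lb, ub, probe, epsilon)
        hold = [j for j in probe if v[j] >= support_tol]
        if not hold:
            return set()
        penalty = sorted(penalty_set)
        v = _lp10(S_eff, lb, ub, hold, penalty, epsilon)
        return {j for j in range(n) if abs(v[j]) >= support_tol}

    A: Set[int] = set()
    penalty_pool = {j for j in range(n) if order[j] not in set(core)}

    supp = sparse_mode(irr_core, penalty_pool, singleton=False)
    blocked = [order[j] for j in irr_core if j not in supp]
    if blocked:
        raise ExtractionError(f"irreversible core reactions cannot carry flux: {sorted(blocked)}")
    A |= supp

    J = [j for j in core_idx if j not in A]
    flipped = False
    singleton = False
    while J:
        penalty = penalty_pool - A
        supp = sparse_mode(J, penalty, singleton)
        A |= supp
        if any(j in A for j in J):
            J = [j for j in J if j not in A]
            flipped = False
            singleton = False
            sign[:] = 1.0
        else:
            probe = J[:1] if singleton else J
            rev_probe = [j for j in probe if rev[j]]
            if flipped or not rev_probe:
                if singleton:
                    raise ExtractionError(
                        f"core reactions cannot carry flux: {[order[J[0]]]}"
                    )
                singleton = True
                flipped = False
                sign[:] = 1.0
            else:
                for j in rev_probe:
                    sign[j] *= -1.0
                flipped = True
    return {order[j] for j in sorted(A)}


# ---------------------------------------------------------------------------
# consensus


def consensus_assignment(
    assignments: Sequence[CoreAssignment], q: float = CONSENSUS_Q_DEFAULT
) -> CoreAssignment:
    """Pool per-sample assignments: a reaction is consensus-core
    (consensus-inactive) when it is core (inactive) in ≥ q of the
    samples; everything else is unknown."""
    if not assignments:
        raise ValueError("need at least one sample assignment")
    if not (0.0 < q <= 1.0):
        raise ValueError(f"consensus threshold q must be in (0, 1], got {q}")
    n = len(assignments)
    all_rxns = set()
    for a in assignments:
        all_rxns |= a.core | a.inactive | a.unknown
    core, inactive, unknown = set(), set(), set()
    for rxn in all_rxns:
        n_core = sum(rxn in a.core for a in assignments)
        n_inact = sum(rxn in a.inactive for a in assignments)
        if n_core / n >= q:
            core.add(rxn)
        elif n_inact / n >= q:
            inactive.add(rxn)
        else:
            unknown.add(rxn)
    return CoreAssignment(core, inactive, unknown)


def build_consensus_model(
    network: MetabolicNetwork,
    assignments: Sequence[CoreAssignment],
    medium: MediumDefinition,
    q: float = CONSENSUS_Q_DEFAULT,
    epsilon: float = EPSILON_FLUX,
    model_id: str = "consensus",
) -> MetabolicNetwork:
    """Consensus context-specific model for one sample group.

    Pipeline: pool sample assignments at threshold q → close consensus-
    inactive reactions → apply the medium → drop flux-inconsistent
    reactions → FASTCORE-extract the consensus core → induced
    sub-network.  The biomass objective, the ATP demand (when present)
    and the medium's exchange reactions are always force-included in
    the core, otherwise no growth objective would survive extraction.
    """
    consensus = consensus_assignment(assignments, q)

    forced = {network.objective_id}
    if network.atp_demand_id:
        forced.add(network.atp_demand_id)
    medium_mets = set(medium.uptake_rates)
    for rid in network.exchange_ids:
        if network.exchange_metabolite(rid) in medium_mets:
            forced.add(rid)

    closable = consensus.inactive - forced
    closed = network.with_bounds({r: (0.0, 0.0) for r in closable})
    constrained = apply_medium(closed, medium)

    consistent = find_consistent_subnetwork(constrained, epsilon)
    core = (consensus.core | forced) & set(network.reactions)
    dropped_core = core - consistent
    if dropped_core:
        logger.info(
            "%d core reactions are flux-inconsistent under the medium and were dropped: %s",
            len(dropped_core), sorted(dropped_core),
        )
    core &= consistent
    if not core:
        raise ExtractionError("empty consensus core: no model can be built")

    pruned = constrained.subnetwork(sorted(consistent), id=model_id)
    extracted = fastcore_extract(pruned, core, epsilon)
    model = constrained.subnetwork(sorted(extracted), id=model_id)

    growth = fba(model)
    if not growth.optimal or growth.objective_value <= epsilon:
        raise ExtractionError(
            f"extracted model {model_id!r} cannot produce biomass "
            f"(status {growth.status}, z*={growth.objective_value})"
        )
    return model


# ---------------------------------------------------------------------------
# I/O


def read_expression(values_path, subtypes_path) -> ExpressionProfile:
    """Expression TSV (genes × samples, first column gene ids) plus a
    subtype-labels CSV with columns ``sample,subtype``."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    labels = pd.read_csv(subtypes_path)
    subtypes = dict(zip(labels["sample"], labels["subtype"]))
    return ExpressionProfile(values, subtypes)


def write_expression(profile: ExpressionProfile, values_path, subtypes_path) -> None:
    profile.values.to_csv(values_path, sep="\t")
    pd.DataFrame(
        {"sample": list(profile.values.columns),
         "subtype": [profile.subtypes[s] for s in profile.values.columns]}
    ).to_csv(subtypes_path, index=False)
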