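"""Linear-programming core: FBA, FVA and flux-consistency testing.

All stages of the pipeline reduce to linear programs over the
steady-state polytope {v : S·v = 0, lb ≤ v ≤ ub}.  Flux balance
analysis (FBA) maximizes one reaction's flux (the biomass proxy);
flux variability analysis (FVA) reports each reaction's attainable
min/max while the objective is held at a fraction of its optimum; the
consistency sweep finds the reactions able to carry at least ε flux in
some steady state, using the few-LP block-detection strategy of the
FASTCORE family rather than one LP pair per reaction.

Solved with the HiGHS solver through :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import coo_matrix, csr_matrix, eye_array, hstack, vstack

from .network import MetabolicNetwork

__all__ = [
    "FluxSolution",
    "FVAResult",
    "LinearProblem",
    "SolverError",
    "fba",
    "fva",
    "find_consistent_subnetwork",
    "TAU_FEAS",
    "EPSILON_FLUX",
]

TAU_FEAS = 1e-9  # solver feasibility tolerance
EPSILON_FLUX = 1e-4  # minimum flux magnitude counted as "carrying flux"
_OPT_RELAX = 1e-6  # relative relaxation of the optimum constraint in FVA


class SolverError(RuntimeError):
    """The LP solver failed in an unexpected way (not plain infeasibility)."""


@dataclass
class FluxSolution:
    objective_value: Optional[float]
    fluxes: Optional[pd.Series]
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAResult:
    ranges: pd.DataFrame  # index: reaction id; columns: minimum, maximum
    fraction: float
    reference_optimum: float

    def range_of(self, rxn_id: str) -> Tuple[float, float]:
        row = self.ranges.loc[rxn_id]
        return float(row["minimum"]), float(row["maximum"])


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


class LinearProblem:
    """Reusable LP wrapper for one network: S·v = 0, lb ≤ v ≤ ub.

    Bounds may be temporarily overridden (gene knockouts, optimum
    pinning) without mutating the source network.
    """

    def __init__(self, network: MetabolicNetwork):
        self.network = network
        self.reaction_ids: List[str] = list(network.reactions)
        self._ridx = {r: i for i, r in enumerate(self.reaction_ids)}
        met_ids = list(network.metabolites)
        midx = {m: i for i, m in enumerate(met_ids)}
        rows, cols, vals = [], [], []
        for j, rid in enumerate(self.reaction_ids):
            for met, coef in network.reactions[rid].stoichiometry.items():
                rows.append(midx[met])
                cols.append(j)
                vals.append(coef)
        self.S = csr_matrix(
            coo_matrix((vals, (rows, cols)), shape=(len(met_ids), len(self.reaction_ids)))
        )
        self.lb = np.array(
            [network.reactions[r].lower_bound for r in self.reaction_ids], dtype=float
        )
        self.ub = np.array(
            [network.reactions[r].upper_bound for r in self.reaction_ids], dtype=float
        )

    @property
    def n(self) -> int:
        return len(self.reaction_ids)

    def index(self, rxn_id: str) -> int:
        return self._ridx[rxn_id]

    def _solve(self, c: np.ndarray, lb: np.ndarray, ub: np.ndarray):
        res = linprog(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        status = _STATUS.get(res.status, "failed")
        if status not in {"optimal", "infeasible", "unbounded"}:
            raise SolverError(f"LP solver failed with status {status!r}: {res.message}")
        return res, status

    def optimize(
        self,
        objective: str,
        sense: str = "max",
        extra_bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    ) -> FluxSolution:
        lb, ub = self.lb.copy(), self.ub.copy()
        if extra_bounds:
            for rid, (lo, hi) in extra_bounds.items():
                j = self._ridx[rid]
                lb[j], ub[j] = lo, hi
        c = np.zeros(self.n)
        c[self._ridx[objective]] = -1.0 if sense == "max" else 1.0
        res, status = self._solve(c, lb, ub)
        if status != "optimal":
            return FluxSolution(None, None, status)
        v = pd.Series(res.x, index=self.reaction_ids)
        z = float(v[objective])
        return FluxSolution(z, v, "optimal")


def fba(
    network: MetabolicNetwork,
    objective: Optional[str] = None,
    extra_bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    problem: Optional[LinearProblem] = None,
) -> FluxSolution:
    """Maximize the objective reaction's flux at steady state.

    Infeasibility is reported as status, never silently as zero growth.
    """
    problem = problem or LinearProblem(network)
    objective = objective or network.objective_id
    return problem.optimize(objective, "max", extra_bounds)


def _optimum_floor(z_star: float, fraction: float) -> float:
    """Lower bound imposed on the objective during FVA.

    At fraction 1.0 the constraint is relaxed to (1−1e−6)·z* so the
    optimal face itself stays numerically feasible.
    """
    target = fraction * z_star
    relax = _OPT_RELAX * max(1.0, abs(z_star))
    if fraction >= 1.0 - 1e-12:
        return target - relax
    return target


def fva(
    network: MetabolicNetwork,
    reactions: Optional[Sequence[str]] = None,
    fraction: float = 1.0,
    objective: Optional[str] = None,
    problem: Optional[LinearProblem] = None,
    extra_bounds: Optional[Dict[str, Tuple[float, float]]] = None,
) -> FVAResult:
    """Per-reaction flux min/max with the objective held ≥ fraction·z*.

    ``fraction`` must lie in (0, 1]; pass ``fraction=None`` for the
    unconstrained attainable range (the f→0 limit used as the
    "maximal range" denominator in exchange profiling).
    """
    if fraction is not None and not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    problem = problem or LinearProblem(network)
    objective = objective or network.objective_id
    reactions = list(reactions) if reactions is not None else list(problem.reaction_ids)

    pin: Dict[str, Tuple[float, float]] = dict(extra_bounds or {})
    z_star = 0.0
    if fraction is not None:
        sol = fba(network, objective, extra_bounds=extra_bounds, problem=problem)
        if not sol.optimal:
            raise SolverError(f"FVA reference FBA is {sol.status}; cannot fix the optimum")
        z_star = sol.objective_value
        j = problem.index(objective)
        base_lb = pin.get(objective, (problem.lb[j], problem.ub[j]))
        floor = max(base_lb[0], _optimum_floor(z_star, fraction))
        pin[objective] = (floor, base_lb[1])

    mins, maxs = {}, {}
    for rid in reactions:
        lo = problem.optimize(rid, "min", pin)
        hi = problem.optimize(rid, "max", pin)
        # Unbounded directions are capped at the reaction's own bounds
        # (Recon-style ±1000 caps are assumed present in realistic inputs).
        j = problem.index(rid)
        mins[rid] = lo.objective_value if lo.optimal else float(problem.lb[j])
        maxs[rid] = hi.objective_value if hi.optimal else float(problem.ub[j])
        if not lo.optimal and lo.status == "infeasible":
            raise SolverError(f"FVA subproblem infeasible for {rid!r}")
    ranges = pd.DataFrame({"minimum": mins, "maximum": maxs}).loc[reactions]
    # clamp solver noise so min <= max and both respect the box
    ranges["minimum"] = np.minimum(ranges["minimum"], ranges["maximum"])
    return FVAResult(ranges, fraction if fraction is not None else 0.0, z_star)


# ---------------------------------------------------------------------------
# flux consistency (FastCC-style)


def _lp7(S, targets: Sequence[int], epsilon: float,
         lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    """Maximize the number of target reactions with forward flux ≥ ε.

    Auxiliary variables z_j ∈ [0, ε] with z_j ≤ v_j; maximizing Σz
    pushes as many targets as possible up to ε simultaneously.
    Returns the flux vector v.  ``S`` may have sign-flipped columns to
    probe the backward direction of reversible reactions.
    """
    n, k = S.shape[1], len(targets)
    if k == 0:
        return np.zeros(n)
    c = np.concatenate([np.zeros(n), -np.ones(k)])
    A_eq = hstack([S, csr_matrix((S.shape[0], k))])
    # z_j - v_j <= 0
    pick = csr_matrix(
        coo_matrix((np.ones(k), (np.arange(k), np.array(targets))), shape=(k, n))
    )
    A_ub = hstack([-pick, eye_array(k, format="csr")])
    bounds = np.column_stack(
        [np.concatenate([lb, np.zeros(k)]), np.concatenate([ub, np.full(k, epsilon)])]
    )
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        A_ub=A_ub,
        b_ub=np.zeros(k),
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        raise SolverError(f"LP7 failed: {res.message}")
    return res.x[:n]


def find_consistent_subnetwork(
    network: MetabolicNetwork, epsilon: float = EPSILON_FLUX
) -> set:
    """Reactions able to carry |v| ≥ ε in some steady-state distribution.

    FastCC-style sweep: one LP over all irreversible reactions, then a
    shrinking worklist of reversible/unresolved reactions probed jointly
    and, when stuck, individually in both directions.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    problem = LinearProblem(network)
    lb0, ub0 = problem.lb.copy(), problem.ub.copy()
    n = problem.n
    support_tol = 0.99 * epsilon

    rev = lb0 < 0
    irreversible = [j for j in range(n) if not rev[j]]
    consistent: set = set()

    sign = np.ones(n)

    def effective():
        """Sign-flipped system: probing forward in the flipped frame
        probes the backward direction of the original reaction."""
        if (sign < 0).any():
            S_eff = csr_matrix(problem.S.multiply(sign))
            lb = np.where(sign > 0, lb0, -ub0)
            ub = np.where(sign > 0, ub0, -lb0)
            return S_eff, lb, ub
        return problem.S, lb0, ub0

    S_eff, lb, ub = effective()
    v = _lp7(S_eff, irreversible, epsilon, lb, ub)
    consistent |= {j for j in range(n) if abs(v[j]) >= support_tol}
    # irreversible reactions the joint LP could not push are blocked for good
    blocked_irr = set(irreversible) - consistent

    worklist = [j for j in range(n) if j not in consistent and j not in blocked_irr]
    flipped = False
    singleton = False
    while worklist:
        probe = worklist[:1] if singleton else worklist
        S_eff, lb, ub = effective()
        v = _lp7(S_eff, probe, epsilon, lb, ub)
        newly = {j for j in range(n) if abs(v[j]) >= support_tol}
        consistent |= newly
        if any(j in consistent for j in worklist):
            worklist = [j for j in worklist if j not in consistent]
            flipped = False
            sign[:] = 1.0
        else:
            j0 = worklist[0]
            if flipped or not rev[j0]:
                if singleton:
                    worklist = worklist[1:]  # j0 is inconsistent
                    singleton = False
                else:
                    singleton = True
                flipped = False
                sign[:] = 1.0
            else:
                for j in probe:
                    if rev[j]:
                        sign[j] *= -1.0
                flipped = True
    return {problem.reaction_ids[j] for j in sorted(consistent)}
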