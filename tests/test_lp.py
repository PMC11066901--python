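"""FBA/FVA correctness against hand LPs and an independent solver, and
the flux-consistency sweep against exhaustive per-reaction testing."""

import numpy as np
import pytest

from gliomagem.gpr import GprRule
from gliomagem.lp import (
    LinearProblem,
    fba,
    find_consistent_subnetwork,
    fva,
)
from gliomagem.network import Metabolite, MetabolicNetwork, Reaction

from conftest import make_chain_network, make_parallel_network, make_random_network, to_cobra


def brute_force_consistent(network, epsilon=1e-4):
    """Independent oracle: per-reaction max/min LPs."""
    problem = LinearProblem(network)
    out = set()
    for rid in network.reactions:
        hi = problem.optimize(rid, "max")
        lo = problem.optimize(rid, "min")
        if (hi.optimal and hi.objective_value >= epsilon) or (
            lo.optimal and lo.objective_value <= -epsilon
        ):
            out.add(rid)
    return out


def test_fba_bottleneck(chain_network):
    sol = fba(chain_network)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(5.0, abs=1e-9)
    # steady state within tolerance
    problem = LinearProblem(chain_network)
    residual = problem.S @ sol.fluxes.values
    assert np.max(np.abs(residual)) < 1e-9


def test_fba_closed_network_zero(chain_network):
    closed = chain_network.with_bounds(
        {rid: (0.0, 0.0) for rid in chain_network.exchange_ids}
    )
    sol = fba(closed)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_fba_infeasible_reported_not_zero():
    mets = [Metabolite("A_c", "c")]
    # source forced on, no consumer: no steady state exists
    rxns = [Reaction("src", {"A_c": 1}, 2, 5), Reaction("obj", {"A_c": -1}, 0, 0)]
    # obj closed: A_c cannot be drained
    net = MetabolicNetwork(mets, rxns, "obj")
    sol = fba(net)
    assert sol.status == "infeasible"
    assert sol.objective_value is None


@pytest.mark.parametrize("seed", range(25))
def test_fba_matches_independent_solver(seed):
    rng = np.random.default_rng(seed)
    net = make_random_network(rng, n_internal=12, n_mets=6)
    mine = fba(net)
    cm = to_cobra(net)
    theirs = cm.optimize()
    if mine.optimal and theirs.status == "optimal":
        assert mine.objective_value == pytest.approx(theirs.objective_value, abs=1e-6)
    else:
        assert mine.status == theirs.status


def test_fva_forced_at_optimum(chain_network):
    res = fva(chain_network, ["R_AB"], fraction=1.0)
    lo, hi = res.range_of("R_AB")
    assert lo == pytest.approx(5.0, abs=1e-5)
    assert hi == pytest.approx(5.0, abs=1e-5)


def test_fva_parallel_branches_free(parallel_network):
    # biomass needs 10 total; each 5-capacity branch can carry 0..5
    res = fva(parallel_network, ["branch1", "branch2"], fraction=1.0)
    for rid in ("branch1", "branch2"):
        lo, hi = res.range_of(rid)
        assert lo == pytest.approx(5.0, abs=1e-5)  # both needed at optimum
    # halve demand: each branch becomes dispensable at optimum
    relaxed = parallel_network.with_bounds({"biomass": (0.0, 5.0)})
    res = fva(relaxed, ["branch1", "branch2"], fraction=1.0)
    for rid in ("branch1", "branch2"):
        lo, hi = res.range_of(rid)
        assert lo == pytest.approx(0.0, abs=1e-5)
        assert hi == pytest.approx(5.0, abs=1e-5)


def test_fva_relaxation_monotone(chain_network):
    tight = fva(chain_network, fraction=1.0)
    loose = fva(chain_network, fraction=0.9)
    for rid in chain_network.reactions:
        t_lo, t_hi = tight.range_of(rid)
        l_lo, l_hi = loose.range_of(rid)
        assert l_lo <= t_lo + 1e-7 and l_hi >= t_hi - 1e-7


def test_fva_fraction_validation(chain_network):
    with pytest.raises(ValueError):
        fva(chain_network, fraction=0.0)
    with pytest.raises(ValueError):
        fva(chain_network, fraction=1.2)


@pytest.mark.parametrize("seed", range(10))
def test_fva_matches_independent_solver(seed):
    from cobra.flux_analysis import flux_variability_analysis

    rng = np.random.default_rng(seed + 100)
    net = make_random_network(rng, n_internal=10, n_mets=5)
    if not fba(net).optimal:
        pytest.skip("random network infeasible; FVA undefined")
    mine = fva(net, fraction=0.9)
    theirs = flux_variability_analysis(to_cobra(net), fraction_of_optimum=0.9)
    for rid in net.reactions:
        assert mine.ranges.loc[rid, "minimum"] == pytest.approx(
            theirs.loc[rid, "minimum"], abs=1e-5
        )
        assert mine.ranges.loc[rid, "maximum"] == pytest.approx(
            theirs.loc[rid, "maximum"], abs=1e-5
        )


def test_permutation_invariance(chain_network):
    base = fba(chain_network).objective_value
    rng = np.random.default_rng(7)
    order = list(chain_network.reactions)
    rng.shuffle(order)
    mets = list(chain_network.metabolites.values())
    rng.shuffle(mets)
    permuted = MetabolicNetwork(
        mets, [chain_network.reactions[r] for r in order], chain_network.objective_id
    )
    assert fba(permuted).objective_value == pytest.approx(base, rel=1e-9)


# -- consistency ----------------------------------------------------------


def test_dead_end_excluded(chain_network):
    mets = list(chain_network.metabolites.values()) + [Metabolite("D_c", "c")]
    rxns = list(chain_network.reactions.values()) + [
        Reaction("deadend", {"A_c": -1, "D_c": 1}, 0, 1000)
    ]
    net = MetabolicNetwork(mets, rxns, "biomass")
    consistent = find_consistent_subnetwork(net)
    assert "deadend" not in consistent
    assert consistent == set(chain_network.reactions)


def test_fully_coupled_chain_retained(chain_network):
    assert find_consistent_subnetwork(chain_network) == set(chain_network.reactions)


def test_epsilon_must_be_positive(chain_network):
    with pytest.raises(ValueError):
        find_consistent_subnetwork(chain_network, epsilon=0)


@pytest.mark.parametrize("seed", range(25))
def test_consistency_matches_bruteforce(seed):
    rng = np.random.default_rng(seed + 500)
    net = make_random_network(rng, n_internal=12, n_mets=6)
    assert find_consistent_subnetwork(net) == brute_force_consistent(net)


@pytest.mark.parametrize("seed", range(8))
def test_consistency_monotone_under_bound_enlargement(seed):
    rng = np.random.default_rng(seed + 900)
    net = make_random_network(rng, n_internal=10, n_mets=5)
    small = find_consistent_subnetwork(net)
    widened = net.with_bounds(
        {rid: (r.lower_bound * 2 if r.lower_bound < 0 else r.lower_bound,
               r.upper_bound * 2)
         for rid, r in net.reactions.items()}
    )
    assert small <= find_consistent_subnetwork(widened)
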