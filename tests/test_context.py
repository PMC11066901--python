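"""Expression discretization, GPR mapping, FASTCORE extraction and
consensus model assembly."""

import numpy as np
import pandas as pd
import pytest

from gliomagem.context import (
    CoreAssignment,
    ExpressionProfile,
    ExtractionError,
    GeneCalls,
    build_consensus_model,
    consensus_assignment,
    discretize_expression,
    fastcore_extract,
    map_calls_to_reactions,
)
from gliomagem.gpr import GprRule
from gliomagem.lp import fba, find_consistent_subnetwork
from gliomagem.network import MediumDefinition, Metabolite, MetabolicNetwork, Reaction

from conftest import exhaustive_minimal_superset, make_two_route_toy


# -- discretization --------------------------------------------------------


def _bimodal_profile(n_genes=200, frac_expressed=0.4, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    n_hi = int(frac_expressed * n_genes)
    expressed = set(genes[:n_hi])
    mu = np.where([g in expressed for g in genes], np.log(64.0), np.log(1.0))
    values = pd.DataFrame(
        {"s1": np.exp(rng.normal(mu, 0.5))}, index=genes
    )
    return ExpressionProfile(values, {"s1": "A"}), expressed


def test_bimodal_sample_recovers_planted_calls():
    profile, expressed = _bimodal_profile()
    calls = discretize_expression(profile, seed=0).calls["s1"]
    recovered = (calls.loc[sorted(expressed)] == 1).mean()
    assert recovered >= 0.95
    silent = [g for g in profile.values.index if g not in expressed]
    assert (calls.loc[silent] == -1).mean() >= 0.95


def test_all_zero_sample_all_inactive():
    profile = ExpressionProfile(
        pd.DataFrame({"s1": [0.0, 0.0, 0.0]}, index=["a", "b", "c"]), {"s1": "A"}
    )
    calls = discretize_expression(profile).calls["s1"]
    assert (calls == -1).all()


def test_degenerate_sample_all_unknown(caplog):
    import logging

    profile = ExpressionProfile(
        pd.DataFrame({"s1": [5.0, 5.0, 5.0, 5.0]}, index=list("abcd")), {"s1": "A"}
    )
    with caplog.at_level(logging.WARNING, logger="gliomagem.context"):
        calls = discretize_expression(profile).calls["s1"]
    assert (calls == 0).all()
    assert any("degenerate" in rec.message for rec in caplog.records)


def test_duplicated_samples_identical_calls():
    profile, _ = _bimodal_profile(seed=3)
    dup = ExpressionProfile(
        pd.DataFrame({"s1": profile.values["s1"], "s2": profile.values["s1"]}),
        {"s1": "A", "s2": "A"},
    )
    calls = discretize_expression(dup, seed=0).calls
    assert (calls["s1"] == calls["s2"]).all()


def test_negative_expression_rejected():
    with pytest.raises(ValueError, match="non-negative"):
        ExpressionProfile(pd.DataFrame({"s1": [-1.0]}, index=["g"]), {"s1": "A"})


# -- GPR mapping -----------------------------------------------------------


def _two_gene_network():
    mets = [Metabolite("A_c", "c"), Metabolite("B_c", "c")]
    rxns = [
        Reaction("src", {"A_c": 1}, 0, 10),
        Reaction("r_or", {"A_c": -1, "B_c": 1}, 0, 10, GprRule("g1 or g2")),
        Reaction("r_and", {"A_c": -1, "B_c": 1}, 0, 10, GprRule("g1 and g2")),
        Reaction("r_plain", {"A_c": -1, "B_c": 1}, 0, 10),
        Reaction("snk", {"B_c": -1}, 0, 10),
    ]
    return MetabolicNetwork(mets, rxns, "snk")


def test_map_calls_to_reactions_min_max_rule():
    net = _two_gene_network()
    calls = GeneCalls(pd.DataFrame({"s": {"g1": 1, "g2": -1}}))
    assignment = map_calls_to_reactions(net, calls, "s")
    assert "r_or" in assignment.core       # OR -> max(+1, -1) = +1
    assert "r_and" in assignment.inactive  # AND -> min(+1, -1) = -1
    assert "r_plain" in assignment.unknown  # empty GPR -> unknown
    assert "src" in assignment.unknown


def test_core_assignment_disjointness_enforced():
    with pytest.raises(ValueError, match="disjoint"):
        CoreAssignment({"a"}, {"a"}, set())


# -- FASTCORE --------------------------------------------------------------


def test_extract_prefers_short_route():
    net, core, minimal = make_two_route_toy(np.random.default_rng(0))
    consistent = find_consistent_subnetwork(net)
    pruned = net.subnetwork(sorted(consistent))
    extracted = fastcore_extract(pruned, core)
    assert extracted == minimal


@pytest.mark.parametrize("seed", range(6))
def test_extract_matches_exhaustive_minimum(seed):
    net, core, _ = make_two_route_toy(np.random.default_rng(seed))
    consistent = find_consistent_subnetwork(net)
    pruned = net.subnetwork(sorted(consistent))
    extracted = fastcore_extract(pruned, core)
    oracle = exhaustive_minimal_superset(pruned, core)
    assert extracted == oracle


def test_extract_core_all_and_empty():
    net, _, _ = make_two_route_toy(np.random.default_rng(1))
    consistent = find_consistent_subnetwork(net)
    pruned = net.subnetwork(sorted(consistent))
    assert fastcore_extract(pruned, consistent) == consistent
    assert fastcore_extract(pruned, set()) == set()


def test_extract_blocked_core_raises():
    net, _, _ = make_two_route_toy(np.random.default_rng(2))
    # dead decoys are closed; request one as core on the unpruned network
    with pytest.raises(ExtractionError, match="dead0"):
        fastcore_extract(net, {"biomass", "dead0"})


def test_extract_superset_and_consistency_invariants():
    for seed in range(4):
        net, core, _ = make_two_route_toy(np.random.default_rng(seed + 50))
        consistent = find_consistent_subnetwork(net)
        pruned = net.subnetwork(sorted(consistent))
        extracted = fastcore_extract(pruned, core)
        assert extracted >= core
        sub = pruned.subnetwork(sorted(extracted))
        assert find_consistent_subnetwork(sub) == extracted


# -- consensus -------------------------------------------------------------


def _assignment(core=(), inactive=(), unknown=()):
    return CoreAssignment(set(core), set(inactive), set(unknown))


def test_consensus_threshold_rules():
    a = _assignment(core=["r1", "r2"], inactive=["r3"])
    b = _assignment(core=["r1"], inactive=["r3"], unknown=["r2"])
    c = _assignment(core=["r1"], inactive=["r2", "r3"])
    d = _assignment(core=["r1", "r2"], inactive=["r3"])
    pooled = consensus_assignment([a, b, c, d], q=0.9)
    assert pooled.core == {"r1"}       # 4/4
    assert pooled.inactive == {"r3"}   # 4/4
    assert pooled.unknown == {"r2"}    # core only in 2/4 < 0.9
    relaxed = consensus_assignment([a, b, c, d], q=0.5)
    assert "r2" in relaxed.core


def test_consensus_identical_samples_equals_single(default_scenario):
    from gliomagem.context import discretize_expression, map_calls_to_reactions

    net = default_scenario.network
    calls = discretize_expression(default_scenario.profile, seed=1)
    sample = default_scenario.profile.samples_of("S1")[0]
    single = map_calls_to_reactions(net, calls, sample)
    pooled = consensus_assignment([single, single, single], q=0.5)
    assert pooled.core == single.core
    assert pooled.inactive == single.inactive


def test_consensus_validation():
    with pytest.raises(ValueError):
        consensus_assignment([], q=0.9)
    with pytest.raises(ValueError):
        consensus_assignment([_assignment(core=["r"])], q=0.0)


def test_build_consensus_model_subtype_pathways(default_scenario):
    """Planted subtype-specific routes appear only in their own model."""
    sc = default_scenario
    calls = discretize_expression(sc.profile, seed=1)
    models = {}
    for group in ("S1", "S2"):
        samples = sc.profile.samples_of(group)
        assignments = [map_calls_to_reactions(sc.network, calls, s) for s in samples]
        models[group] = build_consensus_model(
            sc.network, assignments, sc.medium, model_id=group
        )
    # S1 uses the nutrient route to precursor 2, S2 the carbon route
    assert "R2a" in models["S1"].reactions and "R2b" not in models["S1"].reactions
    assert "R2b" in models["S2"].reactions and "R2a" not in models["S2"].reactions
    # the S1-specific bypass is absent in S1 but present in S2
    assert "R4c" not in models["S1"].reactions
    assert "R4c" in models["S2"].reactions
    for model in models.values():
        growth = fba(model)
        assert growth.optimal and growth.objective_value > 1e-4
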