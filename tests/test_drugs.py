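"""Drug and combination screening: joint-deletion semantics, Bliss
classification, lethal-single exclusion, safety and specificity."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gliomagem.drugs import (
    Drug,
    DrugCatalog,
    classify_bliss,
    read_drug_catalog,
    safety_check,
    screen_combinations,
    screen_single_drugs,
    subtype_specificity,
    write_drug_catalog,
)
from gliomagem.gpr import GprRule
from gliomagem.network import Metabolite, MetabolicNetwork, Reaction

from conftest import make_parallel_network, make_random_network


def _catalog(*drugs):
    return DrugCatalog({d.id: d for d in drugs})


# -- Bliss ----------------------------------------------------------------


def test_bliss_closed_form_examples():
    assert classify_bliss(0.5, 0.5, 0.75) == "additive"  # E_exp = 0.75
    assert classify_bliss(0.0, 0.4, 0.4, tol=0.05) == "additive"
    assert classify_bliss(0.0, 0.0, 1.0, tol=0.5) == "synergistic"
    assert classify_bliss(0.9, 0.9, 0.2) == "antagonistic"


def test_bliss_grid_matches_closed_form_and_symmetry():
    grid = np.linspace(0.0, 1.0, 10)
    for e_a, e_b, e_ab in itertools.product(grid, repeat=3):
        expected = e_a + e_b - e_a * e_b
        cls = classify_bliss(e_a, e_b, e_ab, tol=0.05)
        assert cls == classify_bliss(e_b, e_a, e_ab, tol=0.05)  # symmetric
        if e_ab > expected + 0.05:
            assert cls == "synergistic"
        elif e_ab < expected - 0.05:
            assert cls == "antagonistic"
        else:
            assert cls == "additive"
        # independence surface is additive at any positive tolerance
        assert classify_bliss(e_a, e_b, expected, tol=1e-9) == "additive"
        assert max(e_a, e_b) - 1e-12 <= expected <= 1.0 + 1e-12


def test_bliss_ratio_form():
    # CI = E_AB / E_exp against 1 ± δ
    assert classify_bliss(0.5, 0.5, 0.75, form="ratio") == "additive"
    assert classify_bliss(0.5, 0.5, 0.9, tol=0.05, form="ratio") == "synergistic"
    assert classify_bliss(0.5, 0.5, 0.5, tol=0.05, form="ratio") == "antagonistic"
    # zero expectation: any joint effect beyond the tolerance is synergy
    assert classify_bliss(0.0, 0.0, 1.0, form="ratio") == "synergistic"
    assert classify_bliss(0.0, 0.0, 0.0, form="ratio") == "additive"
    with pytest.raises(ValueError, match="unknown Bliss form"):
        classify_bliss(0.1, 0.1, 0.1, form="nope")


def test_bliss_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify_bliss(-0.1, 0.5, 0.5)
    with pytest.raises(ValueError):
        classify_bliss(0.1, 0.5, 1.5)


# -- single screen ---------------------------------------------------------


def test_joint_deletion_semantics(parallel_network):
    catalog = _catalog(
        Drug("both", "Both", frozenset({"g1", "g2"}), frozenset({"FDA"})),
        Drug("one", "One", frozenset({"g1"}), frozenset({"FDA"})),
        Drug("orphan", "Orphan", frozenset({"gZ"}), frozenset({"FDA"})),
    )
    res = screen_single_drugs(parallel_network, None, catalog)
    # each branch alone halves growth; deleting both targets kills it
    assert res.loc["one", "effect"] == pytest.approx(0.5, abs=1e-6)
    assert res.loc["both", "effect"] == pytest.approx(1.0, abs=1e-9)
    assert bool(res.loc["both", "lethal"]) and bool(res.loc["both", "hit"])
    assert res.loc["orphan", "effect"] == 0.0
    assert res.loc["orphan", "n_mapped_targets"] == 0


def test_adding_targets_never_decreases_effect():
    rng = np.random.default_rng(11)
    for seed in range(6):
        net = make_random_network(np.random.default_rng(seed + 3000), 12, 6)
        from gliomagem.lp import fba

        sol = fba(net)
        if not sol.optimal or sol.objective_value <= 1e-9 or len(net.genes) < 2:
            continue
        genes = sorted(net.genes)
        base = frozenset(genes[:1])
        bigger = frozenset(genes[:2])
        catalog = _catalog(
            Drug("small", "s", base, frozenset({"FDA"})),
            Drug("big", "b", bigger, frozenset({"FDA"})),
        )
        res = screen_single_drugs(net, None, catalog)
        assert res.loc["big", "effect"] >= res.loc["small", "effect"] - 1e-9


# -- combinations ----------------------------------------------------------


def _redundant_routes_network():
    """Two fully redundant biosynthesis routes to one precursor: either
    knockout alone is free, the double knockout is lethal."""
    mets = [Metabolite("s_e", "e"), Metabolite("A_c", "c"), Metabolite("P_c", "c")]
    rxns = [
        Reaction("EX_s", {"s_e": -1}, -10, 1000),
        Reaction("T", {"s_e": -1, "A_c": 1}, 0, 1000),
        Reaction("route1", {"A_c": -1, "P_c": 1}, 0, 1000, GprRule("ga")),
        Reaction("route2", {"A_c": -1, "P_c": 1}, 0, 1000, GprRule("gb")),
        Reaction("biomass", {"P_c": -1}, 0, 1000),
    ]
    return MetabolicNetwork(mets, rxns, "biomass")


def test_redundant_pair_is_synergistic_hit():
    net = _redundant_routes_network()
    net.id = "M1"
    catalog = _catalog(
        Drug("fda_a", "A", frozenset({"ga"}), frozenset({"FDA"})),
        Drug("iag_b", "B", frozenset({"gb"}), frozenset({"IAG"})),
    )
    combos = screen_combinations([net], None, catalog)
    row = combos[(combos["drug_a"] == "fda_a") & (combos["drug_b"] == "iag_b")].iloc[0]
    assert row["effect_a"] == pytest.approx(0.0, abs=1e-9)
    assert row["effect_b"] == pytest.approx(0.0, abs=1e-9)
    assert row["effect_ab"] == pytest.approx(1.0, abs=1e-9)
    assert row["bliss_class"] == "synergistic"
    assert bool(row["hit"])


def test_irrelevant_pair_not_reported_as_hit():
    net = _redundant_routes_network()
    net.id = "M1"
    catalog = _catalog(
        Drug("fda_x", "X", frozenset({"nope1"}), frozenset({"FDA"})),
        Drug("iag_y", "Y", frozenset({"nope2"}), frozenset({"IAG"})),
    )
    combos = screen_combinations([net], None, catalog)
    assert not combos["hit"].any()
    assert (combos["bliss_class"] == "additive").all()


def test_lethal_single_absent_from_every_pair():
    net = _redundant_routes_network()
    net.id = "M1"
    catalog = _catalog(
        Drug("killer", "K", frozenset({"ga", "gb"}), frozenset({"FDA"})),  # lethal single
        Drug("fda_a", "A", frozenset({"ga"}), frozenset({"FDA"})),
        Drug("iag_b", "B", frozenset({"gb"}), frozenset({"IAG"})),
    )
    combos = screen_combinations([net], None, catalog)
    assert "killer" not in set(combos["drug_a"])
    assert "killer" not in set(combos["drug_b"])
    assert {"fda_a"} == set(combos["drug_a"])


# -- safety ----------------------------------------------------------------


def _control_with_bypass(bypass: bool):
    mets = [Metabolite("s_e", "e"), Metabolite("A_c", "c"), Metabolite("P_c", "c"),
            Metabolite("atp_c", "c")]
    rxns = [
        Reaction("EX_s", {"s_e": -1}, -10, 1000),
        Reaction("T", {"s_e": -1, "A_c": 1}, 0, 1000),
        Reaction("route1", {"A_c": -1, "P_c": 1}, 0, 1000, GprRule("ga")),
        Reaction("atp", {"A_c": -1, "atp_c": 1}, 0, 1000, GprRule("ga")),
        Reaction("DM_atp", {"atp_c": -1}, 0, 1000),
        Reaction("biomass", {"P_c": -1}, 0, 1000),
    ]
    if bypass:
        rxns.insert(3, Reaction("route_byp", {"A_c": -1, "P_c": 1}, 0, 1000, GprRule("gc")))
        rxns.insert(5, Reaction("atp_byp", {"A_c": -1, "atp_c": 1}, 0, 1000, GprRule("gc")))
    return MetabolicNetwork(mets, rxns, "biomass", atp_demand_id="DM_atp")


def test_safety_pass_when_targets_absent_or_bypassed():
    ctrl = _control_with_bypass(bypass=True)
    absent = safety_check(ctrl, None, {"not_a_gene"})
    assert absent["pass"] and absent["biomass_ratio"] == pytest.approx(1.0)
    bypassed = safety_check(ctrl, None, {"ga"})
    assert bypassed["pass"]


def test_safety_fail_when_sole_atp_route_hit():
    ctrl = _control_with_bypass(bypass=False)
    result = safety_check(ctrl, None, {"ga"})
    assert not result["pass"]
    assert result["atp_ratio"] == pytest.approx(0.0, abs=1e-9)


def test_safety_requires_atp_demand():
    net = _redundant_routes_network()
    with pytest.raises(ValueError, match="ATP-demand"):
        safety_check(net, None, {"ga"})


# -- specificity -----------------------------------------------------------


def test_specificity_labels():
    frame = pd.DataFrame(
        {
            "drug": ["d_pan"] * 3 + ["d_one"] * 3 + ["d_two"] * 3,
            "model": ["M1", "M2", "M3"] * 3,
            "hit": [True, True, True, False, True, False, True, True, False],
        }
    )
    labels = subtype_specificity(frame, ["drug"]).set_index("drug")["specificity"]
    assert labels["d_pan"] == "pan"
    assert labels["d_one"] == "specific:M2"
    assert labels["d_two"] == "M1|M2"


# -- catalog I/O -----------------------------------------------------------


def test_catalog_round_trip(tmp_path):
    catalog = _catalog(
        Drug("d1", "DrugOne", frozenset({"g1", "g2"}), frozenset({"FDA", "IAG"}),
             cofactor_of_target=True),
        Drug("d2", "DrugTwo", frozenset({"g3"}), frozenset({"AntiBC"})),
    )
    path = tmp_path / "catalog.tsv"
    write_drug_catalog(catalog, path)
    again = read_drug_catalog(path)
    assert set(again.drugs) == {"d1", "d2"}
    assert again.drugs["d1"].targets == {"g1", "g2"}
    assert again.drugs["d1"].categories == {"FDA", "IAG"}
    assert again.drugs["d1"].cofactor_of_target
    assert not again.drugs["d2"].cofactor_of_target


def test_catalog_validation():
    with pytest.raises(ValueError, match="empty target"):
        Drug("d", "d", frozenset(), frozenset({"FDA"}))
    with pytest.raises(ValueError, match="unknown categories"):
        Drug("d", "d", frozenset({"g"}), frozenset({"NOPE"}))
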