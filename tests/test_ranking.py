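"""Evidence aggregation: potency, exclusions, tier calls and the
lexicographic ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from gliomagem.ranking import (
    EvidenceTable,
    RulesConfig,
    apply_exclusions,
    classify_tiers,
    compute_potency,
    rank_candidates,
    read_evidence,
    write_evidence,
)


def _empty(**overrides):
    from gliomagem.ranking import _EVIDENCE_FILES

    frames = {name: pd.DataFrame(columns=cols) for name, cols in _EVIDENCE_FILES.items()}
    frames.update(overrides)
    return EvidenceTable(**frames)


def _ic50(*records):
    return pd.DataFrame(records, columns=["drug", "cell_line", "ic50_um"])


# -- potency ---------------------------------------------------------------


def test_potency_median():
    ev = _empty(ic50=_ic50(("d", "L1", 1.0), ("d", "L2", 2.0), ("d", "L3", 10.0)))
    assert compute_potency(ev)["d"] == pytest.approx(2.0)


def test_potency_single_record():
    ev = _empty(ic50=_ic50(("d", "L1", 5.0)))
    assert compute_potency(ev)["d"] == pytest.approx(5.0)


def test_potency_dedup_then_median():
    ev = _empty(ic50=_ic50(("d", "X", 2.0), ("d", "X", 4.0), ("d", "Y", 10.0)))
    # lineX averages to 3, then median{3, 10} = 6.5
    assert compute_potency(ev)["d"] == pytest.approx(6.5)


def test_nonpositive_ic50_rejected_with_log(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="gliomagem.ranking"):
        ev = _empty(ic50=_ic50(("d", "L1", -2.0), ("d", "L2", 4.0)))
    assert any("non-positive" in rec.message for rec in caplog.records)
    assert compute_potency(ev)["d"] == pytest.approx(4.0)


# -- exclusions ------------------------------------------------------------


def test_exclusions_logged_once_with_all_reasons():
    excl = pd.DataFrame(
        [("cof", 1, 0), ("both", 1, 1)],
        columns=["drug", "cofactor_of_target", "induces_proliferation"],
    )
    retained, log = apply_exclusions(["cof", "both", "clean"], _empty(exclusions=excl))
    assert retained == ["clean"]
    entries = {e["drug"]: e["reasons"] for e in log}
    assert entries["cof"] == "cofactor_of_target"
    assert entries["both"] == "cofactor_of_target;induces_proliferation"
    assert len(log) == 2


# -- tier calls ------------------------------------------------------------


def test_xenograft_threshold_inclusive():
    for median, expected in [(30.0, "effective"), (25.0, "effective"), (24.9, "ineffective")]:
        ev = _empty(xenograft=pd.DataFrame([("d", median)],
                                           columns=["drug", "growth_reduction_pct"]))
        assert classify_tiers("d", ev)["xenograft"] == expected


def test_untested_tiers():
    calls = classify_tiers("d", _empty())
    assert calls == {"in_vitro": "untested", "xenograft": "untested", "clinical": "untested"}


def test_in_vitro_potency_vs_reference():
    ev = _empty(ic50=_ic50(("d", "L1", 2.0)))
    assert classify_tiers("d", ev, reference_potency=6.0)["in_vitro"] == "effective"
    assert classify_tiers("d", ev, reference_potency=1.0)["in_vitro"] == "ineffective"


def test_clinical_rules_and_tie():
    clinical = pd.DataFrame(
        [
            ("two_arm", "II", 2, "improved"),
            ("one_arm", "II", 1, "improved"),
            ("low_phase", "I", 2, "improved"),
            ("tie", "II", 2, "improved"),
            ("tie", "II", 2, "worse"),
        ],
        columns=["drug", "phase", "arms", "outcome"],
    )
    ev = _empty(clinical=clinical)
    audit = []
    assert classify_tiers("two_arm", ev)["clinical"] == "effective"
    assert classify_tiers("one_arm", ev)["clinical"] == "ineffective"
    assert classify_tiers("low_phase", ev)["clinical"] == "ineffective"
    assert classify_tiers("tie", ev, audit=audit)["clinical"] == "ineffective"
    assert any(e["action"] == "tie" for e in audit)


# -- ranking ---------------------------------------------------------------


def _micro_evidence():
    """Three drugs, tiers equal where stated by the worked example."""
    ic50 = _ic50(
        ("fast", "L1", 1.0), ("fast", "L2", 2.0), ("fast", "L3", 10.0),  # 2 µM
        ("slow", "X", 2.0), ("slow", "X", 4.0), ("slow", "Y", 10.0),     # 6.5 µM
        ("cmb_a", "L1", 3.0), ("cmb_c", "L1", 3.0),
    )
    xeno = pd.DataFrame(
        [("fast", 30.0), ("slow", 30.0), ("cmb_a", 30.0), ("cmb_c", 30.0)],
        columns=["drug", "growth_reduction_pct"],
    )
    ddi = pd.DataFrame(
        [("cmb_a", "cmb_b", "major"), ("cmb_c", "cmb_d", "minor")],
        columns=["drug_a", "drug_b", "severity"],
    )
    return _empty(ic50=ic50, xenograft=xeno, ddi=ddi)


def test_equal_tiers_rank_by_potency():
    ranking, _ = rank_candidates(["fast", "slow"], _micro_evidence())
    ordered = list(ranking["candidate"])
    assert ordered == ["fast", "slow"]
    assert list(ranking["rank"]) == [1, 2]


def test_minor_ddi_outranks_major_with_equal_tiers():
    ranking, _ = rank_candidates(
        ["combo_major", "combo_minor"],
        _micro_evidence(),
        combo_members={"combo_major": ("cmb_a", "cmb_b"),
                       "combo_minor": ("cmb_c", "cmb_d")},
    )
    assert list(ranking["candidate"]) == ["combo_minor", "combo_major"]


def test_fully_untested_listed_last_without_rank():
    ranking, _ = rank_candidates(["fast", "ghost"], _micro_evidence())
    assert list(ranking["candidate"]) == ["fast", "ghost"]
    last = ranking.iloc[-1]
    assert bool(last["untested_overall"])
    assert math.isnan(last["rank"])


def test_ranking_total_order_and_shuffle_stability():
    ev = _micro_evidence()
    base, _ = rank_candidates(["fast", "slow", "ghost"], ev)
    rng = np.random.default_rng(0)
    shuffled_ev = _empty(
        ic50=ev.ic50.sample(frac=1.0, random_state=1).reset_index(drop=True),
        xenograft=ev.xenograft.sample(frac=1.0, random_state=2).reset_index(drop=True),
        ddi=ev.ddi,
    )
    again, _ = rank_candidates(["slow", "ghost", "fast"], shuffled_ev)
    assert list(base["candidate"]) == list(again["candidate"])


def test_ranking_invariant_under_uniform_ic50_rescaling():
    ev = _micro_evidence()
    base, _ = rank_candidates(["fast", "slow"], ev)
    scaled = _empty(ic50=ev.ic50.assign(ic50_um=ev.ic50["ic50_um"] * 1000.0),
                    xenograft=ev.xenograft, ddi=ev.ddi)
    again, _ = rank_candidates(["fast", "slow"], scaled)
    assert list(base["candidate"]) == list(again["candidate"])


def test_excluded_member_drops_combination_with_audit():
    ev = _empty(
        exclusions=pd.DataFrame([("bad", 0, 1)],
                                columns=["drug", "cofactor_of_target",
                                         "induces_proliferation"]),
        ic50=_ic50(("ok", "L1", 1.0)),
    )
    ranking, audit = rank_candidates(
        ["ok", "combo"], ev, combo_members={"combo": ("ok", "bad")}
    )
    assert list(ranking["candidate"]) == ["ok"]
    actions = {e["drug"]: e["action"] for e in audit}
    assert actions["bad"] == "excluded"
    assert actions["combo"] == "dropped_candidate"


def test_rules_config_file_round_trip(tmp_path):
    path = tmp_path / "rules.cfg"
    path.write_text("viability_min_pct = 40\nxenograft_min_pct = 20\n# comment\n")
    rules = RulesConfig.from_file(path)
    assert rules.viability_min_pct == 40.0
    assert rules.xenograft_min_pct == 20.0
    bad = tmp_path / "bad.cfg"
    bad.write_text("nope = 1\n")
    with pytest.raises(ValueError, match="unknown rules key"):
        RulesConfig.from_file(bad)


def test_evidence_dir_round_trip(tmp_path):
    ev = _micro_evidence()
    write_evidence(ev, tmp_path / "ev")
    again = read_evidence(tmp_path / "ev")
    pd.testing.assert_frame_equal(
        again.ic50.sort_values(["drug", "cell_line"]).reset_index(drop=True),
        ev.ic50.sort_values(["drug", "cell_line"]).reset_index(drop=True),
    )
    assert again.ddi_severity("cmb_b", "cmb_a") == "major"
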