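"""Synthetic study generator with planted, verifiable ground truth.

Generates every input the pipeline consumes — a toy "generic"
metabolic network, a defined medium, bimodal expression for k tumor
subtype groups plus healthy-control samples, a drug catalog and
curated-evidence tables — with ground truth planted by construction:

* a growth-limiting nutrient whose exchange is forced at optimal
  growth (narrow-bounded in every subtype model), plus a
  subtype-specific nutrient route that forces a second narrow uptake
  only in subtype S1 (mirroring subtype-specific uptake signatures);
* essential genes: single genes gating the only route to a biomass
  precursor (pan-subtype), and per-subtype essentials where each
  subtype expresses a different one of two alternative routes;
* synergistic target pairs: one biomass precursor with two fully
  redundant routes, each gated by its own gene, so either knockout
  alone is free but the joint knockout is lethal (the cleanest
  Bliss-synergy construction) — one such pair is active in every
  group ("pan"), a second lacks its healthy bypass only in S1
  (subtype-specific);
* a healthy-control group whose expression activates bypass routes
  for all planted tumor targets, so planted combinations pass the
  control safety check;
* drug catalog entries per planted essential gene, a lethal single
  FDA drug, FDA/AntiBC/IAG pair drugs for the planted synergies,
  decoys with irrelevant or absent targets, and exclusion-flagged
  drugs; evidence tables with planted effective/ineffective/untested
  tier labels.

Everything is deterministic given the seed; ``verify_scenario``
re-derives each planted claim by direct LP computation on the
intended per-group sub-networks, independently of the extraction
pipeline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .context import ExpressionProfile, write_expression
from .drugs import Drug, DrugCatalog, classify_bliss, write_drug_catalog
from .gpr import GprRule
from .lp import LinearProblem, TAU_FEAS, fba, fva
from .network import (
    MediumDefinition,
    Metabolite,
    MetabolicNetwork,
    Reaction,
    apply_medium,
    write_medium,
    write_network,
)
from .ranking import EvidenceTable, write_evidence

__all__ = [
    "ScenarioParams",
    "GroundTruth",
    "SyntheticScenario",
    "GenerationError",
    "generate_scenario",
    "verify_scenario",
    "write_scenario",
    "intended_network",
]

CONTROL_GROUP = "CTRL"


class GenerationError(RuntimeError):
    """The requested parameters cannot produce a valid scenario."""


@dataclass(frozen=True)
class ScenarioParams:
    k_subtypes: int = 3
    n_samples: int = 8  # tumor samples per subtype
    n_control: int = 4  # healthy-control samples (mirrors a small control cohort)
    n_decoy_paths: int = 10
    expressed_log_mean: float = float(np.log(64.0))
    silent_log_mean: float = float(np.log(1.0))
    log_sigma: float = 0.5
    growth_nutrient_rate: float = 5.0  # uptake cap of the growth-limiting nutrient
    carbon_rate: float = 100.0
    side_nutrient_rate: float = 10.0
    seed: int = 1

    def __post_init__(self):
        if self.k_subtypes < 1:
            raise GenerationError("need at least one subtype")
        if self.n_samples < 1 or self.n_control < 1:
            raise GenerationError("need at least one sample per group")
        if not (2 <= self.n_decoy_paths <= 24):
            raise GenerationError("n_decoy_paths must be in [2, 24]")
        if self.growth_nutrient_rate <= 0 or self.carbon_rate <= 0:
            raise GenerationError("nutrient rates must be positive")


@dataclass
class GroundTruth:
    """Planted facts, keyed by subtype label where subtype-dependent."""

    essential_genes: Dict[str, List[str]]
    narrow_exchanges: Dict[str, List[str]]
    single_drug_hits: Dict[str, List[str]]
    lethal_single_drugs: List[str]
    pan_synergy_pairs: List[Tuple[str, str]]
    specific_synergy_pairs: Dict[str, List[Tuple[str, str]]]  # subtype -> pairs
    safe_pairs: List[Tuple[str, str]]  # pairs that must pass the control check
    excluded_drugs: List[str]
    tier_labels: Dict[str, Dict[str, str]]  # drug -> tier -> call
    active_genes: Dict[str, List[str]]  # group (incl CTRL) -> expressed gene set

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pan_synergy_pairs"] = [list(p) for p in self.pan_synergy_pairs]
        d["specific_synergy_pairs"] = {
            k: [list(p) for p in v] for k, v in self.specific_synergy_pairs.items()
        }
        d["safe_pairs"] = [list(p) for p in self.safe_pairs]
        return d


@dataclass
class SyntheticScenario:
    params: ScenarioParams
    network: MetabolicNetwork
    medium: MediumDefinition
    profile: ExpressionProfile
    catalog: DrugCatalog
    evidence: EvidenceTable
    ground_truth: GroundTruth

    @property
    def subtypes(self) -> List[str]:
        return [f"S{i + 1}" for i in range(self.params.k_subtypes)]


# ---------------------------------------------------------------------------
# network construction


def _build_generic_network(params: ScenarioParams, rng: np.random.Generator):
    """Toy generic reconstruction plus per-group active-gene sets."""
    CAP = 1000.0
    mets: List[Metabolite] = []
    rxns: List[Reaction] = []

    def met(mid: str):
        comp = mid.rsplit("_", 1)[-1]
        mets.append(Metabolite(mid, comp))

    def rxn(rid, stoich, lb, ub, gpr=""):
        rxns.append(Reaction(rid, stoich, lb, ub, GprRule(gpr)))

    for m in ["carbon_e", "carbon_c", "atp_c", "q_e", "q_c", "n2_e", "n2_c",
              "w_e", "w_c", "waste_e",
              "p1_c", "p2_c", "p3_c", "p4_c"]:
        met(m)

    # carbon backbone and energy
    rxn("EX_carbon", {"carbon_e": -1}, -CAP, CAP)
    rxn("T_carbon", {"carbon_e": -1, "carbon_c": 1}, 0, CAP, "tC")
    rxn("R_atp", {"carbon_c": -1, "atp_c": 1}, 0, CAP, "gATP")
    rxn("DM_atp", {"atp_c": -1}, 0, CAP)
    # growth-limiting nutrient q: sole source of the q biomass precursor
    rxn("EX_q", {"q_e": -1}, -CAP, CAP)
    rxn("T_q", {"q_e": -1, "q_c": 1}, 0, CAP, "tQ")
    # precursor 1: single gated route (pan-subtype essential gene gE)
    rxn("R_p1", {"carbon_c": -1, "p1_c": 1}, 0, CAP, "gE")
    # precursor 2: subtype-split routes (nutrient route in S1, carbon route elsewhere)
    rxn("EX_n2", {"n2_e": -1}, -CAP, CAP)
    rxn("T_n2", {"n2_e": -1, "n2_c": 1}, 0, CAP, "tN2")
    rxn("R2a", {"n2_c": -1, "p2_c": 1}, 0, CAP, "gA")
    rxn("R2b", {"carbon_c": -1, "p2_c": 1}, 0, CAP, "gB")
    # precursor 3: redundant routes -> pan synergy target pair (gSa, gSb);
    # bypass gSc active only in healthy control
    rxn("R3a", {"carbon_c": -1, "p3_c": 1}, 0, CAP, "gSa")
    rxn("R3b", {"carbon_c": -1, "p3_c": 1}, 0, CAP, "gSb")
    rxn("R3c", {"carbon_c": -1, "p3_c": 1}, 0, CAP, "gSc")
    # precursor 4: redundant routes -> S1-specific synergy (gTa, gTb);
    # bypass gTc active in the other subtypes and the control
    rxn("R4a", {"carbon_c": -1, "p4_c": 1}, 0, CAP, "gTa")
    rxn("R4b", {"carbon_c": -1, "p4_c": 1}, 0, CAP, "gTb")
    rxn("R4c", {"carbon_c": -1, "p4_c": 1}, 0, CAP, "gTc")
    # biomass: drains one unit of each precursor, q and ATP per unit growth
    rxn("biomass",
        {"p1_c": -1, "p2_c": -1, "p3_c": -1, "p4_c": -1, "q_c": -1, "atp_c": -1},
        0, CAP)
    # free side nutrient w: uptake and excretion unlinked to growth
    rxn("EX_w", {"w_e": -1}, -CAP, CAP)
    rxn("T_w", {"w_e": -1, "w_c": 1}, 0, CAP, "tW")
    rxn("R_w", {"w_c": -1, "waste_e": 1}, 0, CAP, "gW")
    rxn("EX_waste", {"waste_e": -1}, 0, CAP)

    # decoy pathways: uptake -> gated conversion -> excretion
    groups = [f"S{i + 1}" for i in range(params.k_subtypes)] + [CONTROL_GROUP]
    decoy_activity: Dict[str, Set[str]] = {g: set() for g in groups}
    decoy_genes: List[str] = []
    for i in range(1, params.n_decoy_paths + 1):
        met(f"d{i}_e")
        met(f"d{i}_c")
        met(f"dw{i}_e")
        shape = rng.integers(0, 3)
        if shape == 0:
            genes = [f"gd{i}a"]
            gpr = genes[0]
        elif shape == 1:
            genes = [f"gd{i}a", f"gd{i}b"]
            gpr = f"{genes[0]} or {genes[1]}"
        else:
            genes = [f"gd{i}a", f"gd{i}b"]
            gpr = f"{genes[0]} and {genes[1]}"
        decoy_genes.extend(genes)
        rxn(f"EX_d{i}", {f"d{i}_e": -1}, -CAP, CAP)
        rxn(f"T_d{i}", {f"d{i}_e": -1, f"d{i}_c": 1}, 0, CAP, f"td{i}")
        decoy_genes.append(f"td{i}")
        rxn(f"R_d{i}", {f"d{i}_c": -1, f"dw{i}_e": 1}, 0, CAP, gpr)
        rxn(f"EX_dw{i}", {f"dw{i}_e": -1}, 0, CAP)
        # each decoy pathway is active in a random non-empty subset of groups
        active_in = [g for g in groups if rng.random() < 0.6]
        if not active_in:
            active_in = [groups[int(rng.integers(0, len(groups)))]]
        for g in active_in:
            decoy_activity[g].update(genes + [f"td{i}"])

    network = MetabolicNetwork(mets, rxns, "biomass", atp_demand_id="DM_atp",
                               id="generic_toy")
    if not (30 <= len(network.reactions) <= 120):
        raise GenerationError(
            f"generated network has {len(network.reactions)} reactions, outside [30, 120]"
        )

    housekeeping = {"tC", "gATP", "tQ", "gE", "tW", "gW", "ghost1", "ghost2"}
    active: Dict[str, Set[str]] = {}
    for g in groups:
        genes = set(housekeeping) | {"gSa", "gSb", "gTa", "gTb"} | decoy_activity[g]
        if g == "S1":
            genes |= {"tN2", "gA"}
        else:  # other subtypes and the control use the carbon route for p2
            genes |= {"gB"}
        if g != "S1":
            genes |= {"gTc"}  # healthy bypass of the S1-specific target pair
        if g == CONTROL_GROUP:
            genes |= {"gSc"}  # healthy bypass of the pan target pair
        active[g] = genes

    all_genes = sorted(network.genes | {"ghost1", "ghost2"})
    return network, active, all_genes


def _default_medium(params: ScenarioParams, network: MetabolicNetwork) -> MediumDefinition:
    rates = {
        "carbon_e": params.carbon_rate,
        "q_e": params.growth_nutrient_rate,
        "n2_e": params.side_nutrient_rate,
        "w_e": params.side_nutrient_rate,
    }
    for rid in network.exchange_ids:
        met = network.exchange_metabolite(rid)
        if met.startswith("d") and met.endswith("_e") and not met.startswith("dw"):
            rates[met] = params.side_nutrient_rate
    return MediumDefinition(rates)


def intended_network(
    scenario: "SyntheticScenario", group: str, apply_med: bool = True
) -> MetabolicNetwork:
    """The sub-network a group's expression is designed to support:
    reactions whose GPR evaluates false once all non-active genes are
    deleted are closed.  This is the generator's own definition of a
    group model, independent of the extraction pipeline."""
    active = set(scenario.ground_truth.active_genes[group])
    silent = scenario.network.genes - active
    closed = {}
    for rxn in scenario.network.reactions.values():
        if not rxn.gpr.is_empty and not rxn.gpr.evaluate(silent):
            closed[rxn.id] = (0.0, 0.0)
    net = scenario.network.with_bounds(closed)
    net.id = f"intended_{group}"
    if apply_med:
        net = apply_medium(net, scenario.medium)
        net.id = f"intended_{group}"
    return net


# ---------------------------------------------------------------------------
# expression


def _sample_expression(
    params: ScenarioParams,
    active: Dict[str, Set[str]],
    all_genes: List[str],
    rng: np.random.Generator,
) -> ExpressionProfile:
    groups = [f"S{i + 1}" for i in range(params.k_subtypes)]
    columns, labels = {}, {}
    for g in groups + [CONTROL_GROUP]:
        n = params.n_samples if g != CONTROL_GROUP else params.n_control
        for j in range(1, n + 1):
            sample = f"{g}_{j:02d}"
            mu = np.where(
                [gene in active[g] for gene in all_genes],
                params.expressed_log_mean,
                params.silent_log_mean,
            )
            columns[sample] = np.exp(rng.normal(mu, params.log_sigma))
            labels[sample] = g
    values = pd.DataFrame(columns, index=all_genes)
    return ExpressionProfile(values, labels)


# ---------------------------------------------------------------------------
# drugs and evidence


def _build_catalog(params: ScenarioParams) -> Tuple[DrugCatalog, Dict[str, Tuple[str, str]]]:
    drugs = [
        # lethal single: targets the pan-essential precursor gene
        Drug("drug_lethal", "Lethagene", frozenset({"gE"}), frozenset({"FDA"})),
        # one drug per subtype-planted essential gene
        Drug("drug_gA", "Altherin", frozenset({"gA"}), frozenset({"FDA"})),
        Drug("drug_gB", "Bortherin", frozenset({"gB"}), frozenset({"FDA"})),
        # pair drugs for the planted pan synergy
        Drug("comboA_fda", "Panergin", frozenset({"gSa"}), frozenset({"FDA"})),
        Drug("comboA_iag", "Panergol", frozenset({"gSb"}), frozenset({"IAG"})),
        # pair drugs for the S1-specific synergy
        Drug("comboB_fda", "Subtypin", frozenset({"gTa"}), frozenset({"FDA"})),
        Drug("comboB_iag", "Subtypol", frozenset({"gTb"}), frozenset({"AntiBC"})),
        # reference approved anti-brain chemotherapy (sets the potency bar)
        Drug("antibc_ref", "Referan", frozenset({"gW"}), frozenset({"AntiBC"})),
        # decoys: absent target, irrelevant target
        Drug("dec_absent", "Nullin", frozenset({"gX_absent"}), frozenset({"FDA"})),
        Drug("dec_inert", "Inertin", frozenset({"tW"}), frozenset({"FDA"})),
        # exclusion-flagged drugs
        Drug("drug_cof", "Cofactin", frozenset({"gSa"}), frozenset({"FDA"}),
             cofactor_of_target=True),
        Drug("drug_prolif", "Prolifin", frozenset({"gW"}), frozenset({"FDA"}),
             induces_proliferation=True),
    ]
    combos = {
        "comboA_fda+comboA_iag": ("comboA_fda", "comboA_iag"),
        "comboB_fda+comboB_iag": ("comboB_fda", "comboB_iag"),
    }
    return DrugCatalog({d.id: d for d in drugs}), combos


def _build_evidence() -> Tuple[EvidenceTable, Dict[str, Dict[str, str]]]:
    ic50 = pd.DataFrame(
        [
            # median over cell lines: {1, 2, 10} -> 2 µM (potent)
            ("comboA_fda", "L1", 1.0), ("comboA_fda", "L2", 2.0), ("comboA_fda", "L3", 10.0),
            # duplicates on one line average first: {mean(2,4)=3, 10} -> 6.5 µM
            ("drug_lethal", "L1", 2.0), ("drug_lethal", "L1", 4.0), ("drug_lethal", "L2", 10.0),
            # reference AntiBC potency: {4, 8} -> 6 µM
            ("antibc_ref", "L1", 4.0), ("antibc_ref", "L2", 8.0),
            ("comboB_iag", "L1", 20.0),
        ],
        columns=["drug", "cell_line", "ic50_um"],
    )
    viability = pd.DataFrame(
        [("comboB_fda", 60.0), ("comboB_fda", 55.0), ("comboB_iag", 10.0)],
        columns=["drug", "reduction_pct"],
    )
    pk = pd.DataFrame(
        [
            ("comboA_fda", -0.5, True, "none"),
            ("drug_lethal", -1.2, False, "substrate"),
            ("comboA_iag", 0.1, True, "inhibitor"),
            ("comboB_fda", -0.8, True, "unknown"),
            ("antibc_ref", -1.0, True, "substrate"),
        ],
        columns=["drug", "logbb", "bbb_permeable", "abc_transporter"],
    )
    xenograft = pd.DataFrame(
        [
            ("comboA_fda", 30.0),             # median 30 >= 25 -> effective
            ("comboA_iag", 25.0),             # boundary: exactly 25 -> effective
            ("comboB_fda", 10.0), ("comboB_fda", 20.0),  # median 15 -> ineffective
            ("antibc_ref", 28.0),
        ],
        columns=["drug", "growth_reduction_pct"],
    )
    clinical = pd.DataFrame(
        [
            ("drug_lethal", "II", 2, "improved"),
            ("comboA_fda", "I/II", 2, "improved"),
            ("dec_inert", "II", 1, "improved"),   # single-arm -> ineffective
            ("comboB_iag", "II", 2, "worse"),
            ("antibc_ref", "II", 2, "no_change"),
        ],
        columns=["drug", "phase", "arms", "outcome"],
    )
    ddi = pd.DataFrame(
        [
            ("comboA_fda", "comboA_iag", "minor"),
            ("comboB_fda", "comboB_iag", "none"),
            ("comboA_fda", "comboB_iag", "major"),
        ],
        columns=["drug_a", "drug_b", "severity"],
    )
    exclusions = pd.DataFrame(
        [("drug_cof", 1, 0), ("drug_prolif", 0, 1)],
        columns=["drug", "cofactor_of_target", "induces_proliferation"],
    )
    evidence = EvidenceTable(ic50, viability, pk, xenograft, clinical, ddi, exclusions)
    tier_labels = {
        "comboA_fda": {"in_vitro": "effective", "xenograft": "effective",
                       "clinical": "effective"},
        "comboA_iag": {"in_vitro": "untested", "xenograft": "effective",
                       "clinical": "untested"},
        "comboB_fda": {"in_vitro": "effective", "xenograft": "ineffective",
                       "clinical": "untested"},
        "comboB_iag": {"in_vitro": "ineffective", "xenograft": "untested",
                       "clinical": "ineffective"},
        # potency 6.5 µM beats the AntiBC reference median (13 µM)
        "drug_lethal": {"in_vitro": "effective", "xenograft": "untested",
                        "clinical": "effective"},
        "antibc_ref": {"in_vitro": "effective", "xenograft": "effective",
                       "clinical": "ineffective"},
        "dec_inert": {"in_vitro": "untested", "xenograft": "untested",
                      "clinical": "ineffective"},
    }
    return evidence, tier_labels


# ---------------------------------------------------------------------------
# ground truth bookkeeping


def _plant_ground_truth(
    params: ScenarioParams,
    active: Dict[str, Set[str]],
    tier_labels: Dict[str, Dict[str, str]],
) -> GroundTruth:
    subtypes = [f"S{i + 1}" for i in range(params.k_subtypes)]
    essential, narrow, hits = {}, {}, {}
    for g in subtypes:
        if g == "S1":
            essential[g] = sorted({"tC", "gATP", "tQ", "gE", "tN2", "gA"})
            narrow[g] = ["EX_n2", "EX_q"]
            hits[g] = sorted({"drug_lethal", "drug_gA"})
        else:
            essential[g] = sorted({"tC", "gATP", "tQ", "gE", "gB"})
            narrow[g] = ["EX_q"]
            hits[g] = sorted({"drug_lethal", "drug_gB"})
    pan_pair = ("comboA_fda", "comboA_iag")
    specific_pair = ("comboB_fda", "comboB_iag")
    specific = {g: [] for g in subtypes}
    if params.k_subtypes > 1:
        specific["S1"] = [specific_pair]
        pan_pairs = [pan_pair]
    else:
        # degenerate single-subtype case: both pairs hit the only model
        pan_pairs = [pan_pair, specific_pair]
    return GroundTruth(
        essential_genes=essential,
        narrow_exchanges=narrow,
        single_drug_hits=hits,
        lethal_single_drugs=sorted({"drug_lethal", "drug_gA", "drug_gB"}),
        pan_synergy_pairs=pan_pairs,
        specific_synergy_pairs=specific,
        safe_pairs=[pan_pair, specific_pair],
        excluded_drugs=["drug_cof", "drug_prolif"],
        tier_labels=tier_labels,
        active_genes={g: sorted(s) for g, s in active.items()},
    )


# ---------------------------------------------------------------------------
# public API


def generate_scenario(params: Optional[ScenarioParams] = None, seed: Optional[int] = None) -> SyntheticScenario:
    """Build a complete scenario; raises :class:`GenerationError` if the
    construction cannot satisfy growth reachability for every group."""
    if params is None:
        params = ScenarioParams(seed=seed if seed is not None else 1)
    elif seed is not None:
        params = dataclasses.replace(params, seed=seed)
    rng = np.random.default_rng(params.seed)

    network, active, all_genes = _build_generic_network(params, rng)
    medium = _default_medium(params, network)
    profile = _sample_expression(params, active, all_genes, rng)
    catalog, _combos = _build_catalog(params)
    evidence, tier_labels = _build_evidence()
    truth = _plant_ground_truth(params, active, tier_labels)
    scenario = SyntheticScenario(params, network, medium, profile, catalog, evidence, truth)

    # reachability self-check: every group's intended sub-network must grow
    for group in scenario.subtypes + [CONTROL_GROUP]:
        net = intended_network(scenario, group)
        sol = fba(net)
        if not sol.optimal or sol.objective_value <= TAU_FEAS:
            raise GenerationError(
                f"intended sub-network of group {group!r} cannot produce biomass"
            )
    return scenario


def _brute_force_essentials(net: MetabolicNetwork) -> Set[str]:
    problem = LinearProblem(net)
    z_wt = fba(net, problem=problem).objective_value
    out = set()
    from .essentiality import knockout_growth

    for gene in sorted(net.genes):
        if knockout_growth(net, {gene}, problem=problem) / z_wt <= 0.5:
            out.add(gene)
    return out


def _brute_force_narrow(net: MetabolicNetwork, cutoff: float = 0.10) -> Set[str]:
    problem = LinearProblem(net)
    exchanges = sorted(net.exchange_ids)
    at_opt = fva(net, exchanges, fraction=1.0, problem=problem)
    free = fva(net, exchanges, fraction=None, problem=problem)
    out = set()
    for rid in exchanges:
        vmin, vmax = at_opt.range_of(rid)
        amin, amax = free.range_of(rid)
        if abs(vmin) <= 1e-6 and abs(vmax) <= 1e-6:
            continue  # blocked, not growth-critical
        r_max = amax - amin
        rel = (vmax - vmin) / r_max if r_max > 1e-9 else 0.0
        if rel <= cutoff:
            out.add(rid)
    return out


def _pair_effects(net: MetabolicNetwork, catalog: DrugCatalog,
                  pair: Tuple[str, str]) -> Tuple[float, float, float]:
    from .essentiality import knockout_growth

    problem = LinearProblem(net)
    z_wt = fba(net, problem=problem).objective_value
    genes = net.genes

    def eff(targets: Set[str]) -> float:
        mapped = targets & genes
        if not mapped:
            return 0.0
        return 1.0 - min(max(knockout_growth(net, mapped, problem=problem) / z_wt, 0.0), 1.0)

    a, b = (catalog.drugs[pair[0]], catalog.drugs[pair[1]])
    return eff(set(a.targets)), eff(set(b.targets)), eff(set(a.targets) | set(b.targets))


def verify_scenario(scenario: SyntheticScenario, cutoff: float = 0.5) -> List[str]:
    """Re-derive every planted claim by brute force on the intended
    group sub-networks; returns a list of mismatch descriptions (empty
    when the scenario is internally consistent)."""
    truth = scenario.ground_truth
    mismatches: List[str] = []
    nets = {g: intended_network(scenario, g) for g in scenario.subtypes + [CONTROL_GROUP]}

    for g in scenario.subtypes:
        net = nets[g]
        found = _brute_force_essentials(net)
        planted = set(truth.essential_genes[g])
        if found != planted:
            mismatches.append(
                f"essential genes in {g}: planted {sorted(planted)} != derived {sorted(found)}"
            )
        narrow = _brute_force_narrow(net)
        if narrow != set(truth.narrow_exchanges[g]):
            mismatches.append(
                f"narrow exchanges in {g}: planted {truth.narrow_exchanges[g]} "
                f"!= derived {sorted(narrow)}"
            )
        # single drug hits
        from .essentiality import knockout_growth

        problem = LinearProblem(net)
        z_wt = fba(net, problem=problem).objective_value
        found_hits = set()
        for drug in scenario.catalog:
            mapped = set(drug.targets) & net.genes
            if not mapped:
                continue
            eff = 1.0 - min(max(knockout_growth(net, mapped, problem=problem) / z_wt, 0.0), 1.0)
            if eff >= cutoff:
                found_hits.add(drug.id)
        # exclusion-flagged decoys share planted targets; hits are compared
        # on the planted drug list only
        planted_hits = set(truth.single_drug_hits[g])
        extra = {d for d in found_hits - planted_hits
                 if d not in {"drug_cof", "drug_prolif"}}
        if extra or (planted_hits - found_hits):
            mismatches.append(
                f"single-drug hits in {g}: planted {sorted(planted_hits)} != derived "
                f"{sorted(found_hits)}"
            )

    # synergy pattern
    all_pairs = set(truth.pan_synergy_pairs)
    for pairs in truth.specific_synergy_pairs.values():
        all_pairs |= set(pairs)
    for pair in sorted(all_pairs):
        hit_in = []
        for g in scenario.subtypes:
            e_a, e_b, e_ab = _pair_effects(nets[g], scenario.catalog, pair)
            if e_ab >= cutoff:
                hit_in.append(g)
                if classify_bliss(e_a, e_b, e_ab) != "synergistic":
                    mismatches.append(f"pair {pair} in {g} is not synergistic "
                                      f"(E_A={e_a}, E_B={e_b}, E_AB={e_ab})")
        expected_pan = pair in set(truth.pan_synergy_pairs)
        expected_in = set(scenario.subtypes) if expected_pan else {
            g for g, pairs in truth.specific_synergy_pairs.items() if pair in set(pairs)
        }
        if set(hit_in) != expected_in:
            mismatches.append(
                f"pair {pair} hits {hit_in}, planted for {sorted(expected_in)}"
            )

    # planted evidence-tier labels
    from .ranking import classify_tiers, compute_potency

    potency = compute_potency(scenario.evidence)
    antibc = [d.id for d in scenario.catalog.of_category("AntiBC")]
    ref = potency[potency.index.isin(antibc)]
    reference_potency = float(ref.median()) if len(ref) else None
    for drug, planted_tiers in truth.tier_labels.items():
        derived = classify_tiers(drug, scenario.evidence,
                                 reference_potency=reference_potency)
        if derived != planted_tiers:
            mismatches.append(
                f"tier labels for {drug}: planted {planted_tiers} != derived {derived}"
            )

    # safety in the control network
    for pair in truth.safe_pairs:
        a, b = scenario.catalog.drugs[pair[0]], scenario.catalog.drugs[pair[1]]
        union = set(a.targets) | set(b.targets)
        ctrl = nets[CONTROL_GROUP]
        from .essentiality import knockout_growth

        for objective in (ctrl.objective_id, ctrl.atp_demand_id):
            problem = LinearProblem(ctrl)
            z_wt = fba(ctrl, objective=objective, problem=problem).objective_value
            from .essentiality import reactions_disabled_by

            closed = {r: (0.0, 0.0) for r in reactions_disabled_by(ctrl, union & ctrl.genes)}
            z_ko = fba(ctrl, objective=objective, extra_bounds=closed, problem=problem)
            ratio = (z_ko.objective_value or 0.0) / z_wt if z_wt else 0.0
            if ratio < 0.95:
                mismatches.append(
                    f"pair {pair} is unsafe in the control network "
                    f"({objective} ratio {ratio:.3f})"
                )
    return mismatches


def write_scenario(scenario: SyntheticScenario, directory) -> Dict[str, str]:
    """Write every input file the pipeline reads; returns the path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "network_json": str(directory / "generic_model.json"),
        "network_sbml": str(directory / "generic_model.xml"),
        "expression": str(directory / "expression.tsv"),
        "subtypes": str(directory / "subtypes.csv"),
        "medium": str(directory / "medium.csv"),
        "catalog": str(directory / "drug_catalog.tsv"),
        "evidence_dir": str(directory / "evidence"),
        "ground_truth": str(directory / "ground_truth.json"),
    }
    write_network(scenario.network, paths["network_json"], "json")
    write_network(scenario.network, paths["network_sbml"], "sbml-fbc")
    write_expression(scenario.profile, paths["expression"], paths["subtypes"])
    write_medium(scenario.medium, paths["medium"])
    write_drug_catalog(scenario.catalog, paths["catalog"])
    write_evidence(scenario.evidence, paths["evidence_dir"])
    Path(paths["ground_truth"]).write_text(
        json.dumps(scenario.ground_truth.to_dict(), indent=1, sort_keys=True) + "\n"
    )
    return paths
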