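"""Shared fixtures: hand toy networks, a randomized-network factory for
oracle comparisons, and the default synthetic scenario."""

from __future__ import annotations

import numpy as np
import pytest

from gliomagem.gpr import GprRule
from gliomagem.network import MediumDefinition, Metabolite, MetabolicNetwork, Reaction


def make_chain_network() -> MetabolicNetwork:
    """source(ub 10) -> A -> (ub 5) -> B -> sink(ub 100): bottleneck 5."""
    mets = [Metabolite("src_e", "e"), Metabolite("A_c", "c"),
            Metabolite("B_c", "c"), Metabolite("sink_e", "e")]
    rxns = [
        Reaction("EX_src", {"src_e": -1}, -10, 1000),
        Reaction("T_src", {"src_e": -1, "A_c": 1}, 0, 1000, GprRule("gT")),
        Reaction("R_AB", {"A_c": -1, "B_c": 1}, 0, 5),
        Reaction("biomass", {"B_c": -1, "sink_e": 1}, 0, 100),
        Reaction("EX_sink", {"sink_e": -1}, 0, 1000),
    ]
    return MetabolicNetwork(mets, rxns, "biomass")


def make_parallel_network(branch_ub: float = 5.0) -> MetabolicNetwork:
    """Two parallel branches, each capacity ``branch_ub``, feeding a
    biomass that can use up to their sum; each branch gated by one gene."""
    mets = [Metabolite("s_e", "e"), Metabolite("A_c", "c"), Metabolite("B_c", "c"),
            Metabolite("out_e", "e")]
    rxns = [
        Reaction("EX_s", {"s_e": -1}, -1000, 1000),
        Reaction("T_s", {"s_e": -1, "A_c": 1}, 0, 1000),
        Reaction("branch1", {"A_c": -1, "B_c": 1}, 0, branch_ub, GprRule("g1")),
        Reaction("branch2", {"A_c": -1, "B_c": 1}, 0, branch_ub, GprRule("g2")),
        Reaction("biomass", {"B_c": -1, "out_e": 1}, 0, 2 * branch_ub),
        Reaction("EX_out", {"out_e": -1}, 0, 1000),
    ]
    return MetabolicNetwork(mets, rxns, "biomass")


def make_random_network(rng: np.random.Generator, n_internal: int = 8,
                        n_mets: int = 5) -> MetabolicNetwork:
    """Small random network with exchanges on a subset of metabolites.

    Structure is arbitrary (dead ends and blocked cycles allowed) —
    these networks exercise solver agreement, not biology.
    """
    mets = [Metabolite(f"m{i}_c", "c") for i in range(n_mets)]
    rxns = []
    n_exch = max(2, n_mets // 2)
    exch_mets = rng.choice(n_mets, size=n_exch, replace=False)
    for k, i in enumerate(sorted(exch_mets)):
        lb = float(rng.choice([-10.0, -5.0, 0.0]))
        rxns.append(Reaction(f"EX_{k}", {f"m{i}_c": -1}, lb, float(rng.choice([5.0, 10.0]))))
    genes = [f"g{i}" for i in range(4)]
    for j in range(n_internal):
        i_a, i_b = rng.choice(n_mets, size=2, replace=False)
        coef_b = float(rng.choice([1.0, 2.0]))
        lb = float(rng.choice([0.0, 0.0, -8.0]))
        gpr = ""
        roll = rng.random()
        if roll < 0.4:
            gpr = str(rng.choice(genes))
        elif roll < 0.6:
            g1, g2 = rng.choice(genes, size=2, replace=False)
            gpr = f"{g1} {'and' if rng.random() < 0.5 else 'or'} {g2}"
        rxns.append(
            Reaction(f"R{j}", {f"m{i_a}_c": -1, f"m{i_b}_c": coef_b},
                     lb, float(rng.choice([4.0, 8.0, 12.0])), GprRule(gpr))
        )
    objective = "EX_0"
    return MetabolicNetwork(mets, rxns, objective)


def make_two_route_toy(rng: np.random.Generator):
    """Planted extraction toy: biomass reachable via a short route and a
    strictly longer one, plus dead decoy reactions.  The unique minimal
    flux-consistent superset of {biomass} is the short route.

    Returns (network, core, minimal_set).
    """
    long_len = int(rng.integers(2, 4))  # 2-3 internal steps vs 1 on the short route
    mets = [Metabolite("in_e", "e"), Metabolite("A_c", "c"), Metabolite("P_c", "c"),
            Metabolite("out_e", "e")]
    rxns = [
        Reaction("EX_in", {"in_e": -1}, -10, 1000),
        Reaction("T_in", {"in_e": -1, "A_c": 1}, 0, 1000),
        Reaction("short", {"A_c": -1, "P_c": 1}, 0, 1000),
        Reaction("biomass", {"P_c": -1, "out_e": 1}, 0, 1000),
        Reaction("EX_out", {"out_e": -1}, 0, 1000),
    ]
    prev = "A_c"
    for i in range(long_len):
        nxt = "P_c" if i == long_len - 1 else f"L{i}_c"
        if nxt != "P_c":
            mets.append(Metabolite(nxt, "c"))
        rxns.append(Reaction(f"long{i}", {prev: -1, nxt: 1}, 0, 1000))
        prev = nxt
    # dead decoys: produce a metabolite nothing consumes (inconsistent,
    # assumed pre-filtered before extraction; here they are closed)
    for d in range(int(rng.integers(1, 3))):
        mets.append(Metabolite(f"D{d}_c", "c"))
        rxns.append(Reaction(f"dead{d}", {"A_c": -1, f"D{d}_c": 1}, 0, 0))
    net = MetabolicNetwork(mets, rxns, "biomass")
    core = {"biomass"}
    minimal = {"EX_in", "T_in", "short", "biomass", "EX_out"}
    return net, core, minimal


def exhaustive_minimal_superset(network: MetabolicNetwork, core, epsilon=1e-4):
    """Oracle: smallest reaction set A ⊇ core whose induced sub-network
    lets every member carry |v| ≥ ε; subsets enumerated by size."""
    import itertools

    from gliomagem.lp import LinearProblem

    core = set(core)
    others = sorted(set(network.reactions) - core)

    def self_consistent(candidate):
        try:
            sub = network.subnetwork(candidate)
        except Exception:
            return False
        problem = LinearProblem(sub)
        for rid in candidate:
            hi = problem.optimize(rid, "max")
            lo = problem.optimize(rid, "min")
            ok = (hi.optimal and hi.objective_value >= epsilon) or (
                lo.optimal and lo.objective_value <= -epsilon
            )
            if not ok:
                return False
        return True

    for size in range(len(others) + 1):
        for extra in itertools.combinations(others, size):
            candidate = core | set(extra)
            if self_consistent(candidate):
                return candidate
    raise AssertionError("no consistent superset exists")


def to_cobra(network: MetabolicNetwork):
    """Translate to a COBRApy model (GLPK) — the independent solver."""
    import cobra

    model = cobra.Model(network.id)
    model.solver = "glpk"
    cmets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment or "c")
             for m in network.metabolites.values()}
    for rxn in network.reactions.values():
        r = cobra.Reaction(rxn.id, lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound)
        model.add_reactions([r])
        r.add_metabolites({cmets[m]: c for m, c in rxn.stoichiometry.items()})
        if not rxn.gpr.is_empty:
            r.gene_reaction_rule = rxn.gpr.to_string()
    model.objective = network.objective_id
    return model


@pytest.fixture
def chain_network() -> MetabolicNetwork:
    return make_chain_network()


@pytest.fixture
def parallel_network() -> MetabolicNetwork:
    return make_parallel_network()


@pytest.fixture(scope="session")
def default_scenario():
    from gliomagem.synthetic import generate_scenario

    return generate_scenario(seed=1)


@pytest.fixture(scope="session")
def default_pipeline_results(default_scenario, tmp_path_factory):
    """One full pipeline run on the default scenario, shared by tests."""
    from gliomagem.pipeline import PipelineConfig, run_pipeline
    from gliomagem.synthetic import write_scenario

    root = tmp_path_factory.mktemp("default_run")
    paths = write_scenario(default_scenario, root / "inputs")
    cfg = PipelineConfig(
        network=paths["network_json"],
        expression=paths["expression"],
        subtypes=paths["subtypes"],
        medium=paths["medium"],
        drug_catalog=paths["catalog"],
        evidence_dir=paths["evidence_dir"],
        seed=1,
        outdir=str(root / "out"),
    )
    return run_pipeline(cfg)
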