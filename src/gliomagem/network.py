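"""Constraint-based network data model and readers/writers.

A :class:`MetabolicNetwork` holds stoichiometry, flux bounds
(mmol·gDW⁻¹·h⁻¹), GPR rules, a biomass objective and optionally an
ATP-demand reaction.  Exchange reactions follow the SBML-FBC community
convention ``met_e →``: positive flux is release to the environment,
uptake is negative flux, so a medium with maximum uptake rate ``u``
sets the exchange lower bound to ``−u``.

Two serialisations are supported: a JSON dialect (canonical, schema
documented in the README) and SBML Level 3 with the FBC package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional

from .gpr import GprRule

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "MediumDefinition",
    "NetworkError",
    "read_network",
    "write_network",
    "read_medium",
    "write_medium",
    "apply_medium",
]


class NetworkError(ValueError):
    """Malformed network file or violated network invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str = ""
    name: str = ""


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: GprRule = field(default_factory=GprRule)
    name: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def genes(self) -> frozenset:
        return self.gpr.genes


class MetabolicNetwork:
    """Stoichiometric model: metabolites, bounded reactions, GPRs, objective."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        objective_id: str,
        atp_demand_id: Optional[str] = None,
        id: str = "model",
    ):
        self.id = id
        self.metabolites: Dict[str, Metabolite] = {m.id: m for m in metabolites}
        self.reactions: Dict[str, Reaction] = {r.id: r for r in reactions}
        self.objective_id = objective_id
        self.atp_demand_id = atp_demand_id
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met, coef in rxn.stoichiometry.items():
                if met not in self.metabolites:
                    raise NetworkError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met!r}"
                    )
                if coef == 0:
                    raise NetworkError(
                        f"reaction {rxn.id!r} has a zero stoichiometric entry for {met!r}"
                    )
            if rxn.lower_bound > rxn.upper_bound:
                raise NetworkError(
                    f"reaction {rxn.id!r} has lb > ub "
                    f"({rxn.lower_bound} > {rxn.upper_bound})"
                )
        if self.objective_id not in self.reactions:
            raise NetworkError(
                f"objective reaction {self.objective_id!r} is not in the network"
            )
        if self.atp_demand_id is not None and self.atp_demand_id not in self.reactions:
            raise NetworkError(
                f"ATP-demand reaction {self.atp_demand_id!r} is not in the network"
            )

    # -- views -----------------------------------------------------------

    @property
    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    @property
    def exchange_ids(self) -> List[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def exchange_metabolite(self, rxn_id: str) -> str:
        rxn = self.reactions[rxn_id]
        if not rxn.is_exchange:
            raise NetworkError(f"{rxn_id!r} is not an exchange reaction")
        return next(iter(rxn.stoichiometry))

    @property
    def genes(self) -> frozenset:
        out = set()
        for rxn in self.reactions.values():
            out |= rxn.gpr.genes
        return frozenset(out)

    # -- edits (always copy-on-write) -------------------------------------

    def copy(self, id: Optional[str] = None) -> "MetabolicNetwork":
        return MetabolicNetwork(
            [replace(m) for m in self.metabolites.values()],
            [replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions.values()],
            self.objective_id,
            self.atp_demand_id,
            id=id if id is not None else self.id,
        )

    def with_bounds(self, bounds: Dict[str, tuple]) -> "MetabolicNetwork":
        """New network with (lb, ub) replaced for the listed reactions."""
        new = self.copy()
        for rid, (lb, ub) in bounds.items():
            rxn = new.reactions[rid]
            new.reactions[rid] = replace(rxn, lower_bound=lb, upper_bound=ub)
        new.validate()
        return new

    def subnetwork(self, reaction_ids: Iterable[str], id: Optional[str] = None) -> "MetabolicNetwork":
        """Induced sub-network keeping only the listed reactions (and their
        metabolites); the objective and ATP demand must survive."""
        keep = set(reaction_ids)
        missing = keep - set(self.reactions)
        if missing:
            raise NetworkError(f"unknown reactions in subnetwork request: {sorted(missing)}")
        rxns = [self.reactions[r] for r in self.reactions if r in keep]
        mets_used = {m for r in rxns for m in r.stoichiometry}
        mets = [m for m in self.metabolites.values() if m.id in mets_used]
        if self.objective_id not in keep:
            raise NetworkError("subnetwork would drop the objective reaction")
        atp = self.atp_demand_id if self.atp_demand_id in keep else None
        return MetabolicNetwork(mets, rxns, self.objective_id, atp, id=id or self.id)

    def __repr__(self) -> str:
        return (
            f"MetabolicNetwork(id={self.id!r}, {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes)"
        )


@dataclass(frozen=True)
class MediumDefinition:
    """Maximum uptake rate per extracellular metabolite; unlisted
    metabolites default to zero uptake (closed)."""

    uptake_rates: Dict[str, float]

    def __post_init__(self):
        for met, rate in self.uptake_rates.items():
            if rate < 0:
                raise NetworkError(f"medium rate for {met!r} is negative: {rate}")

    def rate(self, metabolite_id: str) -> float:
        return self.uptake_rates.get(metabolite_id, 0.0)


# ---------------------------------------------------------------------------
# medium application


def apply_medium(network: MetabolicNetwork, medium: MediumDefinition) -> MetabolicNetwork:
    """Constrain exchange uptake bounds to the medium.

    Every exchange reaction gets uptake bound ``−rate`` for medium
    metabolites and 0 otherwise; release bounds are untouched.  Returns
    a new network.  Medium metabolites without a matching exchange are
    logged as warnings (common when a context-specific model dropped
    the exchange), never fatal.
    """
    new = network.copy()
    seen = set()
    for rid in new.exchange_ids:
        rxn = new.reactions[rid]
        met = next(iter(rxn.stoichiometry))
        coef = rxn.stoichiometry[met]
        rate = medium.rate(met)
        seen.add(met)
        if coef < 0:  # met_e -> : positive flux = release, uptake negative
            new.reactions[rid] = replace(rxn, lower_bound=-rate)
        else:  # -> met_e : positive flux = uptake
            new.reactions[rid] = replace(rxn, upper_bound=rate)
    for met in medium.uptake_rates:
        if met not in seen:
            logger.warning("medium metabolite %r has no exchange reaction in %s", met, network.id)
    new.validate()
    return new


# ---------------------------------------------------------------------------
# JSON dialect (canonical)


def _network_to_dict(network: MetabolicNetwork) -> dict:
    return {
        "id": network.id,
        "metabolites": [
            {"id": m.id, "compartment": m.compartment, "name": m.name}
            for m in network.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string(),
            }
            for r in network.reactions.values()
        ],
        "objective": network.objective_id,
        "atp_demand": network.atp_demand_id,
    }


def _network_from_dict(data: dict) -> MetabolicNetwork:
    try:
        mets = [
            Metabolite(m["id"], m.get("compartment", ""), m.get("name", ""))
            for m in data["metabolites"]
        ]
        rxns = [
            Reaction(
                r["id"],
                {k: float(v) for k, v in r["stoichiometry"].items()},
                float(r["lower_bound"]),
                float(r["upper_bound"]),
                GprRule(r.get("gpr", "")),
                r.get("name", ""),
            )
            for r in data["reactions"]
        ]
    except KeyError as exc:
        raise NetworkError(f"model JSON missing required field {exc}") from exc
    if "objective" not in data or not data["objective"]:
        raise NetworkError("model JSON does not declare an objective reaction")
    return MetabolicNetwork(
        mets, rxns, data["objective"], data.get("atp_demand"), id=data.get("id", "model")
    )


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC


def _write_sbml(network: MetabolicNetwork, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(network.id)
    mplug = model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment or "c" for m in network.metabolites.values()})
    for comp in compartments:
        c = model.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for met in network.metabolites.values():
        s = model.createSpecies()
        s.setId(met.id)
        if met.name:
            s.setName(met.name)
        s.setCompartment(met.compartment or "c")
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)

    for gene in sorted(network.genes):
        gp = mplug.createGeneProduct()
        gp.setId(_sbml_gene_id(gene))
        gp.setLabel(gene)

    bound_ids: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_ids:
            pid = f"fb_{len(bound_ids)}"
            p = model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_ids[value] = pid
        return bound_ids[value]

    for rxn in network.reactions.values():
        r = model.createReaction()
        r.setId(rxn.id)
        if rxn.name:
            r.setName(rxn.name)
        r.setFast(False)
        r.setReversible(rxn.reversible)
        for met, coef in rxn.stoichiometry.items():
            if coef < 0:
                sr = r.createReactant()
                sr.setStoichiometry(-coef)
            else:
                sr = r.createProduct()
                sr.setStoichiometry(coef)
            sr.setSpecies(met)
            sr.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if not rxn.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            gpa.setAssociation(
                rxn.gpr.to_string().replace("(", " ( ").replace(")", " ) "), True, False
            )

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    mplug.setActiveObjectiveId("obj")
    fo = obj.createFluxObjective()
    fo.setReaction(network.objective_id)
    fo.setCoefficient(1.0)
    if network.atp_demand_id:
        model.appendAnnotation(
            f'<gliomaGem xmlns="https://glioma-gem.invalid/ns" '
            f'atp_demand="{network.atp_demand_id}"/>'
        )

    writer = libsbml.SBMLWriter()
    writer.writeSBMLToFile(doc, str(path))


def _sbml_gene_id(gene: str) -> str:
    safe = "".join(ch if (ch.isalnum() or ch == "_") else "_" for ch in gene)
    return f"G_{safe}"


def _read_sbml(path: Path) -> MetabolicNetwork:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise NetworkError(f"SBML parse error in {path}: {err.getMessage() if err else 'unknown'}")
    model = doc.getModel()
    if model is None:
        raise NetworkError(f"{path} contains no SBML model")
    mplug = model.getPlugin("fbc")
    if mplug is None:
        raise NetworkError(f"{path} lacks the FBC package; flux bounds unavailable")

    gene_labels = {}
    for i in range(mplug.getNumGeneProducts()):
        gp = mplug.getGeneProduct(i)
        gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    mets = [
        Metabolite(
            model.getSpecies(i).getId(),
            model.getSpecies(i).getCompartment(),
            model.getSpecies(i).getName(),
        )
        for i in range(model.getNumSpecies())
    ]

    params = {
        model.getParameter(i).getId(): model.getParameter(i).getValue()
        for i in range(model.getNumParameters())
    }

    rxns = []
    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(r.getNumReactants()):
            sr = r.getReactant(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(r.getNumProducts()):
            sr = r.getProduct(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0}
        rplug = r.getPlugin("fbc")
        if rplug is None or not rplug.isSetLowerFluxBound():
            raise NetworkError(f"reaction {r.getId()!r} in {path} lacks FBC flux bounds")
        lb = params[rplug.getLowerFluxBound()]
        ub = params[rplug.getUpperFluxBound()]
        gpr_text = ""
        if rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            gpr_text = _association_to_text(assoc, gene_labels)
        rxns.append(Reaction(r.getId(), stoich, lb, ub, GprRule(gpr_text), r.getName()))

    active = mplug.getActiveObjective()
    if active is None or active.getNumFluxObjectives() == 0:
        raise NetworkError(f"{path} declares no active flux objective")
    objective_id = active.getFluxObjective(0).getReaction()

    atp_demand = None
    ann = model.getAnnotationString() or ""
    if "atp_demand=" in ann:
        atp_demand = ann.split('atp_demand="', 1)[1].split('"', 1)[0]

    return MetabolicNetwork(mets, rxns, objective_id, atp_demand, id=model.getId() or "model")


def _association_to_text(assoc, gene_labels: Dict[str, str]) -> str:
    import libsbml

    if isinstance(assoc, libsbml.GeneProductRef):
        return gene_labels.get(assoc.getGeneProduct(), assoc.getGeneProduct())
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [
            _association_to_text(assoc.getAssociation(i), gene_labels)
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [
            _association_to_text(assoc.getAssociation(i), gene_labels)
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " or ".join(parts) + ")"
    raise NetworkError(f"unsupported gene association node: {assoc}")


# ---------------------------------------------------------------------------
# public I/O


def _infer_dialect(path: Path) -> str:
    return "sbml-fbc" if path.suffix.lower() in {".xml", ".sbml"} else "json"


def read_network(path, dialect: Optional[str] = None) -> MetabolicNetwork:
    """Read a network from JSON (canonical) or SBML-L3-FBC."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise NetworkError(f"invalid model JSON in {path}: {exc}") from exc
        return _network_from_dict(data)
    if dialect == "sbml-fbc":
        return _read_sbml(path)
    raise NetworkError(f"unknown model dialect {dialect!r}")


def write_network(network: MetabolicNetwork, path, dialect: Optional[str] = None) -> None:
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "json":
        path.write_text(json.dumps(_network_to_dict(network), indent=1, sort_keys=False) + "\n")
    elif dialect == "sbml-fbc":
        _write_sbml(network, path)
    else:
        raise NetworkError(f"unknown model dialect {dialect!r}")


def read_medium(path) -> MediumDefinition:
    """Medium CSV: two columns ``metabolite_id,max_uptake`` with header."""
    import csv

    rates: Dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rates[row["metabolite_id"]] = float(row["max_uptake"])
    return MediumDefinition(rates)


def write_medium(medium: MediumDefinition, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["metabolite_id", "max_uptake"])
        for met, rate in medium.uptake_rates.items():
            writer.writerow([met, repr(rate)])
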