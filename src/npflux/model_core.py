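"""Domain types for constraint-based metabolic models and their file formats.

The central object is :class:`MetabolicModel`: an ordered stoichiometric
network with flux bounds (mmol/gDW/h), boolean gene-protein-reaction (GPR)
rules, pathway (subsystem) labels and a biomass objective.  Models are read
and written as SBML Level 3 + FBC v2 (the community standard) or as a plain
JSON dialect; tabular side inputs (drug targets, medium composition,
expression scores) are headered TSV.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GprRule",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "MediumComposition",
    "DrugTargetTable",
    "ModelFormatError",
    "parse_gpr",
    "read_sbml",
    "write_sbml",
    "read_json_model",
    "write_json_model",
    "read_tables",
    "read_drug_targets",
    "read_medium",
    "read_expression",
    "apply_medium",
]

DEFAULT_BOUND = 1000.0


class ModelFormatError(ValueError):
    """Raised when an input file violates the expected format or schema."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GprRule:
    """Boolean expression tree over gene identifiers.

    ``op`` is ``"gene"`` (leaf), ``"and"`` (enzyme complex: every subunit
    required) or ``"or"`` (isozymes: any one suffices).
    """

    op: str
    gene: str | None = None
    children: tuple["GprRule", ...] = ()

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene:
                raise ValueError("gene leaf requires a gene id")
        elif self.op in ("and", "or"):
            if len(self.children) < 1:
                raise ValueError(f"{self.op!r} node requires children")
        else:
            raise ValueError(f"unknown GPR node op {self.op!r}")

    @property
    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset({self.gene})  # type: ignore[arg-type]
        out: set[str] = set()
        for child in self.children:
            out |= child.genes
        return frozenset(out)

    def evaluate(self, knocked: Iterable[str]) -> bool:
        """Truth value with every gene in *knocked* false, all others true."""
        knocked = set(knocked)
        return self.evaluate_assignment(lambda g: g not in knocked)

    def evaluate_assignment(self, truth) -> bool:
        """Truth value under an arbitrary gene -> bool assignment."""
        if self.op == "gene":
            return bool(truth(self.gene))
        if self.op == "and":
            return all(c.evaluate_assignment(truth) for c in self.children)
        return any(c.evaluate_assignment(truth) for c in self.children)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        joiner = f" {self.op} "
        parts = []
        for child in self.children:
            s = child.to_string()
            if child.op != "gene":
                s = f"({s})"
            parts.append(s)
        return joiner.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_GPR_TOKEN = re.compile(r"\(|\)|[A-Za-z0-9_.\-]+")
_TRANSCRIPT_SUFFIX = re.compile(r"\.\d+$")


def _strip_transcript(gene: str) -> str:
    # Recon3D-style gene ids carry transcript suffixes (".1", ".2"); strip them.
    return _TRANSCRIPT_SUFFIX.sub("", gene)


def parse_gpr(text: str, strip_transcripts: bool = True) -> GprRule | None:
    """Parse a GPR string such as ``"(g1 and g2) or g3"``.

    ``and``/``or`` are case-insensitive; gene tokens match
    ``[A-Za-z0-9_.-]+``.  Returns ``None`` for blank input (reaction not
    under gene control).
    """
    tokens = _GPR_TOKEN.findall(text or "")
    if not tokens:
        return None
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GprRule:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GprRule("or", children=tuple(terms))

    def parse_and() -> GprRule:
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else GprRule("and", children=tuple(terms))

    def parse_atom() -> GprRule:
        tok = peek()
        if tok is None:
            raise ModelFormatError("truncated GPR expression")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise ModelFormatError(f"unbalanced parentheses in GPR: {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelFormatError(f"malformed GPR expression: {text!r}")
        gene = take()
        if strip_transcripts:
            gene = _strip_transcript(gene)
        return GprRule("gene", gene=gene)

    rule = parse_or()
    if pos != len(tokens):
        raise ModelFormatError(f"trailing tokens in GPR expression: {text!r}")
    return rule


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass(frozen=True)
class Reaction:
    id: str
    name: str = ""
    subsystem: str = ""
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    stoichiometry: Mapping[str, float] = field(default_factory=dict)
    gpr: GprRule | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def genes(self) -> frozenset[str]:
        return self.gpr.genes if self.gpr is not None else frozenset()

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass(frozen=True)
class MediumComposition:
    """Extracellular metabolites whose uptake is permitted."""

    metabolite_ids: frozenset[str]

    def __init__(self, metabolite_ids: Iterable[str]):
        object.__setattr__(self, "metabolite_ids", frozenset(metabolite_ids))

    def __contains__(self, metabolite_id: str) -> bool:
        return metabolite_id in self.metabolite_ids

    def __len__(self) -> int:
        return len(self.metabolite_ids)


class MetabolicModel:
    """An ordered stoichiometric model with bounds, GPRs and an objective.

    Invariants checked on construction: unique reaction and metabolite ids,
    ``lower_bound <= upper_bound``, stoichiometry referencing only declared
    metabolites, GPR genes contained in the gene set, and an objective
    reaction that exists in the model.
    """

    def __init__(
        self,
        model_id: str,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        objective_reaction_id: str,
        genes: Iterable[str] | None = None,
    ):
        self.model_id = model_id
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.objective_reaction_id = objective_reaction_id

        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        if len(self._met_index) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._rxn_index) != len(self.reactions):
            raise ValueError("duplicate reaction ids")

        gpr_genes: set[str] = set()
        for rxn in self.reactions:
            gpr_genes |= rxn.genes
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ValueError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}"
                    )
        self.genes = set(genes) if genes is not None else set()
        self.genes |= gpr_genes

        if objective_reaction_id not in self._rxn_index:
            raise ValueError(
                f"objective reaction {objective_reaction_id!r} not in model"
            )

    # -- lookups ------------------------------------------------------------

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction(self, reaction_id: str) -> Reaction:
        return self.reactions[self._rxn_index[reaction_id]]

    def metabolite(self, metabolite_id: str) -> Metabolite:
        return self.metabolites[self._met_index[metabolite_id]]

    def has_reaction(self, reaction_id: str) -> bool:
        return reaction_id in self._rxn_index

    @property
    def objective_reaction(self) -> Reaction:
        return self.reaction(self.objective_reaction_id)

    def is_exchange(self, reaction: Reaction | str) -> bool:
        """A boundary reaction: exactly one nonzero stoichiometric entry."""
        if isinstance(reaction, str):
            reaction = self.reaction(reaction)
        nonzero = [c for c in reaction.stoichiometry.values() if c != 0]
        return len(nonzero) == 1

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if self.is_exchange(r)]

    # -- derived edits ------------------------------------------------------

    def with_reactions(self, reactions: Iterable[Reaction], model_id: str | None = None) -> "MetabolicModel":
        """A model with the same metabolite/gene universe but new reactions."""
        return MetabolicModel(
            model_id=model_id or self.model_id,
            metabolites=self.metabolites,
            reactions=reactions,
            objective_reaction_id=self.objective_reaction_id,
            genes=self.genes,
        )

    def with_bounds(self, new_bounds: Mapping[str, tuple[float, float]],
                    model_id: str | None = None) -> "MetabolicModel":
        reactions = [
            replace(r, lower_bound=new_bounds[r.id][0], upper_bound=new_bounds[r.id][1])
            if r.id in new_bounds else r
            for r in self.reactions
        ]
        return self.with_reactions(reactions, model_id=model_id)

    def subset(self, reaction_ids: Iterable[str], model_id: str | None = None) -> "MetabolicModel":
        """Sub-model keeping the given reactions (declaration order) and the
        metabolites and genes they touch."""
        keep = set(reaction_ids)
        if self.objective_reaction_id not in keep:
            raise ValueError("sub-model must retain the objective reaction")
        reactions = [r for r in self.reactions if r.id in keep]
        used_mets = {m for r in reactions for m in r.stoichiometry}
        metabolites = [m for m in self.metabolites if m.id in used_mets]
        return MetabolicModel(
            model_id=model_id or self.model_id,
            metabolites=metabolites,
            reactions=reactions,
            objective_reaction_id=self.objective_reaction_id,
        )

    # -- equality (structural) ----------------------------------------------

    def structurally_equal(self, other: "MetabolicModel") -> bool:
        if self.model_id != other.model_id:
            return False
        if self.objective_reaction_id != other.objective_reaction_id:
            return False
        if [ (m.id, m.name, m.compartment) for m in self.metabolites ] != \
           [ (m.id, m.name, m.compartment) for m in other.metabolites ]:
            return False
        if self.genes != other.genes:
            return False
        if len(self.reactions) != len(other.reactions):
            return False
        for a, b in zip(self.reactions, other.reactions):
            if (a.id, a.name, a.subsystem) != (b.id, b.name, b.subsystem):
                return False
            if not (math.isclose(a.lower_bound, b.lower_bound, abs_tol=1e-9)
                    and math.isclose(a.upper_bound, b.upper_bound, abs_tol=1e-9)):
                return False
            if set(a.stoichiometry) != set(b.stoichiometry):
                return False
            for met, coef in a.stoichiometry.items():
                if not math.isclose(coef, b.stoichiometry[met], abs_tol=1e-9):
                    return False
            sa = a.gpr.to_string() if a.gpr else ""
            sb = b.gpr.to_string() if b.gpr else ""
            if sa != sb:
                return False
        return True

    def __repr__(self) -> str:  # pragma: no cover - convenience
        return (
            f"MetabolicModel({self.model_id!r}, {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites, {len(self.genes)} genes)"
        )


# ---------------------------------------------------------------------------
# Medium constraining
# ---------------------------------------------------------------------------

def apply_medium(model: MetabolicModel, medium: MediumComposition) -> MetabolicModel:
    """Close uptake through every exchange whose metabolite is not in *medium*.

    An exchange reaction touches exactly one metabolite; the uptake direction
    is the one producing that metabolite inside the system (negative flux for
    the conventional ``m_e -> ∅`` formulation with coefficient −1, positive
    flux when the coefficient is +1).  Secretion directions and non-exchange
    reactions are untouched, so the operation never widens a bound and is
    idempotent.
    """
    new_bounds: dict[str, tuple[float, float]] = {}
    for rxn in model.reactions:
        if not model.is_exchange(rxn):
            continue
        (met_id, coef), = ((m, c) for m, c in rxn.stoichiometry.items() if c != 0)
        if met_id in medium:
            continue
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if coef < 0:
            lb = max(lb, 0.0)  # uptake runs negative
        else:
            ub = min(ub, 0.0)  # uptake runs positive
        if (lb, ub) != (rxn.lower_bound, rxn.upper_bound):
            new_bounds[rxn.id] = (lb, ub)
    return model.with_bounds(new_bounds) if new_bounds else model


# ---------------------------------------------------------------------------
# SBML L3 + FBC v2
# ---------------------------------------------------------------------------

def _sid(raw: str) -> str:
    """Make an SBML-legal SId (prefix with underscore if needed)."""
    s = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not s or not (s[0].isalpha() or s[0] == "_"):
        s = "_" + s
    return s


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Serialise to SBML Level 3 Version 1 with the FBC v2 package.

    Bounds become FBC flux-bound parameters, the objective an FBC objective,
    GPR trees FBC gene-product associations, and subsystem labels FBC-groups
    member lists (one group per label).
    """
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    doc.enablePackage(libsbml.FbcExtension.getXmlnsL3V1V2(), "fbc", True)
    doc.enablePackage(libsbml.GroupsExtension.getXmlnsL3V1V1(), "groups", True)
    doc.setPackageRequired("fbc", False)
    doc.setPackageRequired("groups", False)

    sbml_model = doc.createModel()
    sbml_model.setId(_sid(model.model_id))
    sbml_model.setName(model.model_id)
    fbc = sbml_model.getPlugin("fbc")
    fbc.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites} or {"c"})
    for comp in compartments:
        c = sbml_model.createCompartment()
        c.setId(_sid(comp))
        c.setConstant(True)

    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(_sid(met.id))
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(_sid(met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    for gene in sorted(model.genes):
        gp = fbc.createGeneProduct()
        gp.setId("G_" + _sid(gene))
        gp.setLabel(gene)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    def set_association(assoc_parent, rule: GprRule) -> None:
        if rule.op == "gene":
            ref = assoc_parent.createGeneProductRef()
            ref.setGeneProduct("G_" + _sid(rule.gene))
        elif rule.op == "and":
            node = assoc_parent.createAnd()
            for child in rule.children:
                set_association(node, child)
        else:
            node = assoc_parent.createOr()
            for child in rule.children:
                set_association(node, child)

    for rxn in model.reactions:
        r = sbml_model.createReaction()
        r.setId(_sid(rxn.id))
        if rxn.name:
            r.setName(rxn.name)
        r.setFast(False)
        r.setReversible(rxn.lower_bound < 0)
        for met_id, coef in rxn.stoichiometry.items():
            if coef < 0:
                ref = r.createReactant()
            elif coef > 0:
                ref = r.createProduct()
            else:
                continue
            ref.setSpecies(_sid(met_id))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rfbc = r.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_param(rxn.lower_bound))
        rfbc.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            assoc = rfbc.createGeneProductAssociation()
            set_association(assoc, rxn.gpr)

    objective = fbc.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    flux_obj = objective.createFluxObjective()
    flux_obj.setReaction(_sid(model.objective_reaction_id))
    flux_obj.setCoefficient(1.0)
    fbc.setActiveObjectiveId("obj")

    groups = sbml_model.getPlugin("groups")
    subsystems: dict[str, list[str]] = {}
    for rxn in model.reactions:
        if rxn.subsystem:
            subsystems.setdefault(rxn.subsystem, []).append(rxn.id)
    for i, (label, rxn_ids) in enumerate(subsystems.items()):
        group = groups.createGroup()
        group.setId(f"subsys_{i}")
        group.setName(label)
        group.setKind("partonomy")
        for rid in rxn_ids:
            member = group.createMember()
            member.setIdRef(_sid(rid))

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ModelFormatError(f"cannot write SBML to {path}")


def read_sbml(path: str | Path) -> MetabolicModel:
    """Read an SBML L3 + FBC model into a :class:`MetabolicModel`.

    Subsystems come from FBC-groups when present, else a ``SUBSYSTEM:`` key in
    reaction notes.  Gene transcript suffixes (``.1``) are stripped.  A model
    without an active FBC objective raises a "no objective" error.
    """
    import libsbml

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(f"SBML parse failure in {path.name}: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"no <model> element in {path.name}")

    gene_labels: dict[str, str] = {}
    fbc = sbml_model.getPlugin("fbc")
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            label = gp.getLabel() or gp.getId()
            gene_labels[gp.getId()] = _strip_transcript(label)

    metabolites = [
        Metabolite(
            id=sp.getId(),
            name=sp.getName() or "",
            compartment=sp.getCompartment() or "c",
        )
        for sp in (sbml_model.getSpecies(i) for i in range(sbml_model.getNumSpecies()))
    ]

    def convert_association(assoc) -> GprRule:
        import libsbml as _ls
        if isinstance(assoc, _ls.GeneProductRef):
            gid = assoc.getGeneProduct()
            return GprRule("gene", gene=gene_labels.get(gid, _strip_transcript(gid)))
        children = tuple(
            convert_association(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        )
        if isinstance(assoc, _ls.FbcAnd):
            return children[0] if len(children) == 1 else GprRule("and", children=children)
        if isinstance(assoc, _ls.FbcOr):
            return children[0] if len(children) == 1 else GprRule("or", children=children)
        raise ModelFormatError(f"unsupported GPR association node {type(assoc).__name__}")

    subsystem_of: dict[str, str] = {}
    groups = sbml_model.getPlugin("groups")
    if groups is not None:
        for i in range(groups.getNumGroups()):
            group = groups.getGroup(i)
            label = group.getName() or group.getId()
            for j in range(group.getNumMembers()):
                ref = group.getMember(j).getIdRef()
                if ref:
                    subsystem_of[ref] = label

    def notes_subsystem(r) -> str:
        if not r.isSetNotes():
            return ""
        text = r.getNotesString()
        match = re.search(r"SUBSYSTEM:\s*([^<\n]+)", text)
        return match.group(1).strip() if match else ""

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()

        rfbc = r.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        gpr = None
        if rfbc is not None:
            lb_param = sbml_model.getParameter(rfbc.getLowerFluxBound() or "")
            ub_param = sbml_model.getParameter(rfbc.getUpperFluxBound() or "")
            if lb_param is not None:
                lb = lb_param.getValue()
            if ub_param is not None:
                ub = ub_param.getValue()
            gpa = rfbc.getGeneProductAssociation()
            if gpa is not None and gpa.getAssociation() is not None:
                gpr = convert_association(gpa.getAssociation())
        if not math.isfinite(lb):
            lb = -DEFAULT_BOUND
        if not math.isfinite(ub):
            ub = DEFAULT_BOUND
        reactions.append(
            Reaction(
                id=r.getId(),
                name=r.getName() or "",
                subsystem=subsystem_of.get(r.getId()) or notes_subsystem(r),
                lower_bound=lb,
                upper_bound=ub,
                stoichiometry=stoich,
                gpr=gpr,
            )
        )

    objective_id = None
    if fbc is not None:
        active = fbc.getActiveObjective()
        if active is not None and active.getNumFluxObjectives() > 0:
            objective_id = active.getFluxObjective(0).getReaction()
    if not objective_id:
        raise ModelFormatError(f"no objective declared in {path.name} (missing FBC objective)")

    return MetabolicModel(
        model_id=sbml_model.getName() or sbml_model.getId() or path.stem,
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction_id=objective_id,
        genes=set(gene_labels.values()),
    )


# ---------------------------------------------------------------------------
# Internal JSON dialect
# ---------------------------------------------------------------------------

def write_json_model(model: MetabolicModel, path: str | Path) -> None:
    payload = {
        "model_id": model.model_id,
        "objective_reaction_id": model.objective_reaction_id,
        "genes": sorted(model.genes),
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "subsystem": r.subsystem,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "stoichiometry": dict(r.stoichiometry),
                "gpr": r.gpr.to_string() if r.gpr else "",
            }
            for r in model.reactions
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_json_model(path: str | Path) -> MetabolicModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"invalid JSON model {path}: {exc}") from exc
    for key in ("model_id", "objective_reaction_id", "metabolites", "reactions"):
        if key not in payload:
            raise ModelFormatError(f"JSON model missing key {key!r}")
    return MetabolicModel(
        model_id=payload["model_id"],
        metabolites=[Metabolite(**m) for m in payload["metabolites"]],
        reactions=[
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                subsystem=r.get("subsystem", ""),
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                stoichiometry=r.get("stoichiometry", {}),
                gpr=parse_gpr(r.get("gpr", "")),
            )
            for r in payload["reactions"]
        ],
        objective_reaction_id=payload["objective_reaction_id"],
        genes=set(payload.get("genes", ())),
    )


def load_model(path: str | Path) -> MetabolicModel:
    """Dispatch on extension: ``.json`` -> JSON dialect, else SBML."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_json_model(path)
    return read_sbml(path)


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugTargetTable:
    """Drug -> set of target gene ids, with an optional drug class label
    (``natural_product`` / ``cancer_drug``)."""

    targets: Mapping[str, frozenset[str]]
    drug_class: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "targets", {d: frozenset(g) for d, g in self.targets.items()}
        )
        object.__setattr__(self, "drug_class", dict(self.drug_class))

    @property
    def drugs(self) -> list[str]:
        return sorted(self.targets)

    def genes_for(self, drug: str) -> frozenset[str]:
        return self.targets[drug]

    def drugs_of_class(self, cls: str) -> list[str]:
        return sorted(d for d in self.targets if self.drug_class.get(d) == cls)

    def restrict_to_genes(self, genes: Iterable[str]) -> "DrugTargetTable":
        genes = set(genes)
        return DrugTargetTable(
            {d: g & genes for d, g in self.targets.items()},
            self.drug_class,
        )

    def __len__(self) -> int:
        return len(self.targets)


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ModelFormatError(f"{what}: missing required column(s) {missing}")


def read_drug_targets(path: str | Path) -> DrugTargetTable:
    """Read a ``drug_id<TAB>gene_id[<TAB>drug_class]`` table; duplicate
    (drug, gene) rows are deduplicated."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["drug_id", "gene_id"], f"drug target table {path}")
    targets: dict[str, set[str]] = {}
    classes: dict[str, str] = {}
    for row in df.itertuples(index=False):
        targets.setdefault(row.drug_id, set()).add(row.gene_id)
        if "drug_class" in df.columns and isinstance(row.drug_class, str):
            classes[row.drug_id] = row.drug_class
    return DrugTargetTable(targets, classes)


def read_medium(path: str | Path) -> MediumComposition:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["metabolite_id"], f"medium table {path}")
    return MediumComposition(df["metabolite_id"].dropna())


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression scores, genes as rows (index ``gene_id``), one real-valued
    column per condition."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ModelFormatError(
            f"expression table {path}: first column must be 'gene_id', got {df.columns[0]!r}"
        )
    if df.shape[1] < 2:
        raise ModelFormatError(f"expression table {path}: no condition columns")
    df = df.set_index("gene_id")
    return df.astype(float)


def read_tables(
    targets_path: str | Path,
    medium_path: str | Path,
    expression_path: str | Path,
) -> tuple[DrugTargetTable, MediumComposition, pd.DataFrame]:
    return (
        read_drug_targets(targets_path),
        read_medium(medium_path),
        read_expression(expression_path),
    )
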