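"""Metabolic model containers and format-agnostic I/O.

A :class:`MetabolicModel` is the shared in-memory representation used by every
other module: a set of compartments, metabolites, mass-balance reactions with
flux bounds and optional boolean gene rules, and a single biomass objective.
Two on-disk dialects are supported:

* a JSON dialect (schema documented in ``docs/methods.md``) that round-trips
  every field, and
* an SBML Level 3 subset using the ``fbc`` version 2 package for flux bounds,
  gene-product associations and the flux objective — the convention used by
  the constraint-based modelling community.

Media (maximum uptake rates for extracellular nutrients) are plain TSV tables
with columns ``metabolite`` and ``max_uptake``.

Conventions
-----------
- Compartment ``"e"`` is the extracellular compartment.
- Metabolite ids follow ``<base>_<compartment>`` (e.g. ``galactose_e``); the
  compartment-free *base id* is the join key used to match "the same" compound
  across members of a community.
- Negative flux on an exchange reaction means uptake into the system; positive
  means secretion.
- Unspecified bounds default to [-1000, 1000] for reversible reactions and
  [0, 1000] for irreversible ones.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

EXTRACELLULAR = "e"
DEFAULT_UB = 1000.0
DEFAULT_LB = -1000.0

KINDS = ("internal", "transport", "exchange", "biomass")


class FormatError(ValueError):
    """Raised when a file cannot be parsed under the named dialect."""


class ValidationError(ValueError):
    """Raised when a model or medium violates its invariants.

    Carries ``diagnostics``: one message per violated invariant.
    """

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        super().__init__(
            "%d validation error(s):\n%s"
            % (len(self.diagnostics), "\n".join("  - " + d for d in self.diagnostics))
        )


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    annotation: str = ""

    @property
    def base_id(self) -> str:
        """Compartment-free id: strips a trailing ``_<compartment>`` suffix."""
        suffix = "_" + self.compartment
        if self.id.endswith(suffix):
            return self.id[: -len(suffix)]
        return self.id


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = DEFAULT_LB
    upper_bound: float = DEFAULT_UB
    gene_rule: str | None = None
    subsystem: str | None = None
    kind: str = "internal"

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    id: str
    compartments: set[str] = field(default_factory=set)
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: set[str] = field(default_factory=set)
    objective_reaction_id: str | None = None

    # -- lookup helpers -------------------------------------------------
    @property
    def metabolite_map(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    @property
    def reaction_map(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            compartments=set(self.compartments),
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=set(self.genes),
            objective_reaction_id=self.objective_reaction_id,
        )

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == "exchange"]

    def transport_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == "transport"]


@dataclass
class Medium:
    """Maximum uptake rates (mmol gDW^-1 h^-1) keyed by extracellular base id."""

    uptake_bounds: dict[str, float]
    name: str = "medium"

    def __post_init__(self):
        bad = [k for k, v in self.uptake_bounds.items() if v < 0]
        if bad:
            raise ValidationError(
                [f"medium bound for '{k}' is negative" for k in bad]
            )


# ---------------------------------------------------------------------------
# kind inference and validation
# ---------------------------------------------------------------------------

def infer_kind(reaction: Reaction, model: MetabolicModel) -> str:
    """Classify a reaction when the file does not state its kind.

    exchange: touches exactly one metabolite and it is extracellular;
    transport: touches metabolites in >= 2 distinct compartments;
    biomass: the model's declared objective; otherwise internal.
    """
    if reaction.id == model.objective_reaction_id:
        return "biomass"
    mets = model.metabolite_map
    comps = {mets[m].compartment for m in reaction.stoichiometry if m in mets}
    if len(reaction.stoichiometry) == 1 and comps == {EXTRACELLULAR}:
        return "exchange"
    if len(comps) >= 2:
        return "transport"
    return "internal"


def validate_model(model: MetabolicModel, collect: bool = False):
    """Check every type invariant; raise :class:`ValidationError` listing all
    violations, or return the diagnostics list when ``collect`` is true."""
    from .reconstruction import gene_rule_ids  # local import, no cycle at call time

    diags: list[str] = []
    seen: set[str] = set()
    for m in model.metabolites:
        if not m.id:
            diags.append("metabolite with empty id")
        elif m.id in seen:
            diags.append(f"duplicate metabolite id '{m.id}'")
        seen.add(m.id)
        if m.compartment not in model.compartments:
            diags.append(
                f"metabolite '{m.id}' in undeclared compartment '{m.compartment}'"
            )
    mets = model.metabolite_map
    rseen: set[str] = set()
    n_biomass = 0
    for r in model.reactions:
        if r.id in rseen:
            diags.append(f"duplicate reaction id '{r.id}'")
        rseen.add(r.id)
        for mid in r.stoichiometry:
            if mid not in mets:
                diags.append(
                    f"reaction '{r.id}' references undeclared metabolite '{mid}'"
                )
        if r.lower_bound > r.upper_bound:
            diags.append(
                f"reaction '{r.id}' has lower_bound {r.lower_bound} > "
                f"upper_bound {r.upper_bound}"
            )
        if r.kind not in KINDS:
            diags.append(f"reaction '{r.id}' has unknown kind '{r.kind}'")
        if r.kind == "exchange":
            if len(r.stoichiometry) != 1:
                diags.append(
                    f"exchange reaction '{r.id}' touches "
                    f"{len(r.stoichiometry)} metabolites (must be exactly 1)"
                )
            else:
                (mid,) = r.stoichiometry
                if mid in mets and mets[mid].compartment != EXTRACELLULAR:
                    diags.append(
                        f"exchange reaction '{r.id}' metabolite '{mid}' is not "
                        "extracellular"
                    )
        if r.kind == "transport":
            comps = {mets[m].compartment for m in r.stoichiometry if m in mets}
            if len(comps) < 2:
                diags.append(
                    f"transport reaction '{r.id}' touches only compartments "
                    f"{sorted(comps)} (must span >= 2)"
                )
        if r.kind == "biomass":
            n_biomass += 1
        if r.gene_rule:
            try:
                unknown = gene_rule_ids(r.gene_rule) - model.genes
            except ValueError as exc:
                diags.append(f"reaction '{r.id}' has unparsable gene rule: {exc}")
                unknown = set()
            for g in sorted(unknown):
                diags.append(
                    f"reaction '{r.id}' gene rule uses undeclared gene '{g}'"
                )
    if n_biomass > 1:
        diags.append(f"model declares {n_biomass} biomass reactions (at most 1)")
    obj = model.objective_reaction_id
    if obj is not None:
        if obj not in rseen:
            diags.append(f"objective_reaction_id '{obj}' does not resolve")
        elif model.reaction_map[obj].kind != "biomass":
            diags.append(f"objective reaction '{obj}' does not have kind biomass")
    if collect:
        return diags
    if diags:
        raise ValidationError(diags)
    return []


def models_equal(a: MetabolicModel, b: MetabolicModel, tol: float = 1e-9) -> bool:
    """Id-level equality with float bounds compared within ``tol``."""
    if a.id != b.id or a.compartments != b.compartments or a.genes != b.genes:
        return False
    if a.objective_reaction_id != b.objective_reaction_id:
        return False
    am, bm = a.metabolite_map, b.metabolite_map
    if set(am) != set(bm):
        return False
    for mid, m in am.items():
        n = bm[mid]
        if (m.name, m.compartment, m.formula, m.annotation) != (
            n.name, n.compartment, n.formula, n.annotation
        ):
            return False
    ar, br = a.reaction_map, b.reaction_map
    if set(ar) != set(br):
        return False
    for rid, r in ar.items():
        s = br[rid]
        if r.stoichiometry.keys() != s.stoichiometry.keys():
            return False
        if any(
            not math.isclose(r.stoichiometry[k], s.stoichiometry[k], abs_tol=tol)
            for k in r.stoichiometry
        ):
            return False
        if not math.isclose(r.lower_bound, s.lower_bound, abs_tol=tol):
            return False
        if not math.isclose(r.upper_bound, s.upper_bound, abs_tol=tol):
            return False
        if ((r.gene_rule or None), r.subsystem, r.kind, r.name) != (
            (s.gene_rule or None), s.subsystem, s.kind, s.name
        ):
            return False
    return True


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "compartments": sorted(model.compartments),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "annotation": m.annotation,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_rule": r.gene_rule,
                "subsystem": r.subsystem,
                "kind": r.kind,
            }
            for r in model.reactions
        ],
        "genes": sorted(model.genes),
        "objective": model.objective_reaction_id,
    }


def _model_from_dict(data: dict, source: str = "<json>") -> MetabolicModel:
    try:
        model = MetabolicModel(
            id=data["id"],
            compartments=set(data.get("compartments", [])),
            metabolites=[
                Metabolite(
                    id=m["id"],
                    name=m.get("name", ""),
                    compartment=m.get("compartment", "c"),
                    formula=m.get("formula"),
                    annotation=m.get("annotation", "") or "",
                )
                for m in data.get("metabolites", [])
            ],
            genes=set(data.get("genes", [])),
            objective_reaction_id=data.get("objective"),
        )
        for r in data.get("reactions", []):
            rev = bool(r.get("reversible", True))
            lb = r.get("lower_bound", DEFAULT_LB if rev else 0.0)
            ub = r.get("upper_bound", DEFAULT_UB)
            model.reactions.append(
                Reaction(
                    id=r["id"],
                    name=r.get("name", ""),
                    stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                    lower_bound=float(lb),
                    upper_bound=float(ub),
                    gene_rule=r.get("gene_rule") or None,
                    subsystem=r.get("subsystem"),
                    kind=r.get("kind") or "",
                )
            )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{source}: malformed model JSON ({exc!r})") from exc
    for r in model.reactions:
        if not r.kind:
            r.kind = infer_kind(r, model)
    return model


def model_to_json(model: MetabolicModel) -> str:
    return json.dumps(_model_to_dict(model), indent=1, sort_keys=False) + "\n"


# ---------------------------------------------------------------------------
# SBML dialect (Level 3 core + fbc v2 subset)
# ---------------------------------------------------------------------------

def _write_sbml(model: MetabolicModel, path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for comp in sorted(model.compartments):
        c = sm.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for met in model.metabolites:
        s = sm.createSpecies()
        s.setId(met.id)
        if met.name:
            s.setName(met.name)
        s.setCompartment(met.compartment)
        s.setConstant(False)
        s.setBoundaryCondition(False)
        s.setHasOnlySubstanceUnits(False)
        s.setInitialConcentration(0.0)
        splug = s.getPlugin("fbc")
        if met.formula:
            splug.setChemicalFormula(met.formula)
        if met.annotation:
            s.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>ANNOTATION: {met.annotation}</p></body>"
            )

    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(gene)
        gp.setLabel(gene)

    # one shared parameter per distinct bound value
    params: dict[float, str] = {}

    def _param(value: float) -> str:
        if value not in params:
            pid = f"bnd_{len(params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            params[value] = pid
        return params[value]

    for rxn in model.reactions:
        r = sm.createReaction()
        r.setId(rxn.id)
        if rxn.name:
            r.setName(rxn.name)
        r.setFast(False)
        r.setReversible(rxn.lower_bound < 0)
        notes = []
        if rxn.subsystem:
            notes.append(f"<p>SUBSYSTEM: {rxn.subsystem}</p>")
        notes.append(f"<p>KIND: {rxn.kind}</p>")
        r.setNotes(
            "<body xmlns='http://www.w3.org/1999/xhtml'>" + "".join(notes) + "</body>"
        )
        for mid, coef in rxn.stoichiometry.items():
            if coef < 0:
                sr = r.createReactant()
                sr.setStoichiometry(-coef)
            else:
                sr = r.createProduct()
                sr.setStoichiometry(coef)
            sr.setSpecies(mid)
            sr.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(_param(rxn.lower_bound))
        rplug.setUpperFluxBound(_param(rxn.upper_bound))
        if rxn.gene_rule:
            gpa = rplug.createGeneProductAssociation()
            ret = gpa.setAssociation(rxn.gene_rule)
            if ret != libsbml.LIBSBML_OPERATION_SUCCESS:
                raise FormatError(
                    f"could not encode gene rule '{rxn.gene_rule}' for '{rxn.id}'"
                )

    if model.objective_reaction_id:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective_reaction_id)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if not libsbml.writeSBMLToFile(doc, str(path)):
        raise OSError(f"could not write SBML to {path}")


def _notes_field(notes_str: str, tag: str) -> str | None:
    for line in notes_str.splitlines():
        line = line.strip()
        marker = f"{tag}: "
        if marker in line:
            val = line.split(marker, 1)[1]
            return val.replace("</p>", "").strip()
    return None


def _read_sbml(path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise FormatError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise FormatError(f"{path}: file contains no SBML model")
    mplug = sm.getPlugin("fbc")

    model = MetabolicModel(id=sm.getId() or "model")
    for i in range(sm.getNumCompartments()):
        model.compartments.add(sm.getCompartment(i).getId())

    for i in range(sm.getNumSpecies()):
        s = sm.getSpecies(i)
        splug = s.getPlugin("fbc")
        formula = None
        if splug is not None and splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula()
        annotation = ""
        if s.isSetNotes():
            annotation = _notes_field(s.getNotesString(), "ANNOTATION") or ""
        model.metabolites.append(
            Metabolite(
                id=s.getId(),
                name=s.getName() or "",
                compartment=s.getCompartment(),
                formula=formula,
                annotation=annotation,
            )
        )

    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            model.genes.add(mplug.getGeneProduct(i).getId())
        if mplug.getNumObjectives() > 0:
            obj = mplug.getActiveObjective() or mplug.getObjective(0)
            if obj is not None and obj.getNumFluxObjectives() > 0:
                model.objective_reaction_id = obj.getFluxObjective(0).getReaction()

    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            sr = r.getReactant(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(r.getNumProducts()):
            sr = r.getProduct(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        lb = DEFAULT_LB if r.getReversible() else 0.0
        ub = DEFAULT_UB
        gene_rule = None
        rplug = r.getPlugin("fbc")
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                p = sm.getParameter(rplug.getLowerFluxBound())
                if p is not None:
                    lb = p.getValue()
            if rplug.isSetUpperFluxBound():
                p = sm.getParameter(rplug.getUpperFluxBound())
                if p is not None:
                    ub = p.getValue()
            if rplug.isSetGeneProductAssociation():
                assoc = rplug.getGeneProductAssociation().getAssociation()
                if assoc is not None:
                    gene_rule = assoc.toInfix().strip()
                    if gene_rule.startswith("(") and gene_rule.endswith(")"):
                        # toInfix wraps the whole expression; unwrap one level
                        depth = 0
                        balanced = True
                        for idx, ch in enumerate(gene_rule):
                            depth += ch == "("
                            depth -= ch == ")"
                            if depth == 0 and idx < len(gene_rule) - 1:
                                balanced = False
                                break
                        if balanced:
                            gene_rule = gene_rule[1:-1]
        subsystem = None
        kind = ""
        if r.isSetNotes():
            notes = r.getNotesString()
            subsystem = _notes_field(notes, "SUBSYSTEM")
            kind = _notes_field(notes, "KIND") or ""
        model.reactions.append(
            Reaction(
                id=r.getId(),
                name=r.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_rule=gene_rule,
                subsystem=subsystem,
                kind=kind,
            )
        )
    for rxn in model.reactions:
        if not rxn.kind:
            rxn.kind = infer_kind(rxn, model)
    return model


# ---------------------------------------------------------------------------
# public I/O surface
# ---------------------------------------------------------------------------

def read_model(path, dialect: str = "json") -> MetabolicModel:
    """Read and validate a metabolic model from ``path``.

    Reaction kinds are taken from the file when present, else inferred
    (exchange = single extracellular metabolite; transport = multi-compartment).
    """
    if dialect == "json":
        try:
            with open(path) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}")
        model = _model_from_dict(data, source=str(path))
    elif dialect == "sbml":
        model = _read_sbml(path)
    else:
        raise ValueError(f"unknown dialect '{dialect}' (expected 'json' or 'sbml')")
    validate_model(model)
    return model


def write_model(model: MetabolicModel, path, dialect: str = "json") -> None:
    """Write a validated model; the file re-reads to an equal model."""
    validate_model(model)
    if dialect == "json":
        with open(path, "w") as fh:
            fh.write(model_to_json(model))
    elif dialect == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown dialect '{dialect}' (expected 'json' or 'sbml')")


def read_medium(path) -> Medium:
    """Read a TSV medium table with header ``metabolite<TAB>max_uptake``."""
    import pandas as pd

    try:
        table = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error surface
        raise FormatError(f"{path}: could not parse medium TSV ({exc})") from exc
    expected = ["metabolite", "max_uptake"]
    if list(table.columns[:2]) != expected:
        raise FormatError(
            f"{path}: medium TSV must have header {expected[0]}\\t{expected[1]}, "
            f"got {list(table.columns)}"
        )
    diags = []
    dupes = table["metabolite"][table["metabolite"].duplicated()].tolist()
    for d in dupes:
        diags.append(f"duplicate medium metabolite '{d}'")
    for _, row in table.iterrows():
        if float(row["max_uptake"]) < 0:
            diags.append(
                f"medium bound for '{row['metabolite']}' is negative"
            )
    if diags:
        raise ValidationError(diags)
    bounds = {
        str(row["metabolite"]): float(row["max_uptake"]) for _, row in table.iterrows()
    }
    import os

    return Medium(uptake_bounds=bounds, name=os.path.splitext(os.path.basename(str(path)))[0])


def write_medium(medium: Medium, path) -> None:
    with open(path, "w") as fh:
        fh.write("metabolite\tmax_uptake\n")
        for met, bound in medium.uptake_bounds.items():
            fh.write(f"{met}\t{bound:g}\n")
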