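"""Metabolic model representation, SBML I/O and gene-protein-reaction (GPR) logic.

The central container is :class:`MetabolicModel`: metabolites, bounded
reactions with stoichiometry, boolean GPR rules linking genes to reactions,
optional subsystem labels and a linear objective (the biomass pseudo-reaction
by default).  Everything downstream — expression integration, flux balance
analysis, network construction — transforms or queries this object.

GPR rules are parsed into a small AST over AND / OR / gene literals.  AND
binds tighter than OR; parentheses override.  A reaction with no GPR is
treated as unconditionally available (the COBRA convention), so gene
deletions never disable it.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, replace

import libsbml
import numpy as np

logger = logging.getLogger(__name__)

#: Cap substituted for infinite bounds read from SBML; flux variability needs
#: finite ranges and 1000 mmol gDW^-1 h^-1 is the conventional COBRA cap.
DEFAULT_BOUND = 1000.0


class GPRParseError(ValueError):
    """Raised on malformed GPR strings; carries the offending position."""


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


# ---------------------------------------------------------------------------
# GPR abstract syntax tree
# ---------------------------------------------------------------------------


class GPRExpression:
    """Base class for GPR AST nodes."""

    def genes(self) -> frozenset[str]:
        raise NotImplementedError

    def evaluate(self, present: set[str] | frozenset[str]) -> bool:
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.to_string()!r})"


@dataclass(frozen=True)
class GeneLeaf(GPRExpression):
    gene: str

    def genes(self) -> frozenset[str]:
        return frozenset({self.gene})

    def evaluate(self, present) -> bool:
        return self.gene in present

    def to_string(self) -> str:
        return self.gene


@dataclass(frozen=True)
class BoolOp(GPRExpression):
    """AND/OR node; operands are order-insensitive for semantic equality."""

    op: str  # "and" | "or"
    operands: tuple[GPRExpression, ...]

    def genes(self) -> frozenset[str]:
        return frozenset().union(*(o.genes() for o in self.operands))

    def evaluate(self, present) -> bool:
        fn = all if self.op == "and" else any
        return fn(o.evaluate(present) for o in self.operands)

    def to_string(self) -> str:
        parts = []
        for o in self.operands:
            s = o.to_string()
            if isinstance(o, BoolOp) and o.op != self.op:
                s = f"({s})"
            parts.append(s)
        return f" {self.op} ".join(parts)


def gpr_and(*operands: GPRExpression) -> GPRExpression:
    return operands[0] if len(operands) == 1 else BoolOp("and", tuple(operands))


def gpr_or(*operands: GPRExpression) -> GPRExpression:
    return operands[0] if len(operands) == 1 else BoolOp("or", tuple(operands))


_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.:\-']+)")


def parse_gpr(rule: str) -> GPRExpression | None:
    """Parse a GPR rule string into an AST.

    ``and`` binds tighter than ``or``; both are case-insensitive.  Returns
    ``None`` for an empty/blank rule (reaction not gene-associated).

    Raises
    ------
    GPRParseError
        On unbalanced parentheses or a missing operand, with the character
        position of the problem.
    """
    if rule is None or not rule.strip():
        return None
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(rule):
        m = _TOKEN_RE.match(rule, pos)
        if m is None:
            if rule[pos:].strip():
                raise GPRParseError(f"unexpected character at position {pos}: {rule[pos]!r}")
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()

    idx = 0

    def peek():
        return tokens[idx][0] if idx < len(tokens) else None

    def parse_or() -> GPRExpression:
        nonlocal idx
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            idx += 1
            terms.append(parse_and())
        return gpr_or(*terms)

    def parse_and() -> GPRExpression:
        nonlocal idx
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            idx += 1
            factors.append(parse_atom())
        return gpr_and(*factors)

    def parse_atom() -> GPRExpression:
        nonlocal idx
        tok = peek()
        at = tokens[idx][1] if idx < len(tokens) else len(rule)
        if tok is None:
            raise GPRParseError(f"missing operand at position {at}")
        if tok == "(":
            idx += 1
            inner = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parenthesis at position {at}")
            idx += 1
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"missing operand at position {at}")
        idx += 1
        return GeneLeaf(tok)

    expr = parse_or()
    if idx != len(tokens):
        raise GPRParseError(f"unexpected token {tokens[idx][0]!r} at position {tokens[idx][1]}")
    return expr


def evaluate_gpr(expr: GPRExpression | None, present_genes: set[str] | frozenset[str]) -> bool:
    """Boolean availability of a reaction given the set of present genes.

    An empty GPR (``None``) evaluates True: the reaction is not
    gene-associated and no deletion can disable it.
    """
    if expr is None:
        return True
    return expr.evaluate(present_genes)


def gpr_equal(a: GPRExpression | None, b: GPRExpression | None) -> bool:
    """AST equality up to operand order within AND/OR (commutativity)."""
    if a is None or b is None:
        return a is b or (a is None and b is None)
    return _canon(a) == _canon(b)


def _canon(expr: GPRExpression):
    if isinstance(expr, GeneLeaf):
        return ("g", expr.gene)
    # flatten nested nodes of the same operator: (a and (b and c)) == (a and b and c)
    flat = []
    for o in expr.operands:
        c = _canon(o)
        if isinstance(o, BoolOp) and o.op == expr.op:
            flat.extend(c[1])
        else:
            flat.append(c)
    return (expr.op, tuple(sorted(flat, key=repr)))


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    """A bounded, possibly gene-associated biochemical conversion.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  Flux bounds are in mmol gDW^-1 h^-1.  A reaction is
    irreversible iff ``lower_bound >= 0``.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRExpression | None = None
    subsystem: str = ""
    objective_coefficient: float = 0.0

    @property
    def irreversible(self) -> bool:
        return self.lower_bound >= 0

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @property
    def gene_set(self) -> frozenset[str]:
        return self.gpr.genes() if self.gpr is not None else frozenset()

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    """A stoichiometric model: the scaffold every analysis stage queries."""

    id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- structural queries -------------------------------------------------

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.gene_set
        return frozenset(out)

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        try:
            return self._rxn_index[rid]
        except (AttributeError, KeyError):
            self._rxn_index = {r.id: r for r in self.reactions}
            if rid not in self._rxn_index:
                raise KeyError(f"no reaction {rid!r} in model {self.id!r}")
            return self._rxn_index[rid]

    @property
    def objective_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.objective_coefficient != 0]

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions)."""
        met_idx = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoichiometry.items():
                S[met_idx[mid], j] = coef
        return S

    # -- validation & copying ----------------------------------------------

    def validate(self) -> None:
        mids = [m.id for m in self.metabolites]
        if len(set(mids)) != len(mids):
            raise ModelValidationError(f"duplicate metabolite ids in {self.id!r}")
        if any(not m for m in mids):
            raise ModelValidationError("empty metabolite id")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ModelValidationError(f"duplicate reaction ids in {self.id!r}")
        known = set(mids)
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id!r}: lower_bound {r.lower_bound} > upper_bound {r.upper_bound}"
                )
            unknown = set(r.stoichiometry) - known
            if unknown:
                raise ModelValidationError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(unknown)}"
                )
        self._rxn_index = {r.id: r for r in self.reactions}

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
        )


# ---------------------------------------------------------------------------
# Gene-to-reaction mapping & summary statistics
# ---------------------------------------------------------------------------


def genes_to_reactions(model: MetabolicModel, genes) -> dict[str, set[str]]:
    """Map each queried gene to the reactions whose GPR contains it as a leaf.

    Genes absent from every GPR map to the empty set (logged at WARNING).
    """
    model_genes = model.genes
    out: dict[str, set[str]] = {}
    for g in genes:
        hits = {r.id for r in model.reactions if g in r.gene_set}
        if not hits and g not in model_genes:
            logger.warning("gene %r not present in any GPR of model %r", g, model.id)
        out[g] = hits
    return out


@dataclass(frozen=True)
class ModelStats:
    n_genes: int
    n_reactions: int
    n_irreversible: int
    n_metabolites: int
    n_subsystems: int


def model_stats(model: MetabolicModel) -> ModelStats:
    """Summary counts; irreversible means lower_bound >= 0."""
    return ModelStats(
        n_genes=len(model.genes),
        n_reactions=len(model.reactions),
        n_irreversible=sum(1 for r in model.reactions if r.irreversible),
        n_metabolites=len(model.metabolites),
        n_subsystems=len({r.subsystem for r in model.reactions if r.subsystem}),
    )


# ---------------------------------------------------------------------------
# SBML I/O
# ---------------------------------------------------------------------------

_NOTES_GA_RE = re.compile(r"GENE[ _]?ASSOCIATION\s*:\s*([^<\n]*)", re.IGNORECASE)
_NOTES_SS_RE = re.compile(r"SUBSYSTEM\s*:\s*([^<\n]*)", re.IGNORECASE)


def _fbc_assoc_to_string(assoc) -> str:
    """Render an fbc association subtree as a parenthesised and/or string."""
    if assoc is None:
        return ""
    if assoc.isGeneProductRef():
        return assoc.getGeneProduct()
    if assoc.isFbcAnd():
        op = " and "
    elif assoc.isFbcOr():
        op = " or "
    else:  # pragma: no cover - unknown node type
        return ""
    parts = [_fbc_assoc_to_string(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
    return "(" + op.join(p for p in parts if p) + ")"


def _finite(value: float, cap: float) -> float:
    if value is None or math.isinf(value):
        return math.copysign(cap, value if value is not None else 1.0)
    return float(value)


def read_sbml(path: str, default_bound: float = DEFAULT_BOUND) -> MetabolicModel:
    """Read an SBML model, preserving bounds, GPRs, subsystems and objective.

    Both GPR encodings in the wild for the yeast consensus-model lineage are
    accepted: ``fbc:geneProductAssociation`` (preferred when both present) and
    a notes-field ``GENE_ASSOCIATION:`` string.  Bounds come from fbc flux
    bound parameters or, for level-2 files, COBRA-style kinetic-law
    parameters.  Infinite bounds are capped at ``default_bound``.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ModelValidationError
        If no reaction carries a nonzero objective coefficient.
    """
    import os

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelValidationError(
            f"SBML parse errors in {path}: "
            + "; ".join(
                doc.getError(i).getMessage()
                for i in range(doc.getNumErrors())
                if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
            )
        )
    sm = doc.getModel()
    if sm is None:
        raise ModelValidationError(f"no model element in {path}")

    mets = [
        Metabolite(id=s.getId(), name=s.getName() or "", compartment=s.getCompartment() or "")
        for s in (sm.getSpecies(i) for i in range(sm.getNumSpecies()))
        if not s.getBoundaryCondition()
    ]
    met_ids = {m.id for m in mets}

    mplug = sm.getPlugin("fbc")
    objective_coefs: dict[str, float] = {}
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        for i in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(i)
            objective_coefs[fo.getReaction()] = fo.getCoefficient()

    reactions = []
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            if ref.getSpecies() in met_ids:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            if ref.getSpecies() in met_ids:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0}

        lb, ub = None, None
        obj_coef = objective_coefs.get(sr.getId(), 0.0)
        rplug = sr.getPlugin("fbc")
        if rplug is not None:
            for attr, setter in ((rplug.getLowerFluxBound(), "lb"), (rplug.getUpperFluxBound(), "ub")):
                if attr:
                    p = sm.getParameter(attr)
                    if p is not None:
                        if setter == "lb":
                            lb = p.getValue()
                        else:
                            ub = p.getValue()
        kl = sr.getKineticLaw()
        if kl is not None:
            for pname, target in (("LOWER_BOUND", "lb"), ("UPPER_BOUND", "ub")):
                p = kl.getParameter(pname) or kl.getLocalParameter(pname)
                if p is not None:
                    if target == "lb" and lb is None:
                        lb = p.getValue()
                    elif target == "ub" and ub is None:
                        ub = p.getValue()
            p = kl.getParameter("OBJECTIVE_COEFFICIENT") or kl.getLocalParameter("OBJECTIVE_COEFFICIENT")
            if p is not None and sr.getId() not in objective_coefs:
                obj_coef = p.getValue()
        if lb is None:
            lb = 0.0 if not sr.getReversible() else -default_bound
        if ub is None:
            ub = default_bound
        lb = _finite(lb, default_bound)
        ub = _finite(ub, default_bound)

        gpr_string = ""
        if rplug is not None and rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            gpr_string = _fbc_assoc_to_string(assoc)
            # fbc gene product ids -> labels where set
            if mplug is not None:
                for k in range(mplug.getNumGeneProducts()):
                    gp = mplug.getGeneProduct(k)
                    label = gp.getLabel() or gp.getId()
                    if label != gp.getId():
                        gpr_string = re.sub(rf"\b{re.escape(gp.getId())}\b", label, gpr_string)
        notes = sr.getNotesString() if sr.isSetNotes() else ""
        if not gpr_string and notes:
            m = _NOTES_GA_RE.search(notes)
            if m:
                gpr_string = m.group(1).strip()
        subsystem = ""
        if notes:
            m = _NOTES_SS_RE.search(notes)
            if m:
                subsystem = m.group(1).strip()

        try:
            gpr = parse_gpr(gpr_string)
        except GPRParseError as exc:
            logger.warning("unparseable GPR for reaction %r (%s); kept with empty GPR", sr.getId(), exc)
            gpr = None

        reactions.append(
            Reaction(
                id=sr.getId(),
                name=sr.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                subsystem=subsystem,
                objective_coefficient=obj_coef,
            )
        )

    model = MetabolicModel(id=sm.getId() or "model", metabolites=mets, reactions=reactions)
    if not model.objective_reactions:
        raise ModelValidationError(f"model {model.id!r} has no objective reaction")
    return model


def _string_to_fbc_assoc(expr: GPRExpression, parent, gp_ids: dict[str, str]):
    if isinstance(expr, GeneLeaf):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(gp_ids[expr.gene])
        return
    node = parent.createAnd() if expr.op == "and" else parent.createOr()
    for o in expr.operands:
        _string_to_fbc_assoc(o, node, gp_ids)


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write the model as SBML level 3 with the fbc (v2) package.

    GPRs go to ``fbc:geneProductAssociation``; subsystems to the reaction
    notes (``SUBSYSTEM:`` line), mirroring how they are read back.
    """
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment or "c" for m in model.metabolites} | {"c"})
    for cid in compartments:
        c = sm.createCompartment()
        c.setId(cid)
        c.setConstant(True)

    for m in model.metabolites:
        s = sm.createSpecies()
        s.setId(m.id)
        s.setName(m.name)
        s.setCompartment(m.compartment or "c")
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)

    def _sanitize(gene: str) -> str:
        return "G_" + re.sub(r"[^A-Za-z0-9_]", "_", gene)

    gp_ids: dict[str, str] = {}
    for g in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gid = _sanitize(g)
        gp.setId(gid)
        gp.setLabel(g)
        gp_ids[g] = gid

    # shared bound parameters, one per distinct value
    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"FB_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    mplug.setActiveObjectiveId("obj")

    for r in model.reactions:
        sr = sm.createReaction()
        sr.setId(r.id)
        sr.setName(r.name)
        sr.setReversible(r.lower_bound < 0)
        sr.setFast(False)
        for mid, coef in sorted(r.stoichiometry.items()):
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(r.lower_bound))
        rplug.setUpperFluxBound(_bound_param(r.upper_bound))
        if r.gpr is not None:
            ga = rplug.createGeneProductAssociation()
            _string_to_fbc_assoc(r.gpr, ga, gp_ids)
        if r.subsystem:
            sr.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml"><p>SUBSYSTEM: {r.subsystem}</p></body>'
            )
        if r.objective_coefficient != 0:
            fo = obj.createFluxObjective()
            fo.setReaction(r.id)
            fo.setCoefficient(r.objective_coefficient)

    libsbml.writeSBMLToFile(doc, path)


# ---------------------------------------------------------------------------
# Native JSON dump (fixtures, diffing)
# ---------------------------------------------------------------------------


def model_to_json(model: MetabolicModel) -> str:
    payload = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment} for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string() if r.gpr else "",
                "subsystem": r.subsystem,
                "objective_coefficient": r.objective_coefficient,
            }
            for r in model.reactions
        ],
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def model_from_json(text: str) -> MetabolicModel:
    payload = json.loads(text)
    return MetabolicModel(
        id=payload["id"],
        metabolites=[Metabolite(**m) for m in payload["metabolites"]],
        reactions=[
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gpr=parse_gpr(r.get("gpr", "")),
                subsystem=r.get("subsystem", ""),
                objective_coefficient=float(r.get("objective_coefficient", 0.0)),
            )
            for r in payload["reactions"]
        ],
    )
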