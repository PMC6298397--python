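"""Model serialization: tabular reaction lists and SBML Level 3 + FBC.

The table dialect mirrors a supplementary-table layout: one reaction per
row with an equation string such as ``g6p + atp -> f16bp + adp``.
Coefficients are optional (default 1), a compartment suffix like ``[e]``
is part of the metabolite id, ``<=>`` marks reversible and ``->``/``=>``
irreversible reactions.  An exchange row leaves one side empty
(``glc-D[e] <=>``).

SBML I/O uses python-libsbml with the FBC v2 package: bounds become flux-
bound parameters, GPR rules become gene-product associations, the biomass
(and optional EPS) objectives are stored in the objective list, and the
subsystem label travels in the reaction notes.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import libsbml
import pandas as pd

from .core import MetabolicModel, Metabolite, ModelStructureError, Reaction
from .gpr import BoolOp, GeneRef, GprNode, GprRule
from .media import DEFAULT_FLUX_CAP

ARROWS = {"<=>": True, "->": False, "=>": False}

_DEFAULT_COLUMNS = {
    "reaction_id": ("reaction_id", "id", "rxn", "abbreviation"),
    "equation": ("equation", "reaction", "formula"),
    "lower_bound": ("lower_bound", "lb"),
    "upper_bound": ("upper_bound", "ub"),
    "gpr": ("gpr", "gene_association", "genes"),
    "subsystem": ("subsystem", "pathway"),
    "name": ("name", "description"),
}


class TableFormatError(ValueError):
    pass


def parse_equation(text: str, row: int | None = None) -> tuple[dict[str, float], bool]:
    """Parse an equation string into (stoichiometry, reversible)."""

    def fail(msg: str) -> TableFormatError:
        where = f" (row {row})" if row is not None else ""
        return TableFormatError(f"{msg}{where}: {text!r}")

    arrow = None
    for token in ARROWS:
        if token in text:
            arrow = token
            break
    if arrow is None:
        raise fail("no arrow token (<=>, -> or =>) in equation")
    lhs, rhs = text.split(arrow, 1)

    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in re.split(r"\s+\+\s+", side):
            parts = term.split()
            if not parts:
                continue
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            else:
                try:
                    coeff = float(parts[0])
                except ValueError:
                    raise fail(f"coefficient {parts[0]!r} is not a number") from None
                met = " ".join(parts[1:])
                if coeff <= 0:
                    raise fail(f"coefficient for {met!r} must be positive")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise fail("equation has no metabolites")
    return stoich, ARROWS[arrow]


def format_equation(stoich: Mapping[str, float], reversible: bool) -> str:
    def side(items: list[tuple[str, float]]) -> str:
        parts = []
        for met, coeff in items:
            c = abs(coeff)
            parts.append(met if c == 1 else f"{c:g} {met}")
        return " + ".join(parts)

    lhs = [(m, c) for m, c in stoich.items() if c < 0]
    rhs = [(m, c) for m, c in stoich.items() if c > 0]
    arrow = "<=>" if reversible else "->"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


def _resolve_columns(
    columns: list[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    lower = {c.strip().lower(): c for c in columns}
    resolved: dict[str, str] = {}
    for field, aliases in _DEFAULT_COLUMNS.items():
        if column_map and field in column_map:
            resolved[field] = column_map[field]
            continue
        for alias in aliases:
            if alias in lower:
                resolved[field] = lower[alias]
                break
    for required in ("reaction_id", "equation"):
        if required not in resolved:
            raise TableFormatError(f"table is missing a {required!r} column")
    return resolved


def read_model_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    biomass_reaction_id: str | None = None,
    eps_reaction_id: str | None = None,
    sep: str = "\t",
) -> MetabolicModel:
    """Load a model from a delimited reaction table.

    ``column_map`` overrides the default header aliases (spec field name ->
    actual column name) so externally formatted supplementary tables can be
    adapted without editing the file.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = _resolve_columns(list(df.columns), column_map)
    model = MetabolicModel(id=Path(path).stem)

    for i, rec in enumerate(df.to_dict("records")):
        row_no = i + 2  # 1-based plus header
        rid = rec[cols["reaction_id"]].strip()
        if not rid:
            raise TableFormatError(f"empty reaction id (row {row_no})")
        stoich, reversible = parse_equation(rec[cols["equation"]], row=row_no)
        lb_text = rec.get(cols.get("lower_bound", ""), "").strip()
        ub_text = rec.get(cols.get("upper_bound", ""), "").strip()
        lb = float(lb_text) if lb_text else (-DEFAULT_FLUX_CAP if reversible else 0.0)
        ub = float(ub_text) if ub_text else DEFAULT_FLUX_CAP
        gpr_text = rec.get(cols.get("gpr", ""), "").strip()
        subsystem = rec.get(cols.get("subsystem", ""), "").strip() or "other"
        name = rec.get(cols.get("name", ""), "").strip()
        for mid in stoich:
            if mid not in model.metabolites:
                model.add_metabolite(Metabolite(mid))
        try:
            model.add_reaction(
                Reaction(
                    rid,
                    stoich,
                    lower_bound=lb,
                    upper_bound=ub,
                    name=name,
                    gpr=GprRule.from_string(gpr_text),
                    subsystem=subsystem,
                )
            )
        except ModelStructureError as exc:
            raise TableFormatError(f"{exc} (row {row_no})") from exc

    model.biomass_reaction_id = biomass_reaction_id or _autodetect(model, "biomass")
    model.eps_reaction_id = eps_reaction_id or _autodetect(model, "eps")
    model.validate()
    return model


def _autodetect(model: MetabolicModel, token: str) -> str | None:
    hits = [rid for rid in model.reactions if token in rid.lower()]
    return hits[0] if hits else None


def write_model_table(model: MetabolicModel, path: str | Path, sep: str = "\t") -> None:
    rows = []
    for rid, rxn in model.reactions.items():
        rows.append(
            {
                "reaction_id": rid,
                "equation": format_equation(rxn.stoichiometry, rxn.reversible),
                "lower_bound": rxn.lower_bound,
                "upper_bound": rxn.upper_bound,
                "gpr": rxn.gpr.to_string(),
                "subsystem": rxn.subsystem,
                "name": rxn.name,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# SBML Level 3 Version 1 with FBC v2
# ---------------------------------------------------------------------------

class SbmlError(ValueError):
    pass


def _encode_sid(raw: str, prefix: str) -> str:
    out = []
    for ch in raw:
        if ch.isalnum() or ch == "_":
            out.append(ch)
        else:
            out.append(f"__{ord(ch)}__")
    return prefix + "".join(out)


_DECODE_RE = re.compile(r"__(\d+)__")


def _decode_sid(sid: str, prefix: str) -> str:
    if sid.startswith(prefix):
        sid = sid[len(prefix):]
    return _DECODE_RE.sub(lambda m: chr(int(m.group(1))), sid)


def _formula_string(formula: Mapping[str, int]) -> str:
    order = sorted(formula, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{e}{formula[e] if formula[e] != 1 else ''}" for e in order)


def _gpr_to_association(node: GprNode, plugin, parent=None):
    if parent is None:
        parent = plugin.createGeneProductAssociation()
    if isinstance(node, GeneRef):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(_encode_sid(node.gene, "G_"))
    elif node.op == "and":
        op = parent.createAnd()
        for child in node.children:
            _gpr_to_association(child, plugin, op)
    else:
        op = parent.createOr()
        for child in node.children:
            _gpr_to_association(child, plugin, op)
    return parent


def _association_to_gpr(assoc) -> GprNode:
    if assoc.isGeneProductRef():
        return GeneRef(_decode_sid(assoc.getGeneProduct(), "G_"))
    op = "and" if assoc.isFbcAnd() else "or"
    children = tuple(
        _association_to_gpr(assoc.getAssociation(i))
        for i in range(assoc.getNumAssociations())
    )
    return BoolOp(op, children)


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Serialize to SBML L3V1 with the FBC v2 package."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_encode_sid(model.id, "") or "model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(False)

    compartments = {m.compartment or "c" for m in model.metabolites.values()}
    for comp in sorted(compartments):
        c = sm.createCompartment()
        c.setId(_encode_sid(comp, "C_"))
        c.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(_encode_sid(met.id, "M_"))
        sp.setName(met.name or met.id)
        sp.setCompartment(_encode_sid(met.compartment or "c", "C_"))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(_formula_string(met.formula))
        if met.charge is not None:
            splug.setCharge(int(met.charge))

    genes = sorted(model.genes)
    for gene in genes:
        gp = mplug.createGeneProduct()
        gp.setId(_encode_sid(gene, "G_"))
        gp.setLabel(gene)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rid, rxn in model.reactions.items():
        sr = sm.createReaction()
        sr.setId(_encode_sid(rid, "R_"))
        sr.setName(rxn.name or rid)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        sr.setNotes(
            f'<body xmlns="http://www.w3.org/1999/xhtml">'
            f"<p>SUBSYSTEM: {rxn.subsystem}</p></body>"
        )
        for mid, coeff in rxn.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(_encode_sid(mid, "M_"))
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr:
            _gpr_to_association(rxn.gpr.root, rplug)

    for obj_id, rid, active in (
        ("obj_biomass", model.biomass_reaction_id, True),
        ("obj_eps", model.eps_reaction_id, False),
    ):
        if rid is None:
            continue
        obj = mplug.createObjective()
        obj.setId(obj_id)
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_encode_sid(rid, "R_"))
        fo.setCoefficient(1.0)
        if active:
            mplug.setActiveObjectiveId(obj_id)

    libsbml.writeSBMLToFile(doc, str(path))


def read_sbml(path: str | Path) -> MetabolicModel:
    """Parse an SBML L3+FBC document back into a :class:`MetabolicModel`."""
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        messages = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise SbmlError("invalid SBML: " + "; ".join(messages))
    sm = doc.getModel()
    if sm is None:
        raise SbmlError(f"no model element in {path}")
    mplug = sm.getPlugin("fbc")

    model = MetabolicModel(id=_decode_sid(sm.getId(), ""))
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula() or None
            if splug.isSetCharge():
                charge = splug.getCharge()
        model.add_metabolite(
            Metabolite(
                _decode_sid(sp.getId(), "M_"),
                name=sp.getName(),
                compartment=_decode_sid(sp.getCompartment(), "C_"),
                formula=formula,
                charge=charge,
            )
        )

    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }

    subsystem_re = re.compile(r"SUBSYSTEM:\s*([^<\s][^<]*)")
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = _decode_sid(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = _decode_sid(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lb = params.get(rplug.getLowerFluxBound(), -DEFAULT_FLUX_CAP)
        ub = params.get(rplug.getUpperFluxBound(), DEFAULT_FLUX_CAP)
        gpr = GprRule(None)
        gpa = rplug.getGeneProductAssociation()
        if gpa is not None and gpa.getAssociation() is not None:
            gpr = GprRule(_association_to_gpr(gpa.getAssociation()))
        subsystem = "other"
        if sr.isSetNotes():
            m = subsystem_re.search(sr.getNotesString())
            if m:
                subsystem = m.group(1).strip()
        model.add_reaction(
            Reaction(
                _decode_sid(sr.getId(), "R_"),
                stoich,
                lower_bound=lb,
                upper_bound=ub,
                name=sr.getName(),
                gpr=gpr,
                subsystem=subsystem,
            )
        )

    if mplug is not None:
        for i in range(mplug.getNumObjectives()):
            obj = mplug.getObjective(i)
            if obj.getNumFluxObjectives() == 0:
                continue
            rid = _decode_sid(obj.getFluxObjective(0).getReaction(), "R_")
            if obj.getId() == mplug.getActiveObjectiveId() or obj.getId() == "obj_biomass":
                model.biomass_reaction_id = rid
            elif obj.getId() == "obj_eps":
                model.eps_reaction_id = rid
    model.validate()
    return model
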