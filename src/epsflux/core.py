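"""Core stoichiometric-model data structures and structural QC.

A metabolic model is a set of metabolites, a set of bounded reactions over
them (columns of the stoichiometric matrix S), a gene inventory wired to
reactions through GPR rules, and designated biomass / product objectives.
Coefficient convention: negative = consumed, positive = produced; a reaction
is reversible iff its lower bound is negative.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from .gpr import GprRule

#: subsystem labels used for reporting breakdowns
SUBSYSTEMS = ("LM", "AM", "CM", "TR", "MC", "NM", "EM", "GB", "MT", "ER")

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
#: id prefixes of boundary pseudo-reactions exempt from mass/charge balance
BOUNDARY_PREFIXES = ("EX_", "DM_", "SK_", "sink_")


class ModelStructureError(ValueError):
    """Violated structural invariant (duplicate id, dangling reference, ...)."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string like ``C6H12O6`` into counts."""
    counts: dict[str, int] = {}
    consumed = 0
    for m in _FORMULA_RE.finditer(formula):
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        consumed += len(m.group(0))
    if consumed != len(formula.replace(" ", "")):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: dict[str, int] | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelStructureError("metabolite id must be non-empty")
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)
        if self.formula is not None and any(v < 0 for v in self.formula.values()):
            raise ModelStructureError(f"negative element count in {self.id}")


@dataclass
class Reaction:
    """A bounded reaction column.

    ``stoichiometry`` maps metabolite id -> coefficient.  Bounds are in
    mmol/gDW/h (the biomass pseudo-reaction is in 1/h).  An exchange
    reaction touches exactly one metabolite and crosses the system boundary;
    uptake is negative flux by convention.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""
    gpr: GprRule = field(default_factory=GprRule)
    subsystem: str = "other"

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelStructureError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelStructureError(f"reaction {self.id} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelStructureError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if isinstance(self.gpr, str):
            self.gpr = GprRule.from_string(self.gpr)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def genes(self) -> frozenset[str]:
        return self.gpr.genes

    def copy(self) -> "Reaction":
        r = _copy.copy(self)
        r.stoichiometry = dict(self.stoichiometry)
        return r


class MetabolicModel:
    """Ordered collections of metabolites and reactions plus gene inventory."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        genes: Iterable[str] | None = None,
        biomass_reaction_id: str | None = None,
        eps_reaction_id: str | None = None,
        id: str = "model",
    ) -> None:
        self.id = id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)
        self.genes: set[str] = set(genes) if genes is not None else set()
        for r in self.reactions.values():
            self.genes |= r.genes
        self.biomass_reaction_id = biomass_reaction_id
        self.eps_reaction_id = eps_reaction_id

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelStructureError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelStructureError(f"duplicate reaction id {rxn.id!r}")
        missing = set(rxn.stoichiometry) - set(self.metabolites)
        if missing:
            raise ModelStructureError(
                f"reaction {rxn.id} references unknown metabolites {sorted(missing)}"
            )
        self.reactions[rxn.id] = rxn
        if hasattr(self, "genes"):
            self.genes |= rxn.genes

    def validate(self) -> None:
        """Check all structural invariants; raise ModelStructureError on failure."""
        for r in self.reactions.values():
            missing = set(r.stoichiometry) - set(self.metabolites)
            if missing:
                raise ModelStructureError(
                    f"reaction {r.id} references unknown metabolites {sorted(missing)}"
                )
            if not r.genes <= self.genes:
                raise ModelStructureError(
                    f"reaction {r.id} GPR uses genes outside the model inventory"
                )
        if self.biomass_reaction_id is not None and (
            self.biomass_reaction_id not in self.reactions
        ):
            raise ModelStructureError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        if self.eps_reaction_id is not None and self.eps_reaction_id not in self.reactions:
            raise ModelStructureError(f"EPS reaction {self.eps_reaction_id!r} not in model")

    def copy(self) -> "MetabolicModel":
        m = MetabolicModel(
            metabolites=[_copy.copy(x) for x in self.metabolites.values()],
            reactions=[r.copy() for r in self.reactions.values()],
            genes=set(self.genes),
            biomass_reaction_id=self.biomass_reaction_id,
            eps_reaction_id=self.eps_reaction_id,
            id=self.id,
        )
        return m

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MetabolicModel({self.id!r}: {len(self.genes)} genes, "
            f"{len(self.metabolites)} metabolites, {len(self.reactions)} reactions)"
        )


def assemble_stoichiometric_matrix(
    model: MetabolicModel,
) -> tuple[sparse.csc_matrix, dict[str, int], dict[str, int]]:
    """Build the sparse stoichiometric matrix S.

    Rows are metabolites, columns are reactions, in model insertion order.
    Returns ``(S, metabolite_index, reaction_index)`` where the index maps
    are id -> row/column bijections.
    """
    met_index = {mid: i for i, mid in enumerate(model.metabolites)}
    rxn_index = {rid: j for j, rid in enumerate(model.reactions)}
    rows, cols, vals = [], [], []
    for rid, rxn in model.reactions.items():
        j = rxn_index[rid]
        for mid, coeff in rxn.stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            vals.append(float(coeff))
    S = sparse.csc_matrix(
        (vals, (rows, cols)), shape=(len(met_index), len(rxn_index))
    )
    return S, met_index, rxn_index


@dataclass
class BalanceEntry:
    reaction_id: str
    status: str  # balanced | imbalanced | unverifiable | exempt
    element_imbalance: dict[str, float] = field(default_factory=dict)
    charge_imbalance: float | None = None


def _is_balance_exempt(model: MetabolicModel, rxn: Reaction) -> bool:
    if rxn.is_exchange:
        return True
    if rxn.id in (model.biomass_reaction_id, model.eps_reaction_id):
        return True
    return rxn.id.startswith(BOUNDARY_PREFIXES) or "biomass" in rxn.id.lower()


def check_mass_charge_balance(
    model: MetabolicModel, tol: float = 1e-6
) -> list[BalanceEntry]:
    """Report elemental and charge imbalances for every reaction.

    Boundary pseudo-reactions (exchanges, demands/sinks, biomass, EPS target)
    are intentionally unbalanced and reported ``exempt``.  A reaction whose
    metabolites all lack formulas cannot be checked and is reported
    ``unverifiable`` rather than imbalanced.
    """
    report: list[BalanceEntry] = []
    for rxn in model.reactions.values():
        if _is_balance_exempt(model, rxn):
            report.append(BalanceEntry(rxn.id, "exempt"))
            continue
        mets = [model.metabolites[mid] for mid in rxn.stoichiometry]
        if all(m.formula is None for m in mets):
            report.append(BalanceEntry(rxn.id, "unverifiable"))
            continue
        elements: dict[str, float] = {}
        charge = 0.0
        charge_known = True
        for mid, coeff in rxn.stoichiometry.items():
            met = model.metabolites[mid]
            for elem, cnt in (met.formula or {}).items():
                elements[elem] = elements.get(elem, 0.0) + coeff * cnt
            if met.charge is None:
                charge_known = False
            else:
                charge += coeff * met.charge
        imbalance = {e: v for e, v in elements.items() if abs(v) > tol}
        charge_off = charge if (charge_known and abs(charge) > tol) else None
        if imbalance or charge_off is not None:
            report.append(
                BalanceEntry(rxn.id, "imbalanced", imbalance, charge_off)
            )
        else:
            report.append(BalanceEntry(rxn.id, "balanced"))
    return report


def find_dead_ends(model: MetabolicModel) -> set[str]:
    """Metabolites that can only be produced or only consumed.

    Direction is taken from bounds: a reaction with ``ub > 0`` can run
    forward, one with ``lb < 0`` backward.  An exchange reaction can both
    supply and drain its metabolite (its bounds decide at simulation time,
    but structurally the route exists), so exchange-covered metabolites are
    never dead ends.
    """
    producible: set[str] = set()
    consumable: set[str] = set()
    for rxn in model.reactions.values():
        if rxn.is_exchange:
            mid = next(iter(rxn.stoichiometry))
            producible.add(mid)
            consumable.add(mid)
            continue
        fwd = rxn.upper_bound > 0
        bwd = rxn.lower_bound < 0
        for mid, coeff in rxn.stoichiometry.items():
            if coeff > 0:
                if fwd:
                    producible.add(mid)
                if bwd:
                    consumable.add(mid)
            elif coeff < 0:
                if fwd:
                    consumable.add(mid)
                if bwd:
                    producible.add(mid)
    return {
        mid
        for mid in model.metabolites
        if mid not in producible or mid not in consumable
    }


def reactions_from_matrix(
    S: sparse.spmatrix,
    met_index: Mapping[str, int],
    rxn_index: Mapping[str, int],
) -> dict[str, dict[str, float]]:
    """Invert :func:`assemble_stoichiometric_matrix` back to stoichiometries."""
    met_ids = {i: mid for mid, i in met_index.items()}
    out: dict[str, dict[str, float]] = {rid: {} for rid in rxn_index}
    coo = sparse.coo_matrix(S)
    rid_of = {j: rid for rid, j in rxn_index.items()}
    for i, j, v in zip(coo.row, coo.col, coo.data):
        if v != 0:
            out[rid_of[j]][met_ids[i]] = float(v)
    return out
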