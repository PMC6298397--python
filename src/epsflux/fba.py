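"""Flux balance analysis: the steady-state LP and its parsimonious variant.

FBA maximizes the flux of an objective reaction over the polytope
``{v : S v = 0, lb <= v <= ub}``.  The LP is solved with HiGHS through
scipy.  Because FBA optima are generically non-unique, downstream code
that needs a *reproducible* flux vector (e.g. the MOMA reference) uses
:func:`parsimonious_reference`, which re-minimizes the total absolute
flux while holding the objective at >= 99.99% of its optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse

from .core import MetabolicModel, assemble_stoichiometric_matrix
from .media import MediumDefinition

#: numeric floor distinguishing real flux from solver dust
FLUX_EPS = 1e-6
#: fraction of the FBA optimum retained during parsimonious minimization
PFBA_FRACTION = 0.9999

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_UNBOUNDED = "unbounded"

_LINPROG_STATUS = {0: STATUS_OPTIMAL, 2: STATUS_INFEASIBLE, 3: STATUS_UNBOUNDED}


class FbaError(RuntimeError):
    """Raised when a solve that must succeed does not."""


@dataclass
class FluxDistribution:
    """Solver output: per-reaction fluxes plus objective metadata."""

    fluxes: dict[str, float] = field(default_factory=dict)
    objective_id: str = ""
    objective_value: float = float("nan")
    status: str = STATUS_INFEASIBLE

    @property
    def optimal(self) -> bool:
        return self.status == STATUS_OPTIMAL

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


def apply_medium(
    model: MetabolicModel,
    medium: MediumDefinition,
    missing: str = "error",
) -> MetabolicModel:
    """Return a copy of *model* with exchange bounds set by *medium*.

    Every exchange listed in the medium gets lower bound ``-limit``;
    every unlisted exchange has uptake closed (lower bound 0).  Secretion
    is capped at the medium's secretion cap when unconstrained.  Non-
    exchange bounds are untouched.  ``missing`` controls what happens when
    the medium names an exchange absent from the model ("error"|"ignore").
    """
    new = model.copy()
    exchange_ids = {r.id for r in new.exchanges}
    for rid in medium.uptake_limits:
        if rid not in exchange_ids:
            if rid in new.reactions:
                raise ValueError(f"medium names non-exchange reaction {rid!r}")
            if missing == "error":
                raise ValueError(f"medium names unknown exchange {rid!r}")
    for rid in exchange_ids:
        rxn = new.reactions[rid]
        rxn.lower_bound = -float(medium.uptake_limits.get(rid, 0.0))
        if medium.unconstrained_secretion:
            rxn.upper_bound = medium.secretion_cap
    return new


def solve_fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    direction: str = "max",
) -> FluxDistribution:
    """Solve the FBA linear program for one objective reaction.

    Infeasible and unbounded outcomes are reported in ``status``, never
    silently mapped to zero flux.
    """
    objective_id = objective_id or model.biomass_reaction_id
    if objective_id not in model.reactions:
        raise KeyError(f"objective reaction {objective_id!r} not in model")
    S, _, rxn_index = assemble_stoichiometric_matrix(model)
    n = S.shape[1]
    c = np.zeros(n)
    c[rxn_index[objective_id]] = -1.0 if direction == "max" else 1.0
    bounds = [
        (r.lower_bound, r.upper_bound) for r in model.reactions.values()
    ]
    res = optimize.linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": 1e-9, "dual_feasibility_tolerance": 1e-9},
    )
    status = _LINPROG_STATUS.get(res.status, STATUS_INFEASIBLE)
    if status != STATUS_OPTIMAL:
        return FluxDistribution({}, objective_id, float("nan"), status)
    fluxes = {rid: float(res.x[j]) for rid, j in rxn_index.items()}
    return FluxDistribution(fluxes, objective_id, float(fluxes[objective_id]), status)


def parsimonious_reference(
    model: MetabolicModel,
    objective_id: str | None = None,
    fraction: float = PFBA_FRACTION,
) -> FluxDistribution:
    """Two-step LP: fix the objective near its optimum, minimize total |flux|.

    Among flux vectors attaining at least ``fraction`` of the FBA optimum,
    returns one minimizing the L1 norm (flux splitting ``v = p - q`` with
    ``p, q >= 0``).  Futile cycles and arbitrary splits across parallel
    paths are thereby suppressed, giving a reproducible reference vector.
    """
    objective_id = objective_id or model.biomass_reaction_id
    first = solve_fba(model, objective_id)
    if not first.optimal:
        return first
    S, _, rxn_index = assemble_stoichiometric_matrix(model)
    m, n = S.shape
    # variables x = [p; q], v = p - q
    A_eq = sparse.hstack([S, -S]).tocsc()
    b_eq = np.zeros(m)
    c = np.ones(2 * n)
    lb = np.zeros(2 * n)
    ub = np.full(2 * n, np.inf)
    extra_rows = []
    extra_rhs = []
    for rid, j in rxn_index.items():
        rxn = model.reactions[rid]
        ub[j] = max(rxn.upper_bound, 0.0)
        ub[n + j] = max(-rxn.lower_bound, 0.0)
        # splitting relaxes one-sided bounds that exclude zero; restore them
        if rxn.lower_bound > 0:  # -(p - q) <= -lb
            extra_rows.append((j, -1.0, n + j, 1.0))
            extra_rhs.append(-rxn.lower_bound)
        if rxn.upper_bound < 0:  # p - q <= ub
            extra_rows.append((j, 1.0, n + j, -1.0))
            extra_rhs.append(rxn.upper_bound)
    # objective retention: v_obj >= fraction * optimum (sign-aware)
    j_obj = rxn_index[objective_id]
    target = first.objective_value
    floor = fraction * target if target >= 0 else target / fraction
    extra_rows.append((j_obj, -1.0, n + j_obj, 1.0))
    extra_rhs.append(-floor)
    rows, cols, vals = [], [], []
    for i, (ja, va, jb, vb) in enumerate(extra_rows):
        rows += [i, i]
        cols += [ja, jb]
        vals += [va, vb]
    A_ub = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(extra_rows), 2 * n)
    )
    b_ub = np.array(extra_rhs)
    res = optimize.linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status != 0:
        raise FbaError(
            f"parsimonious step failed with status {res.status} ({res.message})"
        )
    v = res.x[:n] - res.x[n:]
    fluxes = {rid: float(v[j]) for rid, j in rxn_index.items()}
    return FluxDistribution(
        fluxes, objective_id, float(fluxes[objective_id]), STATUS_OPTIMAL
    )


def steady_state_residual(model: MetabolicModel, dist: FluxDistribution) -> float:
    """max |S v| for a flux distribution — should be ~0 for any solution."""
    S, _, rxn_index = assemble_stoichiometric_matrix(model)
    v = np.zeros(S.shape[1])
    for rid, j in rxn_index.items():
        v[j] = dist.fluxes.get(rid, 0.0)
    return float(np.abs(S @ v).max()) if S.shape[0] else 0.0
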