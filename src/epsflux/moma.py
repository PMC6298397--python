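"""Minimization of metabolic adjustment (MOMA).

After a perturbation (knockout or forced overexpression), MOMA predicts
the new flux state as the Euclidean projection of the wild-type reference
distribution onto the perturbed flux polytope:

    min   sum_i (v_i - v_ref,i)^2
    s.t.  S v = 0,  lb <= v <= ub

a strictly convex QP with a unique minimizer.  The QP is solved with OSQP
when available (polished, tight tolerances) and otherwise with scipy's
trust-constr solver; both paths verify the steady-state residual.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, sparse

from .core import MetabolicModel, assemble_stoichiometric_matrix
from .fba import (
    STATUS_INFEASIBLE,
    STATUS_OPTIMAL,
    FluxDistribution,
)

try:  # pragma: no cover - environment probe
    import osqp

    _HAVE_OSQP = True
except ImportError:  # pragma: no cover
    _HAVE_OSQP = False


def _check_feasible(S, lb, ub) -> bool:
    res = optimize.linprog(
        np.zeros(S.shape[1]),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return res.status == 0


def _solve_qp_osqp(S, ref, lb, ub):
    n = S.shape[1]
    P = sparse.eye(n, format="csc") * 2.0
    q = -2.0 * ref
    A = sparse.vstack([S, sparse.eye(n)], format="csc")
    l = np.concatenate([np.zeros(S.shape[0]), lb])
    u = np.concatenate([np.zeros(S.shape[0]), ub])
    prob = osqp.OSQP()
    prob.setup(
        P=P, q=q, A=A, l=l, u=u,
        eps_abs=1e-10, eps_rel=1e-10, max_iter=200_000,
        polish=True, verbose=False,
    )
    try:
        res = prob.solve(raise_error=False)
    except TypeError:  # older osqp releases lack the keyword
        res = prob.solve()
    status = res.info.status.lower()
    if "solved" not in status:
        return None
    return np.asarray(res.x, dtype=float)


def _solve_qp_scipy(S, ref, lb, ub):
    n = S.shape[1]
    Sd = S.toarray()

    def fun(v):
        d = v - ref
        return float(d @ d)

    def jac(v):
        return 2.0 * (v - ref)

    x0 = np.clip(ref, lb, ub)
    res = optimize.minimize(
        fun,
        x0,
        jac=jac,
        hess=lambda v: 2.0 * np.eye(n),
        method="trust-constr",
        constraints=[optimize.LinearConstraint(Sd, 0.0, 0.0)],
        bounds=optimize.Bounds(lb, ub),
        options={"gtol": 1e-12, "xtol": 1e-12, "maxiter": 5000},
    )
    return np.asarray(res.x, dtype=float)


def solve_moma(
    model: MetabolicModel,
    reference: FluxDistribution,
    objective_id: str | None = None,
) -> FluxDistribution:
    """Project *reference* onto the flux polytope of (possibly perturbed) *model*.

    ``objective_id`` only labels which flux is reported as the headline
    objective value (defaults to the reference's objective).  Infeasible
    perturbed polytopes are reported via ``status``.
    """
    S, _, rxn_index = assemble_stoichiometric_matrix(model)
    n = S.shape[1]
    lb = np.empty(n)
    ub = np.empty(n)
    ref = np.zeros(n)
    for rid, j in rxn_index.items():
        rxn = model.reactions[rid]
        lb[j] = rxn.lower_bound
        ub[j] = rxn.upper_bound
        ref[j] = reference.fluxes.get(rid, 0.0)

    objective_id = objective_id or reference.objective_id
    if not _check_feasible(S, lb, ub):
        return FluxDistribution({}, objective_id, float("nan"), STATUS_INFEASIBLE)

    v = _solve_qp_osqp(S, ref, lb, ub) if _HAVE_OSQP else None
    if v is None:
        v = _solve_qp_scipy(S, ref, lb, ub)
    # clip solver dust outside bounds
    v = np.clip(v, lb, ub)
    fluxes = {rid: float(v[j]) for rid, j in rxn_index.items()}
    obj = fluxes.get(objective_id, float("nan"))
    return FluxDistribution(fluxes, objective_id, float(obj), STATUS_OPTIMAL)


def moma_distance(a: FluxDistribution, b: FluxDistribution) -> float:
    """Euclidean distance between two flux distributions (shared keys union)."""
    keys = set(a.fluxes) | set(b.fluxes)
    return float(
        np.sqrt(sum((a.fluxes.get(k, 0.0) - b.fluxes.get(k, 0.0)) ** 2 for k in keys))
    )
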