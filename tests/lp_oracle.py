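"""Independent brute-force LP oracle for tiny flux polytopes.

Enumerates basic feasible solutions of ``max c.v s.t. S v = 0,
lb <= v <= ub`` directly from LP vertex theory: at a vertex, at least
``n - rank(S)`` variables sit at a bound and the rest solve the reduced
linear system.  Every candidate is verified feasible before its objective
is scored, so the enumeration never depends on any LP solver.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


def enumerate_lp_max(S, lb, ub, c, tol: float = 1e-7) -> float:
    """Best objective over all enumerated basic feasible solutions."""
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    m, n = S.shape
    r = int(np.linalg.matrix_rank(S)) if S.size else 0
    k = n - r
    best = -np.inf
    for nonbasic in combinations(range(n), k):
        basic = [j for j in range(n) if j not in nonbasic]
        B = S[:, basic]
        for picks in product((0, 1), repeat=k):
            x = np.zeros(n)
            for j, pick in zip(nonbasic, picks):
                x[j] = lb[j] if pick == 0 else ub[j]
            rhs = -S[:, list(nonbasic)] @ x[list(nonbasic)] if k else np.zeros(m)
            if basic:
                sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
                x[basic] = sol
            if np.max(np.abs(S @ x), initial=0.0) > tol:
                continue
            if np.any(x < lb - tol) or np.any(x > ub + tol):
                continue
            best = max(best, float(c @ x))
    return best


def model_arrays(model, objective_id):
    """Dense (S, lb, ub, c) arrays for a model, in reaction order."""
    from epsflux.core import assemble_stoichiometric_matrix

    S, _, rxn_index = assemble_stoichiometric_matrix(model)
    n = S.shape[1]
    lb = np.zeros(n)
    ub = np.zeros(n)
    c = np.zeros(n)
    for rid, j in rxn_index.items():
        lb[j] = model.reactions[rid].lower_bound
        ub[j] = model.reactions[rid].upper_bound
    c[rxn_index[objective_id]] = 1.0
    return S.toarray(), lb, ub, c
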