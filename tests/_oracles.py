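"""Independent brute-force oracles used to cross-check the solvers.

Deliberately naive implementations that share no code with the package:
LP optima by exhaustive vertex enumeration of {A x = b, lb <= x <= ub},
and reconciliation by generic constrained optimisation (SLSQP).
"""

from itertools import combinations, product

import numpy as np
from scipy.optimize import minimize

FEAS_TOL = 1e-7


def enumerate_vertices(A, b, bounds):
    """All vertices of {A x = b, lb <= x <= ub} for small n."""
    A = np.asarray(A, dtype=float)
    n = A.shape[1]
    rank = np.linalg.matrix_rank(A) if A.size else 0
    k = n - rank
    lbs = np.array([lo for lo, _ in bounds], dtype=float)
    ubs = np.array([hi for _, hi in bounds], dtype=float)
    vertices = []
    for fixed_idx in combinations(range(n), k):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        choices = []
        for j in fixed_idx:
            opts = [v for v in (lbs[j], ubs[j]) if np.isfinite(v)]
            if not opts:
                break
            choices.append(sorted(set(opts)))
        else:
            for vals in product(*choices) if choices else [()]:
                x = np.zeros(n)
                for j, v in zip(fixed_idx, vals):
                    x[j] = v
                if free_idx:
                    A_free = A[:, free_idx]
                    rhs = b - A[:, list(fixed_idx)] @ np.array(vals) \
                        if fixed_idx else b
                    if np.linalg.matrix_rank(A_free) < len(free_idx):
                        continue
                    sol, *_ = np.linalg.lstsq(A_free, rhs, rcond=None)
                    if np.max(np.abs(A_free @ sol - rhs)) > FEAS_TOL:
                        continue
                    x[free_idx] = sol
                elif A.size and np.max(np.abs(A @ x - b)) > FEAS_TOL:
                    continue
                if np.all(x >= lbs - FEAS_TOL) and np.all(x <= ubs + FEAS_TOL):
                    vertices.append(x)
    return vertices


def vertex_optimum(A, b, bounds, c, sense="max"):
    """Optimal objective value over the vertex set; None if infeasible."""
    vertices = enumerate_vertices(A, b, bounds)
    if not vertices:
        return None
    values = [float(np.dot(c, v)) for v in vertices]
    return max(values) if sense == "max" else min(values)


def wls_reconcile_oracle(R, y, se):
    """Constrained weighted least squares by generic SLSQP.

    Returns (reconciled x, weighted objective h)."""
    y = np.asarray(y, dtype=float)
    w = 1.0 / np.asarray(se, dtype=float) ** 2

    def objective(x):
        return float(np.sum(w * (x - y) ** 2))

    cons = [{"type": "eq", "fun": (lambda x, row=row: float(row @ x))}
            for row in np.atleast_2d(R)]
    res = minimize(objective, y, method="SLSQP", constraints=cons,
                   options={"ftol": 1e-14, "maxiter": 500})
    assert res.success, res.message
    return res.x, objective(res.x)
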