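"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths they check: the LP oracle
enumerates basic solutions instead of calling a simplex/interior-point
solver; the Denton oracle parametrises the constraint set's null space
and solves an unconstrained least-squares problem; the peak oracle is a
dense grid argmax.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.linalg import null_space


def lp_vertex_oracle(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, tol=1e-8):
    """Minimise c'x over {A_ub x <= b_ub, A_eq x = b_eq, x >= 0} by
    enumerating every basic (vertex) solution.

    Returns (min_cost, x) or (None, None) when no feasible vertex exists.
    Valid whenever an optimum is attained at a vertex (e.g. c > 0, x >= 0).
    """
    c = np.asarray(c, dtype=float)
    n = c.size
    rows, rhs, must = [], [], []
    if A_eq is not None:
        for a, b in zip(np.atleast_2d(A_eq), np.atleast_1d(b_eq)):
            must.append(len(rows))
            rows.append(np.asarray(a, dtype=float))
            rhs.append(float(b))
    if A_ub is not None:
        for a, b in zip(np.atleast_2d(A_ub), np.atleast_1d(b_ub)):
            rows.append(np.asarray(a, dtype=float))
            rhs.append(float(b))
    for i in range(n):  # x_i >= 0 bounds as potential active constraints
        e = np.zeros(n)
        e[i] = 1.0
        rows.append(e)
        rhs.append(0.0)
    rows = np.asarray(rows)
    rhs = np.asarray(rhs)
    free = [i for i in range(len(rows)) if i not in must]
    k = n - len(must)
    if k < 0:
        return None, None

    A_ub_all = np.atleast_2d(A_ub) if A_ub is not None else None
    b_ub_all = np.atleast_1d(b_ub) if A_ub is not None else None
    best_cost, best_x = None, None
    for extra in combinations(free, k):
        idx = list(must) + list(extra)
        M = rows[idx]
        if np.linalg.matrix_rank(M) < n:
            continue
        try:
            x = np.linalg.solve(M, rhs[idx])
        except np.linalg.LinAlgError:
            continue
        scale = 1.0 + np.abs(rhs).max()
        if (x < -tol * scale).any():
            continue
        if A_ub_all is not None and (
            A_ub_all @ x > b_ub_all + tol * (1.0 + np.abs(b_ub_all))
        ).any():
            continue
        if A_eq is not None:
            resid = np.atleast_2d(A_eq) @ x - np.atleast_1d(b_eq)
            if (np.abs(resid) > tol * scale).any():
                continue
        cost = float(c @ x)
        if best_cost is None or cost < best_cost:
            best_cost, best_x = cost, x
    return best_cost, best_x


def random_diet_instance(rng, max_items: int = 6, max_constraints: int = 5):
    """A random feasible least-cost-diet-like LP.

    Feasibility is guaranteed by construction: bounds are placed around a
    known interior point x0 >= 0.
    Returns (c, A_ub, b_ub, A_eq, b_eq).
    """
    n = int(rng.integers(2, max_items + 1))
    m = int(rng.integers(1, max_constraints + 1))
    x0 = rng.uniform(0.2, 2.0, size=n)
    c = rng.uniform(0.5, 5.0, size=n)
    A_rows, b_vals = [], []
    for _ in range(m):
        a = rng.lognormal(0.0, 1.0, size=n) * (rng.random(n) > 0.3)
        if not a.any():
            a[rng.integers(n)] = 1.0
        level = float(a @ x0)
        if rng.random() < 0.5:  # lower bound: -a x <= -b
            A_rows.append(-a)
            b_vals.append(-rng.uniform(0.3, 0.95) * level)
        else:  # upper bound
            A_rows.append(a)
            b_vals.append(rng.uniform(1.05, 3.0) * level)
    A_eq = b_eq = None
    if rng.random() < 0.5:  # energy-style equality through x0
        a_e = rng.lognormal(0.0, 0.5, size=n)
        A_eq = a_e[None, :]
        b_eq = np.array([float(a_e @ x0)])
    return c, np.asarray(A_rows), np.asarray(b_vals), A_eq, b_eq


def denton_nullspace_oracle(annual: np.ndarray) -> np.ndarray:
    """Additive Denton benchmark via null-space least squares.

    Writes the monthly path as x0 + Z v with x0 the step function that
    repeats each annual factor and Z an orthonormal basis of the
    annual-average constraint null space, then minimises the first
    differences of x over v with a single lstsq call.
    """
    annual = np.asarray(annual, dtype=float)
    n_years = annual.size
    n = 12 * n_years
    A = np.zeros((n_years, n))
    for y in range(n_years):
        A[y, 12 * y : 12 * (y + 1)] = 1.0 / 12.0
    x0 = np.repeat(annual, 12)
    Z = null_space(A)
    D = np.diff(np.eye(n), axis=0)
    v, *_ = np.linalg.lstsq(D @ Z, -D @ x0, rcond=None)
    return x0 + Z @ v


def peak_grid_argmax(beta_s: float, beta_c: float, grid=None) -> float:
    """Peak month of bs*sin(2 pi t/12) + bc*cos(2 pi t/12) on a fine grid
    over (0, 12]."""
    if grid is None:
        grid = np.arange(1e-4, 12.0 + 1e-4, 1e-4)
    vals = beta_s * np.sin(2 * np.pi * grid / 12.0) + beta_c * np.cos(
        2 * np.pi * grid / 12.0
    )
    return float(grid[np.argmax(vals)])


def circular_month_distance(a: float, b: float, period: float = 12.0) -> float:
    d = abs(a - b) % period
    return min(d, period - d)
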