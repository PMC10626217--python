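"""Independent oracles used by the test suite.

Everything here is deliberately naive (vertex enumeration, brute-force
step-up, normal equations) and shares no code with the implementation paths
it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def polytope_vertices(
    A_eq: np.ndarray,
    A_ub: np.ndarray,
    b_ub: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    tol: float = 1e-9,
) -> np.ndarray:
    """All vertices of {x : A_eq x = 0, A_ub x <= b_ub, l <= x <= u}.

    Brute force: a vertex is the unique solution of n linearly independent
    active constraints; equalities are always active, the remaining ones are
    chosen among inequality rows and bound facets.  Only usable for tiny n.
    """
    n = A_eq.shape[1] if A_eq.size else len(lower)
    rows = [(A_eq[i], 0.0) for i in range(A_eq.shape[0])] if A_eq.size else []
    n_eq = len(rows)
    extra = []
    if A_ub is not None and len(A_ub):
        extra += [(A_ub[i], float(b_ub[i])) for i in range(A_ub.shape[0])]
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        if np.isfinite(upper[j]):
            extra.append((e.copy(), float(upper[j])))
        if np.isfinite(lower[j]):
            extra.append((-e.copy(), float(-lower[j])))

    vertices = []
    need = n - n_eq
    for combo in itertools.combinations(range(len(extra)), need):
        M = np.array([r[0] for r in rows] + [extra[i][0] for i in combo])
        rhs = np.array([r[1] for r in rows] + [extra[i][1] for i in combo])
        if np.linalg.matrix_rank(M) < n:
            continue
        x, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        if np.max(np.abs(M @ x - rhs)) > 1e-7:
            continue
        ok = True
        if A_eq.size and np.max(np.abs(A_eq @ x)) > 1e-7:
            ok = False
        if ok and extra:
            for a, b in extra:
                if a @ x > b + 1e-7:
                    ok = False
                    break
        if ok:
            vertices.append(x)
    if not vertices:
        return np.empty((0, n))
    V = np.array(vertices)
    # deduplicate
    keep = []
    for v in V:
        if not any(np.max(np.abs(v - V[k])) < 1e-6 for k in keep):
            keep.append(len(keep))
            V[len(keep) - 1] = v
    return V[: len(keep)]


def fva_by_vertex_enumeration(model, reaction_id: str, w: float | None = None):
    """(min, max) flux of one reaction over a community model's polytope.

    Enumerate the vertices of the full constraint set (optionally with the
    community biomass fixed to ``w``) and scan the coordinate.  Valid only
    for bounded toy models.
    """
    S, bounds, A_c = model.matrices()
    lower = np.array([b[0] for b in bounds], dtype=float)
    upper = np.array([b[1] for b in bounds], dtype=float)
    if w is not None:
        j = model._rxn_index[model.community_biomass]
        lower[j] = upper[j] = w
    V = polytope_vertices(S, A_c, np.zeros(len(A_c)), lower, upper)
    assert len(V), "polytope has no vertices (infeasible or unbounded)"
    j = model._rxn_index[reaction_id]
    return float(V[:, j].min()), float(V[:, j].max())


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values straight from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def ols_normal_equations(y, X):
    """(X'X)^-1 X'y with an explicit inverse — the textbook estimator."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    XtX = X.T @ X
    return np.linalg.inv(XtX) @ (X.T @ y)


def hc1_sandwich_se(y, X, coef_index: int) -> float:
    """HC1 heteroscedasticity-robust standard error from the sandwich formula."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = ols_normal_equations(y, X)
    resid = y - X @ beta
    bread = np.linalg.inv(X.T @ X)
    meat = X.T @ (X * resid[:, None] ** 2)
    V = bread @ meat @ bread * (n / (n - k))
    return math.sqrt(V[coef_index, coef_index])


def exhaustive_permutation_p(f, compute_stat, observed: float) -> float:
    """Permutation p over all n! orderings of ``f`` with the >= counting rule."""
    f = np.asarray(f, dtype=float)
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(f))):
        stat = compute_stat(f[list(perm)])
        if stat >= observed - 1e-12:
            count += 1
        total += 1
    return count / total
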