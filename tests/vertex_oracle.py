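"""Brute-force LP oracle: enumerate vertices of {S v = 0, lb <= v <= ub}.

The flux polytope of a tiny model has low dimension k = n - rank(S);
its vertices are intersections of k active bound hyperplanes with the
null-space affine hull.  Enumerating all C(2n, k) candidate active sets
and keeping the feasible ones yields every vertex, so any bounded LP
optimum and any FVA range can be read off by scanning vertices —
completely independent of the solver used by the package.
"""

from itertools import combinations

import numpy as np
from scipy.linalg import null_space


def enumerate_vertices(S, lb, ub, tol=1e-9):
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    N = null_space(S)
    k = N.shape[1]
    if k == 0:
        return np.zeros((1, S.shape[1]))
    # constraints in y-space: [N; -N] y <= [ub; -lb]
    A = np.vstack([N, -N])
    b = np.concatenate([ub, -lb])
    vertices = []
    for rows in combinations(range(A.shape[0]), k):
        M = A[list(rows)]
        if abs(np.linalg.det(M)) < 1e-10:
            continue
        y = np.linalg.solve(M, b[list(rows)])
        x = N @ y
        if np.all(x <= ub + tol) and np.all(x >= lb - tol):
            vertices.append(np.clip(x, lb, ub))
    uniq = []
    for v in vertices:
        if not any(np.allclose(v, u, atol=1e-8) for u in uniq):
            uniq.append(v)
    return np.asarray(uniq)


def lp_max(vertices, c):
    """Maximum of c.v over the vertex set (bounded LP optimum)."""
    return float(np.max(vertices @ np.asarray(c, dtype=float)))


def flux_ranges(vertices):
    """Per-coordinate (min, max) over the vertex set (FVA oracle)."""
    return vertices.min(axis=0), vertices.max(axis=0)


def model_arrays(model):
    """S, lb, ub, reaction-id list from a cobra model."""
    from cobra.util.array import create_stoichiometric_matrix

    S = create_stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    ids = [r.id for r in model.reactions]
    return S, lb, ub, ids
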