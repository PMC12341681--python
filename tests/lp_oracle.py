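"""Brute-force LP oracle: enumerate the vertices of a box-bounded polytope.

Independent of the package's LP route (scipy/HiGHS): a vertex of
{v : A_eq v = b_eq, L <= v <= U} has at least n - rank(A_eq) coordinates at
a bound; for tiny fixtures all such candidate points can be enumerated and
the optimum of any linear objective read off the vertex list.
"""

import itertools

import numpy as np


def enumerate_vertices(A_eq, b_eq, lower, upper, tol=1e-7):
    A_eq = np.atleast_2d(np.asarray(A_eq, dtype=float))
    b_eq = np.asarray(b_eq, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    n = A_eq.shape[1]
    k = np.linalg.matrix_rank(A_eq) if A_eq.size else 0
    vertices = []
    for free in itertools.combinations(range(n), k):
        fixed = [j for j in range(n) if j not in free]
        A_free = A_eq[:, list(free)]
        if k and np.linalg.matrix_rank(A_free) < k:
            continue
        for choice in itertools.product(*[(lower[j], upper[j]) for j in fixed]):
            rhs = b_eq - (A_eq[:, fixed] @ np.array(choice) if fixed else 0.0)
            if k:
                x_free, *_ = np.linalg.lstsq(A_free, rhs, rcond=None)
                if np.linalg.norm(A_free @ x_free - rhs) > tol:
                    continue
            else:
                x_free = np.empty(0)
            v = np.empty(n)
            v[list(free)] = x_free
            v[fixed] = choice
            if np.all(v >= lower - tol) and np.all(v <= upper + tol):
                vertices.append(np.clip(v, lower, upper))
    return np.array(vertices)


def brute_force_fba(model, c, sense="max"):
    """Optimum of c.v over the flux polytope by vertex enumeration."""
    verts = enumerate_vertices(
        model.S, np.zeros(model.n_metabolites), model.lower, model.upper
    )
    if verts.size == 0:
        return None
    values = verts @ np.asarray(c)
    return float(values.max() if sense == "max" else values.min())


def brute_force_fva(model, c, q, mu):
    """Per-reaction flux ranges under c.v >= q*mu, by vertex enumeration.

    Vertices of the q-constrained polytope either are vertices of the
    original polytope satisfying the inequality, or lie on the facet where
    the inequality is active (handled by appending it as an equality row).
    """
    c = np.asarray(c, dtype=float)
    zero = np.zeros(model.n_metabolites)
    v_plain = enumerate_vertices(model.S, zero, model.lower, model.upper)
    keep = (
        v_plain[v_plain @ c >= q * mu - 1e-9]
        if v_plain.size
        else np.empty((0, model.n_reactions))
    )
    A_aug = np.vstack([model.S, c])
    b_aug = np.append(zero, q * mu)
    v_facet = enumerate_vertices(A_aug, b_aug, model.lower, model.upper)
    allv = [x for x in (keep, v_facet) if x.size]
    verts = np.vstack(allv)
    return verts.min(axis=0), verts.max(axis=0)
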