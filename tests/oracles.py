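"""Independent oracles used by the test suite.

Everything here is deliberately written against the *definitions* (exact
boundary-matrix ranks via sympy, brute-force enumeration of simplices
and subsets) rather than against the package's algorithms, so agreement
between the two routes is informative.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import sympy


def complex_at_scale(M: np.ndarray, t: float):
    """Edges and triangles of the Vietoris-Rips complex at scale t."""
    n = len(M)
    edges = [
        (i, j)
        for i, j in combinations(range(n), 2)
        if np.isfinite(M[i, j]) and M[i, j] <= t
    ]
    eset = set(edges)
    triangles = [
        (i, j, k)
        for i, j, k in combinations(range(n), 3)
        if (i, j) in eset and (i, k) in eset and (j, k) in eset
    ]
    return edges, triangles


def betti_via_exact_ranks(M: np.ndarray, t: float) -> tuple[int, int]:
    """(beta0, beta1) of the Rips complex at scale t from exact boundary ranks."""
    n = len(M)
    edges, triangles = complex_at_scale(M, t)
    eidx = {e: c for c, e in enumerate(edges)}
    d1 = sympy.zeros(n, len(edges))
    for c, (i, j) in enumerate(edges):
        d1[i, c], d1[j, c] = -1, 1
    d2 = sympy.zeros(len(edges), len(triangles))
    for c, (i, j, k) in enumerate(triangles):
        d2[eidx[(j, k)], c] = 1
        d2[eidx[(i, k)], c] = -1
        d2[eidx[(i, j)], c] = 1
    r1 = d1.rank() if edges else 0
    r2 = d2.rank() if triangles else 0
    return n - r1, len(edges) - r1 - r2


def ordinary_betti(simplices, n: int) -> int:
    """Betti number of an abstract simplicial complex via exact sympy ranks."""
    simplices = [tuple(sorted(s)) for s in simplices]
    chains = {d: sorted({s for s in simplices if len(s) == d + 1}) for d in range(0, 4)}

    def boundary(d):
        rows, cols = chains[d - 1], chains[d]
        idx = {s: i for i, s in enumerate(rows)}
        m = sympy.zeros(len(rows), len(cols))
        for c, s in enumerate(cols):
            for i in range(len(s)):
                face = s[:i] + s[i + 1 :]
                m[idx[face], c] += (-1) ** i
        return m

    cn = len(chains[n])
    if cn == 0:
        return 0
    rn = boundary(n).rank() if n > 0 and chains[n - 1] else 0
    rnp1 = boundary(n + 1).rank() if chains[n + 1] else 0
    return cn - rn - rnp1


def vr_edges_from_set_definition(points: np.ndarray, weights: np.ndarray, t: float):
    """Edge set of the weighted Vietoris-Rips complex at scale t, straight
    from the set definition d(x_i, x_j) <= t v_i + t v_j."""
    out = set()
    for i, j in combinations(range(len(points)), 2):
        if np.linalg.norm(points[i] - points[j]) <= t * (weights[i] + weights[j]):
            out.add((i, j))
    return out


def k_distance_via_power_distance(query, points: np.ndarray, k: int) -> float:
    """k-distance through the power-distance identity: minimum over all
    k-subsets of d^2(x, barycenter) - w_bary, with
    w_bary = -(1/k) sum d^2(bary, x_i)."""
    query = np.asarray(query, dtype=float)
    best = np.inf
    for subset in combinations(range(len(points)), k):
        bary = points[list(subset)].mean(axis=0)
        w = -np.mean([np.sum((bary - points[i]) ** 2) for i in subset])
        best = min(best, np.sum((query - bary) ** 2) - w)
    return float(np.sqrt(best))


def random_valid_weighted_complex(rng, n_vertices=5, p_edge=0.6, p_tri=0.6):
    """A random face-closed complex with divisibility-consistent weights."""
    from math import lcm

    weights = {}
    for v in range(n_vertices):
        weights[(v,)] = int(rng.integers(1, 4))
    for e in combinations(range(n_vertices), 2):
        if rng.random() < p_edge:
            base = lcm(weights[(e[0],)], weights[(e[1],)])
            weights[e] = base * int(rng.integers(1, 3))
    for t in combinations(range(n_vertices), 3):
        faces = [(t[0], t[1]), (t[0], t[2]), (t[1], t[2])]
        if all(f in weights for f in faces) and rng.random() < p_tri:
            base = lcm(*(weights[f] for f in faces))
            weights[t] = base * int(rng.integers(1, 3))
    return weights
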