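"""Simplex-weighted homology in exact arithmetic.

A weighted simplicial complex assigns every simplex a nonzero integer
weight subject to divisibility: the weight of a face divides the weight
of every coface.  The weighted boundary map rescales each face term,

    boundary(sigma) = sum_i (w(sigma) / w(d_i sigma)) (-1)^i d_i(sigma),

which squares to zero thanks to the divisibility condition, and reduces
to the ordinary simplicial boundary when all weights are equal.
Weighted Betti numbers are ranks of ker/im over the field of fractions
of the weight ring (here Z, so over Q); the p-persistent variant
quotients the cycle group at one filtration level by the boundary group
p levels later.

All rank/null-space computations are exact (integer or Fraction
arithmetic); floating point is deliberately never used in this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations

__all__ = [
    "WeightedComplex",
    "FilteredWeightedComplex",
    "ValidationReport",
    "validate_weighted_complex",
    "weighted_boundary_matrix",
    "weighted_betti",
    "persistent_weighted_betti",
    "restrict_by_ideal",
]


# ---------------------------------------------------------------------------
# exact linear algebra over Q (Fraction-based Gaussian elimination)
# ---------------------------------------------------------------------------


def _rank_exact(rows: list[list]) -> int:
    """Rank of a matrix with int/Fraction entries, by exact elimination."""
    m = [[Fraction(x) for x in row] for row in rows]
    if not m or not m[0]:
        return 0
    n_rows, n_cols = len(m), len(m[0])
    rank = 0
    col = 0
    for col in range(n_cols):
        pivot = next((r for r in range(rank, n_rows) if m[r][col] != 0), None)
        if pivot is None:
            continue
        m[rank], m[pivot] = m[pivot], m[rank]
        pr = m[rank]
        inv = pr[col]
        for r in range(rank + 1, n_rows):
            f = m[r][col] / inv
            if f:
                m[r] = [a - f * b for a, b in zip(m[r], pr)]
        rank += 1
        if rank == n_rows:
            break
    return rank


def _nullspace_exact(rows: list[list]) -> list[list[Fraction]]:
    """Basis of the right null space of a matrix over Q."""
    if not rows:
        return []
    m = [[Fraction(x) for x in row] for row in rows]
    n_rows, n_cols = len(m), len(m[0])
    pivots: list[int] = []
    r = 0
    for c in range(n_cols):
        pivot = next((i for i in range(r, n_rows) if m[i][c] != 0), None)
        if pivot is None:
            continue
        m[r], m[pivot] = m[pivot], m[r]
        m[r] = [x / m[r][c] for x in m[r]]
        for i in range(n_rows):
            if i != r and m[i][c] != 0:
                f = m[i][c]
                m[i] = [a - f * b for a, b in zip(m[i], m[r])]
        pivots.append(c)
        r += 1
        if r == n_rows:
            break
    free = [c for c in range(n_cols) if c not in pivots]
    basis = []
    for fc in free:
        v = [Fraction(0)] * n_cols
        v[fc] = Fraction(1)
        for i, pc in enumerate(pivots):
            v[pc] = -m[i][fc]
        basis.append(v)
    return basis


def _smith_diagonal(rows: list[list[int]]) -> list[int]:
    """Nonzero diagonal of the Smith normal form of an integer matrix."""
    m = [list(map(int, row)) for row in rows]
    if not m or not m[0]:
        return []
    n_rows, n_cols = len(m), len(m[0])
    diag = []
    top = 0
    while top < min(n_rows, n_cols):
        # find smallest nonzero entry to pivot on
        best = None
        for i in range(top, n_rows):
            for j in range(top, n_cols):
                if m[i][j] != 0 and (best is None or abs(m[i][j]) < abs(m[best[0]][best[1]])):
                    best = (i, j)
        if best is None:
            break
        bi, bj = best
        m[top], m[bi] = m[bi], m[top]
        for row in m:
            row[top], row[bj] = row[bj], row[top]
        again = False
        for i in range(top + 1, n_rows):
            q = m[i][top] // m[top][top]
            if q:
                m[i] = [a - q * b for a, b in zip(m[i], m[top])]
            if m[i][top]:
                again = True
        for j in range(top + 1, n_cols):
            q = m[top][j] // m[top][top]
            if q:
                for row in m:
                    row[j] -= q * row[top]
            if m[top][j]:
                again = True
        if again:
            continue
        diag.append(abs(m[top][top]))
        top += 1
    return diag


# ---------------------------------------------------------------------------
# weighted complexes
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    missing_faces: list = field(default_factory=list)
    divisibility_violations: list = field(default_factory=list)
    zero_weights: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.missing_faces or self.divisibility_violations or self.zero_weights)

    def to_json(self) -> str:
        return json.dumps(
            {
                "ok": self.ok,
                "missing_faces": [list(s) for s in self.missing_faces],
                "divisibility_violations": [
                    [list(a), list(b)] for a, b in self.divisibility_violations
                ],
                "zero_weights": [list(s) for s in self.zero_weights],
            }
        )


class WeightedComplex:
    """A simplicial complex with a divisibility-consistent integer weight
    per simplex (weight ring Z)."""

    def __init__(self, weights: dict):
        self.weights = {tuple(sorted(s)): int(w) for s, w in weights.items()}

    @classmethod
    def from_simplices(cls, simplices) -> "WeightedComplex":
        """From an iterable of (vertex_tuple, weight)."""
        return cls(dict(simplices))

    @classmethod
    def constant_weight(cls, simplices, weight: int = 1) -> "WeightedComplex":
        return cls({tuple(s): weight for s in simplices})

    @property
    def simplices(self) -> list[tuple]:
        return sorted(self.weights, key=lambda s: (len(s), s))

    def simplices_of_dim(self, n: int) -> list[tuple]:
        return sorted(s for s in self.weights if len(s) == n + 1)

    @property
    def dimension(self) -> int:
        return max((len(s) - 1 for s in self.weights), default=-1)

    def validate(self) -> ValidationReport:
        report = ValidationReport()
        for s, w in self.weights.items():
            if w == 0:
                report.zero_weights.append(s)
            if len(s) > 1:
                for f in combinations(s, len(s) - 1):
                    if f not in self.weights:
                        report.missing_faces.append(f)
                    elif self.weights[f] == 0 or w % self.weights[f] != 0:
                        report.divisibility_violations.append((f, s))
        return report

    def require_valid(self) -> None:
        report = self.validate()
        if not report.ok:
            raise ValueError(f"invalid weighted complex: {report.to_json()}")

    def is_subcomplex_of(self, other: "WeightedComplex") -> bool:
        return all(s in other.weights and other.weights[s] == w for s, w in self.weights.items())

    def to_json(self) -> str:
        return json.dumps(
            [{"vertices": list(s), "weight": w} for s, w in sorted(self.weights.items(),
                                                                   key=lambda kv: (len(kv[0]), kv[0]))]
        )

    @classmethod
    def from_json(cls, text: str) -> "WeightedComplex":
        return cls({tuple(d["vertices"]): d["weight"] for d in json.loads(text)})


def validate_weighted_complex(K: WeightedComplex) -> ValidationReport:
    """Report every missing face and violated divisibility pair (empty = valid)."""
    return K.validate()


def weighted_boundary_matrix(K: WeightedComplex, n: int) -> list[list[int]]:
    """Matrix of the weighted boundary from n-chains to (n-1)-chains.

    Columns follow ``simplices_of_dim(n)``, rows ``simplices_of_dim(n-1)``,
    both in lexicographic order of the sorted vertex tuples (orientation =
    increasing vertex order).  Entry: (-1)^i w(sigma)/w(d_i sigma).
    """
    K.require_valid()
    cols = K.simplices_of_dim(n)
    rows = K.simplices_of_dim(n - 1)
    row_index = {s: i for i, s in enumerate(rows)}
    mat = [[0] * len(cols) for _ in rows]
    for j, s in enumerate(cols):
        for i in range(len(s)):
            face = s[:i] + s[i + 1 :]
            mat[row_index[face]][j] += (-1) ** i * (K.weights[s] // K.weights[face])
    return mat


def weighted_betti(K: WeightedComplex, n: int, torsion: bool = False):
    """Rank of H_n(K, w) over Q: nullity(d_n) - rank(d_{n+1}), exactly.

    With ``torsion=True`` also returns the torsion coefficients of
    coker(d_{n+1}) restricted to ker(d_n), from the Smith normal form.
    """
    K.require_valid()
    n_chains = len(K.simplices_of_dim(n))
    if n_chains == 0:
        return (0, []) if torsion else 0
    d_n = weighted_boundary_matrix(K, n) if n > 0 else []
    d_np1 = weighted_boundary_matrix(K, n + 1)
    rank_dn = _rank_exact(d_n) if d_n else 0
    rank_dnp1 = _rank_exact(d_np1) if d_np1 and d_np1[0] else 0
    betti = n_chains - rank_dn - rank_dnp1
    if not torsion:
        return betti
    diag = _smith_diagonal(d_np1) if d_np1 and d_np1[0] else []
    return betti, [d for d in diag if d > 1]


def restrict_by_ideal(K: WeightedComplex, m: int) -> WeightedComplex:
    """Remove every simplex whose weight lies in the principal ideal (m).

    The result is guaranteed face-closed (removing a face removes its
    cofaces automatically because face weights divide coface weights); a
    closure failure would indicate corrupt input and raises.
    """
    if m < 1:
        raise ValueError("m must be a positive integer")
    kept = {s: w for s, w in K.weights.items() if w % m != 0}
    out = WeightedComplex(kept)
    report = out.validate()
    if report.missing_faces:
        raise RuntimeError(
            "ideal restriction broke face closure; the input complex violated divisibility"
        )
    return out


# ---------------------------------------------------------------------------
# filtered weighted complexes and p-persistent homology
# ---------------------------------------------------------------------------


class FilteredWeightedComplex:
    """A nested sequence of weighted complexes with consistent weights."""

    def __init__(self, levels: list[WeightedComplex]):
        if not levels:
            raise ValueError("need at least one filtration level")
        for a, b in zip(levels, levels[1:]):
            if not a.is_subcomplex_of(b):
                raise ValueError("each level must be a subcomplex of the next, with equal weights")
        self.levels = list(levels)

    def __len__(self):
        return len(self.levels)


def persistent_weighted_betti(
    F: FilteredWeightedComplex, i: int, p: int, k: int
) -> int:
    """Rank of the p-persistent k-th weighted homology at level i.

    Computed exactly as dim Z_k^i - dim(B_k^{i+p} intersect Z_k^i),
    using rank identities over Q: dim(B cap Z) = rank(B) + rank(Z) -
    rank([B | Z]).
    """
    if i < 0 or i + p >= len(F.levels) or p < 0:
        raise IndexError(f"levels i={i}, i+p={i + p} out of range 0..{len(F.levels) - 1}")
    Ki, Kip = F.levels[i], F.levels[i + p]
    chains_i = Ki.simplices_of_dim(k)
    if not chains_i:
        return 0
    chains_ip = Kip.simplices_of_dim(k)
    col_of = {s: j for j, s in enumerate(chains_ip)}

    d_k = weighted_boundary_matrix(Ki, k) if k > 0 else []
    if d_k and d_k[0]:
        z_basis = _nullspace_exact(d_k)
    else:
        z_basis = [
            [Fraction(int(a == b)) for a in range(len(chains_i))] for b in range(len(chains_i))
        ]
    # embed cycle vectors of level i into the (larger) chain space of level i+p
    z_cols = []
    for v in z_basis:
        vec = [Fraction(0)] * len(chains_ip)
        for s, x in zip(chains_i, v):
            vec[col_of[s]] = x
        z_cols.append(vec)

    d_kp1 = weighted_boundary_matrix(Kip, k + 1)
    b_cols = (
        [[Fraction(row[j]) for row in d_kp1] for j in range(len(d_kp1[0]))]
        if d_kp1 and d_kp1[0]
        else []
    )
    rank_b = _rank_exact([list(col) for col in zip(*b_cols)]) if b_cols else 0
    stacked = b_cols + z_cols
    rank_bz = _rank_exact([list(col) for col in zip(*stacked)]) if stacked else 0
    dim_z = len(z_cols)
    dim_intersection = rank_b + dim_z - rank_bz
    return dim_z - dim_intersection
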