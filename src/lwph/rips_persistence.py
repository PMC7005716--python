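"""Vietoris-Rips persistent homology in dimensions 0 and 1.

The filtration is the standard clique (flag) construction on a
:class:`~lwph.filtrations.FiltrationMatrix`: vertices enter at 0, edge
(i, j) at M_ij, and a triangle at the largest of its three edge values.
Simplices whose value is infinite or beyond ``max_scale`` are never
created.  Dimension is capped at 1 -- triangles are built only as
killers of 1-cycles -- because the local domains this package analyses
contain too few atoms for meaningful higher homology.

Persistence is computed over the two-element field by boundary-matrix
column reduction (columns as integer bitmasks).  Dimension 0 is
additionally recomputed by Kruskal-style union-find and the two answers
are required to agree, which guards the reduction against ordering
bugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filtrations import FiltrationMatrix

__all__ = [
    "Filtration",
    "Barcode",
    "build_rips_filtration",
    "compute_barcodes",
    "barcodes_from_matrix",
    "betti_at",
    "group_merge_value",
]


@dataclass
class Filtration:
    """Ordered simplices (dim <= 2) with non-decreasing filtration values."""

    simplices: list[tuple[int, ...]]
    values: np.ndarray
    n_vertices: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.simplices):
            raise ValueError("one value per simplex required")

    def __len__(self):
        return len(self.simplices)

    def validate(self) -> None:
        """Check that faces precede cofaces and values are monotone."""
        position = {s: i for i, s in enumerate(self.simplices)}
        if np.any(np.diff(self.values) < 0):
            raise ValueError("filtration values must be non-decreasing")
        for i, s in enumerate(self.simplices):
            if len(s) == 1:
                continue
            for f in _facets(s):
                j = position.get(f)
                if j is None or j > i:
                    raise ValueError(f"face {f} does not precede coface {s}")
                if self.values[j] > self.values[i]:
                    raise ValueError(f"face {f} has larger value than coface {s}")


def _facets(simplex: tuple[int, ...]):
    return [simplex[:i] + simplex[i + 1 :] for i in range(len(simplex))]


def build_rips_filtration(matrix: FiltrationMatrix, max_scale: float = 10.0) -> Filtration:
    """All vertices, edges with M_ij <= max_scale, and triangles whose three
    edges are all present (value = max edge); deterministic total order by
    (value, dimension, vertex tuple)."""
    if max_scale <= 0:
        raise ValueError("max_scale must be positive")
    M = matrix.values
    n = matrix.n
    simplices: list[tuple[float, int, tuple[int, ...]]] = [(0.0, 0, (i,)) for i in range(n)]

    adj = (M <= max_scale) & np.isfinite(M)
    np.fill_diagonal(adj, False)
    iu, ju = np.nonzero(np.triu(adj, k=1))
    for i, j in zip(iu, ju):
        simplices.append((float(M[i, j]), 1, (int(i), int(j))))
    for i, j in zip(iu, ju):
        common = np.nonzero(adj[i] & adj[j])[0]
        for k in common[common > j]:
            value = max(M[i, j], M[i, k], M[j, k])
            simplices.append((float(value), 2, (int(i), int(j), int(k))))
    simplices.sort(key=lambda t: (t[0], t[1], t[2]))
    return Filtration(
        simplices=[s for _, _, s in simplices],
        values=np.array([v for v, _, _ in simplices]),
        n_vertices=n,
    )


@dataclass
class Barcode:
    """Birth/death intervals per homology dimension; death may be +inf."""

    intervals: np.ndarray  # shape (m, 3): dimension, birth, death
    provenance: str = "unknown"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.intervals, dtype=float).reshape(-1, 3)
        if np.any(arr[:, 2] < arr[:, 1]):
            raise ValueError("death must be >= birth")
        self.intervals = arr

    def of_dimension(self, k: int) -> np.ndarray:
        """(m_k, 2) array of (birth, death) for dimension k."""
        return self.intervals[self.intervals[:, 0] == k][:, 1:]

    def n_intervals(self, k: int) -> int:
        return int(np.sum(self.intervals[:, 0] == k))

    @property
    def persistence(self) -> np.ndarray:
        return self.intervals[:, 2] - self.intervals[:, 1]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.intervals, columns=["dim", "birth", "death"]).astype(
            {"dim": int}
        )

    def save(self, path) -> None:
        """CSV with dim,birth,death; infinite deaths as the literal 'inf'."""
        import json

        df = self.to_dataframe()
        df.to_csv(path, index=False)
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump({"provenance": self.provenance, "params": self.params}, fh)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[max(ri, rj)] = min(ri, rj)
        return True


def _dim0_deaths_union_find(filtration: Filtration) -> list[float]:
    uf = _UnionFind(filtration.n_vertices)
    deaths = []
    for s, v in zip(filtration.simplices, filtration.values):
        if len(s) == 2 and uf.union(*s):
            deaths.append(float(v))
    return deaths


def compute_barcodes(filtration: Filtration, keep_zero_length: bool = False) -> Barcode:
    """Persistence pairing over GF(2) by standard column reduction.

    Unpaired creators die at +inf.  Zero-persistence pairs in dimension
    >= 1 (a cycle filled the instant it appears) are dropped unless
    ``keep_zero_length``; dimension-0 intervals are always all kept, so
    their number equals the vertex count.
    """
    simplices, values = filtration.simplices, filtration.values
    position = {s: i for i, s in enumerate(simplices)}

    pivot_of_low: dict[int, int] = {}
    columns: dict[int, int] = {}
    paired_creator: dict[int, int] = {}  # creator index -> killer index
    positive: list[int] = []

    for idx, s in enumerate(simplices):
        if len(s) == 1:
            positive.append(idx)
            continue
        col = 0
        for f in _facets(s):
            j = position.get(f)
            if j is None:
                raise ValueError(f"filtration is not face-closed at {s}")
            col ^= 1 << j
        while col:
            low = col.bit_length() - 1
            other = pivot_of_low.get(low)
            if other is None:
                break
            col ^= columns[other]
        if col == 0:
            positive.append(idx)
        else:
            low = col.bit_length() - 1
            pivot_of_low[low] = idx
            columns[idx] = col
            paired_creator[low] = idx

    rows = []
    for idx in positive:
        k = len(simplices[idx]) - 1
        if k > 1:
            continue  # dimension capped at 1
        birth = values[idx]
        killer = paired_creator.get(idx)
        death = np.inf if killer is None else values[killer]
        if k >= 1 and death == birth and not keep_zero_length:
            continue
        rows.append((k, float(birth), float(death)))

    barcode = Barcode(np.array(rows, dtype=float).reshape(-1, 3), provenance="rips")

    # independent dimension-0 cross-check
    uf_deaths = sorted(_dim0_deaths_union_find(filtration))
    d0 = barcode.of_dimension(0)
    red_deaths = sorted(d0[np.isfinite(d0[:, 1]), 1])
    if len(uf_deaths) != len(red_deaths) or not np.allclose(uf_deaths, red_deaths):
        raise AssertionError("union-find and matrix reduction disagree in dimension 0")
    return barcode


def barcodes_from_matrix(
    matrix: FiltrationMatrix, max_scale: float = 10.0, keep_zero_length: bool = False
) -> Barcode:
    """Convenience: build the Rips filtration and reduce it in one call."""
    barcode = compute_barcodes(build_rips_filtration(matrix, max_scale), keep_zero_length)
    barcode.provenance = f"rips[{matrix.provenance}]"
    barcode.params = {"max_scale": max_scale, **matrix.params}
    return barcode


def betti_at(barcode: Barcode, t: float, k: int) -> int:
    """Number of k-dimensional intervals containing t (closed at both ends)."""
    if t < 0:
        raise ValueError("filtration scale must be >= 0")
    iv = barcode.of_dimension(k)
    if iv.size == 0:
        return 0
    return int(np.sum((iv[:, 0] <= t) & (t <= iv[:, 1])))


def group_merge_value(matrix: FiltrationMatrix, groups) -> float:
    """Scale at which components carrying different group labels first merge.

    Edges are processed in increasing filtration order through
    union-find; the first union joining two components that contain
    different labels (e.g. the two nucleotides of a base pair) is
    reported.  Raises if the groups never connect.
    """
    groups = list(groups)
    if len(groups) != matrix.n:
        raise ValueError("one group label per point required")
    M = matrix.values
    iu, ju = np.triu_indices(matrix.n, k=1)
    finite = np.isfinite(M[iu, ju])
    order = np.argsort(M[iu, ju][finite], kind="stable")
    edges = list(zip(iu[finite][order], ju[finite][order]))

    uf = _UnionFind(matrix.n)
    members: dict[int, set] = {i: {groups[i]} for i in range(matrix.n)}
    for i, j in edges:
        ri, rj = uf.find(int(i)), uf.find(int(j))
        if ri == rj:
            continue
        if members[ri] != members[rj]:
            return float(M[i, j])
        uf.union(ri, rj)
        members[uf.find(ri)] = members[ri] | members[rj]
    raise ValueError("the labelled groups never merge within the finite filtration")
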