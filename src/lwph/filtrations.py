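"""Weighted filtration matrices and weight functions for point clouds.

Every construction returns a :class:`FiltrationMatrix`: a symmetric
matrix of filtration values with zero diagonal, where ``+inf`` marks a
pair that never forms an edge.  In computation infinity simply means
"larger than any filtration scale", so simplices carrying it are never
created.

The constructions:

* ``euclidean_matrix`` -- plain pairwise distances (localized PH).
* ``localized_weighted_matrix`` -- distances kept only between atoms of
  *different* residues, infinite within a residue, so only
  non-covalent, inter-nucleotide structure registers (LWPH).
* ``multilevel_matrix`` -- bonded pairs (or all pairs closer than a
  level n) pushed to infinity.
* ``interactive_matrix`` -- only cross-molecule distances kept.
* ``radius_weighted_matrix`` -- d / (v_i + v_j), the weighted
  Vietoris-Rips scaling by per-point radii.
* ``superlevel_edge_matrix`` -- w_max - w transform realizing the
  decreasing clique-weight filtration of a weighted graph with
  increasing-filtration machinery.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "WeightedPointCloud",
    "FiltrationMatrix",
    "KernelSpec",
    "euclidean_matrix",
    "localized_weighted_matrix",
    "multilevel_matrix",
    "interactive_matrix",
    "radius_weighted_matrix",
    "superlevel_edge_matrix",
    "k_distance",
    "rigidity_value",
    "infer_bonds",
]

#: default covalent-bond cutoff between heavy atoms (Angstrom)
BOND_CUTOFF = 1.7


@dataclass
class WeightedPointCloud:
    """Points with optional per-point weights, residue/molecule labels and bonds."""

    points: np.ndarray
    weights: np.ndarray | None = None
    residue_labels: list | None = None
    molecule_labels: list | None = None
    bonds: list[tuple[int, int]] | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        n = len(self.points)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (n,):
                raise ValueError(f"expected {n} weights, got shape {self.weights.shape}")
            if np.any(self.weights < 0):
                raise ValueError("weights must be nonnegative")
        for name in ("residue_labels", "molecule_labels"):
            labels = getattr(self, name)
            if labels is not None and len(labels) != n:
                raise ValueError(f"{name} length {len(labels)} != point count {n}")

    @classmethod
    def from_structure(cls, structure, weights=None, molecule_by: str = "chain"):
        """Point cloud from a Structure: residue labels from residue identity,
        molecule labels from the chain (or a custom per-atom attribute)."""
        return cls(
            points=structure.coords.copy(),
            weights=weights,
            residue_labels=structure.residue_ids,
            molecule_labels=[getattr(a, molecule_by) for a in structure.atoms],
        )

    def __len__(self):
        return len(self.points)


@dataclass(frozen=True)
class KernelSpec:
    """A decaying atomic kernel: Lorentz (power-law) or generalized exponential."""

    kind: str = "lorentz"
    eta: float = 1.0
    nu: float = 2.0

    def __post_init__(self):
        if self.kind not in ("lorentz", "exponential"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.eta <= 0 or self.nu <= 0:
            raise ValueError("kernel scale eta and power nu must be > 0")

    def __call__(self, d):
        x = (np.asarray(d, dtype=float) / self.eta) ** self.nu
        return 1.0 / (1.0 + x) if self.kind == "lorentz" else np.exp(-x)


@dataclass
class FiltrationMatrix:
    """Symmetric matrix of filtration values; +inf marks forbidden edges."""

    values: np.ndarray
    provenance: str = "unknown"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        M = np.asarray(self.values, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError(f"filtration matrix must be square, got {M.shape}")
        if not np.array_equal(M, M.T):
            raise ValueError("filtration matrix must be symmetric")
        if np.any(np.diag(M) != 0):
            raise ValueError("filtration matrix diagonal must be zero")
        if np.any(M < 0) or np.any(np.isnan(M)):
            raise ValueError("filtration matrix entries must be >= 0 and not NaN")
        self.values = M

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def finite_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        v = self.values[iu]
        return v[np.isfinite(v)]

    # -- CSV + JSON-header round trip --------------------------------------
    def save(self, path) -> None:
        path = str(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            for row in self.values:
                writer.writerow(["inf" if not np.isfinite(x) else repr(float(x)) for x in row])
        with open(path + ".meta.json", "w") as fh:
            json.dump({"provenance": self.provenance, "params": self.params, "n": self.n}, fh)

    @classmethod
    def load(cls, path) -> "FiltrationMatrix":
        path = str(path)
        with open(path, newline="") as fh:
            rows = [[float(x) for x in row] for row in csv.reader(fh)]
        meta = {"provenance": "unknown", "params": {}}
        try:
            with open(path + ".meta.json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            pass
        return cls(np.array(rows), provenance=meta["provenance"], params=meta.get("params", {}))


def _euclidean(points: np.ndarray) -> np.ndarray:
    if len(points) == 1:
        return np.zeros((1, 1))
    return squareform(pdist(points))


def euclidean_matrix(cloud: WeightedPointCloud) -> FiltrationMatrix:
    """Plain Euclidean distance matrix."""
    if len(cloud) < 1:
        raise ValueError("need at least one point")
    return FiltrationMatrix(_euclidean(cloud.points), provenance="euclidean")


def _mask_matrix(cloud, same_group_infinite: np.ndarray, provenance: str, params=None):
    M = _euclidean(cloud.points)
    M[same_group_infinite] = np.inf
    np.fill_diagonal(M, 0.0)
    return FiltrationMatrix(M, provenance=provenance, params=params or {})


def localized_weighted_matrix(cloud: WeightedPointCloud) -> FiltrationMatrix:
    """Distances between atoms of different residues; +inf within a residue.

    This is the weighting behind LWPH: covalent (intra-residue)
    structure is suppressed so the barcode reflects inter-nucleotide,
    non-covalent organization only.
    """
    if cloud.residue_labels is None:
        raise ValueError("localized_weighted_matrix requires residue labels")
    lab = np.asarray(cloud.residue_labels, dtype=object)
    return _mask_matrix(cloud, lab[:, None] == lab[None, :], "lwph")


def interactive_matrix(cloud: WeightedPointCloud) -> FiltrationMatrix:
    """Cross-molecule distances only; intra-molecule pairs are +inf."""
    if cloud.molecule_labels is None:
        raise ValueError("interactive_matrix requires molecule labels")
    lab = np.asarray(cloud.molecule_labels, dtype=object)
    if len(set(cloud.molecule_labels)) == 1:
        warnings.warn("single molecule: every off-diagonal entry is infinite", stacklevel=2)
    return _mask_matrix(cloud, lab[:, None] == lab[None, :], "interactive")


def multilevel_matrix(
    cloud: WeightedPointCloud, mode: str = "bonded", n: float | None = None
) -> FiltrationMatrix:
    """Bonded pairs (mode='bonded') or all pairs with d <= n (mode='level-n')
    pushed to +inf; everything else Euclidean."""
    if mode == "bonded":
        bonds = cloud.bonds
        if bonds is None:
            raise ValueError("bonded mode requires a bond list (or use infer_bonds)")
        mask = np.zeros((len(cloud), len(cloud)), dtype=bool)
        for i, j in bonds:
            mask[i, j] = mask[j, i] = True
        return _mask_matrix(cloud, mask, "multilevel", {"mode": "bonded"})
    if mode == "level-n":
        if n is None:
            raise ValueError("level-n mode requires the level n")
        D = _euclidean(cloud.points)
        return _mask_matrix(cloud, D <= n, "multilevel", {"mode": "level-n", "n": n})
    raise ValueError(f"unknown multilevel mode {mode!r}")


def radius_weighted_matrix(cloud: WeightedPointCloud) -> FiltrationMatrix:
    """d(x_i, x_j) / (v_i + v_j): the weighted Vietoris-Rips matrix, whose
    sublevel edges at scale t are exactly d <= t v_i + t v_j."""
    if cloud.weights is None:
        raise ValueError("radius_weighted_matrix requires per-point weights")
    vsum = cloud.weights[:, None] + cloud.weights[None, :]
    if np.any((vsum == 0) & ~np.eye(len(cloud), dtype=bool)):
        raise ZeroDivisionError("some pair has zero weight sum")
    D = _euclidean(cloud.points)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = D / vsum
    np.fill_diagonal(M, 0.0)
    return FiltrationMatrix(M, provenance="radius-weighted")


def superlevel_edge_matrix(edge_weights: np.ndarray) -> FiltrationMatrix:
    """Turn a weighted graph into an increasing filtration matrix.

    The clique filtration of a weighted network goes from the largest
    edge weight downward: at threshold t the subgraph of edges with
    weight larger than t is formed.  Substituting w -> w_max - w turns
    that into an ordinary increasing Vietoris-Rips filtration; absent
    edges (NaN or inf input) stay +inf.  ``params['w_max']`` is recorded
    so barcodes can be reported on the original decreasing weight scale
    (birth/death -> w_max - value).
    """
    W = np.asarray(edge_weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1] or not np.allclose(W, W.T, equal_nan=True):
        raise ValueError("edge weights must form a symmetric square matrix")
    finite = np.isfinite(W) & ~np.eye(len(W), dtype=bool)
    if np.any(W[finite] < 0):
        raise ValueError("edge weights must be nonnegative")
    if not finite.any():
        raise ValueError("no finite edge weights")
    w_max = float(W[finite].max())
    M = np.full_like(W, np.inf)
    M[finite] = w_max - W[finite]
    np.fill_diagonal(M, 0.0)
    return FiltrationMatrix(M, provenance="superlevel-edge", params={"w_max": w_max})


def k_distance(query, cloud: WeightedPointCloud, k: int) -> float:
    """Root mean squared distance to the k nearest points (ties by index)."""
    if k <= 0 or k > len(cloud):
        raise ValueError(f"k must be in 1..{len(cloud)}, got {k}")
    d2 = np.sum((cloud.points - np.asarray(query, dtype=float)) ** 2, axis=1)
    order = np.argsort(d2, kind="stable")  # stable: equal distances keep index order
    return float(np.sqrt(d2[order[:k]].mean()))


def rigidity_value(query, cloud: WeightedPointCloud, kernel: KernelSpec) -> float:
    """Weighted kernel sum mu(x) = sum_i v_i Phi(d(x, x_i)); unit weights if none."""
    d = np.linalg.norm(cloud.points - np.asarray(query, dtype=float), axis=1)
    v = cloud.weights if cloud.weights is not None else np.ones(len(cloud))
    return float(np.sum(v * kernel(d)))


def infer_bonds(cloud: WeightedPointCloud, cutoff: float = BOND_CUTOFF):
    """Heavy-atom pairs within a covalent cutoff (default 1.7 Angstrom)."""
    D = _euclidean(cloud.points)
    iu = np.triu_indices(len(cloud), k=1)
    return [(int(i), int(j)) for i, j in zip(*iu) if D[i, j] <= cutoff]
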