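"""PCA over LWPH feature vectors: DNA-form classification, trajectory
clustering, and the occupancy-area confinement statistic.

The pipeline per structure (or trajectory frame) is: select atoms,
enumerate local base-step domains, build the localized weighted
distance matrix of each domain, compute its Rips barcode, sample the
PBN feature vector, and either average over domains (form
classification) or concatenate the steps in 5'->3' order (trajectory
frames).  A covariance eigendecomposition projects all samples onto the
first two principal components; confinement of an ensemble is the
number of occupancy-grid bins whose population exceeds a fraction of
the fullest bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from . import features as _features
from .features import FeatureVector, PBNCurve, average_pbn, concatenate_frame_features, featurize_step, pbn_curve
from .filtrations import WeightedPointCloud, euclidean_matrix, localized_weighted_matrix
from .rips_persistence import Barcode, barcodes_from_matrix
from .structures_io import Structure, enumerate_local_domains, select_atoms

__all__ = [
    "ProjectionSet",
    "OccupancyGrid",
    "PCAProjector",
    "LWPHVectorizer",
    "pca_fit",
    "occupancy_area",
    "classify_forms",
    "cluster_trajectory",
    "preferred_state_count",
]


# ---------------------------------------------------------------------------
# PCA with a deterministic sign convention
# ---------------------------------------------------------------------------


@dataclass
class ProjectionSet:
    """Samples projected on the first two principal components."""

    coords: np.ndarray  # (n, 2)
    eigenvalues: np.ndarray  # all covariance eigenvalues, non-increasing
    components: np.ndarray  # (2, d) orthonormal loadings
    labels: list | None = None


class PCAProjector(BaseEstimator, TransformerMixin):
    """Covariance eigendecomposition of column-mean-centered features.

    The sign of each component is fixed so its largest-magnitude loading
    is positive, making projections reproducible across runs.  Fitted
    attributes: ``components_`` (n_components, d), ``eigenvalues_`` (all
    of them), ``mean_``.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D feature matrix with at least 2 samples")
        if np.allclose(X, X[0]):
            raise ValueError("rank-0 data: all samples identical")
        pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
        pca.fit(X)
        comp = pca.components_[: self.n_components].copy()
        for row in comp:
            if row[np.argmax(np.abs(row))] < 0:
                row *= -1
        self.mean_ = pca.mean_
        self.components_ = comp
        self.eigenvalues_ = pca.explained_variance_
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def fit_project(self, X, labels=None) -> ProjectionSet:
        self.fit(X)
        return ProjectionSet(
            coords=self.transform(X),
            eigenvalues=self.eigenvalues_,
            components=self.components_,
            labels=list(labels) if labels is not None else None,
        )


def pca_fit(features: np.ndarray, labels=None) -> ProjectionSet:
    """Project feature rows onto the first two principal components."""
    return PCAProjector(n_components=2).fit_project(features, labels)


# ---------------------------------------------------------------------------
# occupancy area
# ---------------------------------------------------------------------------


@dataclass
class OccupancyGrid:
    """A 2-D histogram of PCA projections."""

    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    threshold: float


def occupancy_area(
    projections,
    bins: int = 50,
    threshold: float = 0.05,
    extent=None,
    pad: float = 0.05,
) -> tuple[int, OccupancyGrid]:
    """Number of grid cells with population strictly above ``threshold``
    times the largest cell population.

    The grid defaults to the bounding box of the projections padded by
    5% per side; pass ``extent`` ((xmin, xmax), (ymin, ymax)) to compare
    ensembles on a shared grid.
    """
    pts = projections.coords if isinstance(projections, ProjectionSet) else np.asarray(projections, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("projections must be a non-empty (n, 2) array")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if extent is None:
        (xmin, ymin), (xmax, ymax) = pts.min(axis=0), pts.max(axis=0)
        dx = (xmax - xmin) or 1.0
        dy = (ymax - ymin) or 1.0
        extent = ((xmin - pad * dx, xmax + pad * dx), (ymin - pad * dy, ymax + pad * dy))
    (xmin, xmax), (ymin, ymax) = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate occupancy grid extent")
    counts, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins, range=extent)
    area = int(np.sum(counts > threshold * counts.max()))
    return area, OccupancyGrid(counts, xe, ye, threshold)


# ---------------------------------------------------------------------------
# structure -> feature pipeline
# ---------------------------------------------------------------------------

_MATRIX_BUILDERS = {"lwph": localized_weighted_matrix, "euclidean": euclidean_matrix}


def _domain_barcodes(
    structure: Structure,
    selection: str,
    matrix: str,
    window: str,
    exclude_terminal: bool,
    max_scale: float,
) -> list[Barcode]:
    selected = select_atoms(structure, selection)
    domains = enumerate_local_domains(selected, window, exclude_terminal)
    build = _MATRIX_BUILDERS[matrix]
    out = []
    for domain in domains:
        if len(set(domain.residues)) < 2:
            raise ValueError(f"domain {domain.label} has fewer than 2 residues")
        sub = selected.subset(domain.atom_indices)
        out.append(barcodes_from_matrix(build(WeightedPointCloud.from_structure(sub)), max_scale))
    return out


class LWPHVectorizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: structures (or trajectory frames) to
    localized-persistence feature rows.

    ``aggregate='mean'`` averages the per-step 120-vectors (one row per
    structure, used for form classification); ``aggregate='concat'``
    concatenates the steps (1560 values for a 16-mer's 13 non-terminal
    steps, used for trajectory frames).
    """

    def __init__(
        self,
        selection: str = "base+C1'",
        matrix: str = "lwph",
        window: str = "base-step",
        exclude_terminal: bool = True,
        max_scale: float = 8.0,
        aggregate: str = "mean",
    ):
        self.selection = selection
        self.matrix = matrix
        self.window = window
        self.exclude_terminal = exclude_terminal
        self.max_scale = max_scale
        self.aggregate = aggregate

    def fit(self, X, y=None):
        return self

    def _frame_vector(self, barcodes: list[Barcode]) -> np.ndarray:
        vecs = [featurize_step(bc) for bc in barcodes]
        if self.aggregate == "concat":
            return concatenate_frame_features(vecs).values
        if self.aggregate == "mean":
            return np.mean([v.values for v in vecs], axis=0)
        raise ValueError(f"unknown aggregate {self.aggregate!r}")

    def transform(self, X) -> np.ndarray:
        if isinstance(X, Structure):
            X = list(X.frames())
        rows = []
        for structure in X:
            barcodes = _domain_barcodes(
                structure, self.selection, self.matrix, self.window,
                self.exclude_terminal, self.max_scale,
            )
            if not barcodes:
                raise ValueError("structure yields no local domains")
            rows.append(self._frame_vector(barcodes))
        return np.stack(rows)


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------


def classify_forms(
    structures: list[Structure],
    labels: list,
    selection: str = "base+C1'",
    matrix: str = "lwph",
    exclude_terminal: bool = False,
    max_scale: float = 8.0,
):
    """Project labelled DNA structures onto the LWPH feature plane.

    Per structure: base-step LWPH barcodes -> per-step PBN vectors ->
    mean over steps; PCA over all structures.  Also returns the average
    PBN curve (aPBN) per form and homology dimension.  Structures whose
    domains cannot be built are skipped with a warning.
    """
    if len(structures) != len(labels):
        raise ValueError("one label per structure required")
    rows, kept_labels = [], []
    curves: dict = {}
    for structure, label in zip(structures, labels):
        try:
            barcodes = _domain_barcodes(
                structure, selection, matrix, "base-step", exclude_terminal, max_scale
            )
        except ValueError as exc:
            warnings.warn(f"skipping structure labelled {label!r}: {exc}", stacklevel=2)
            continue
        if not barcodes:
            warnings.warn(f"skipping structure labelled {label!r}: no local domains", stacklevel=2)
            continue
        vecs = [featurize_step(bc) for bc in barcodes]
        rows.append(np.mean([v.values for v in vecs], axis=0))
        kept_labels.append(label)
        for k in (0, 1):
            curves.setdefault(label, {}).setdefault(k, []).extend(
                pbn_curve(bc, dim=k) for bc in barcodes
            )
    if len(rows) < 2:
        raise ValueError("need at least two usable structures")
    projections = pca_fit(np.stack(rows), kept_labels)
    apbn = {
        form: {k: average_pbn(cs) for k, cs in per_dim.items()}
        for form, per_dim in curves.items()
    }
    return projections, apbn


def cluster_trajectory(
    trajectories,
    pool: bool = False,
    bins: int = 50,
    threshold: float = 0.05,
    selection: str = "base+C1'",
    max_scale: float = 8.0,
):
    """PCA + occupancy analysis of one or several DNA trajectories.

    Each frame contributes the concatenation of its non-terminal
    base-step LWPH features.  With ``pool=True`` (several trajectories),
    the PCA is fitted on the pooled frames and each trajectory is
    projected with the shared components and counted on the shared
    occupancy grid, so areas are comparable.

    Returns a dict with projections, eigenvalues, occupancy grid spec
    and area(s).
    """
    single = isinstance(trajectories, Structure)
    traj_list = [trajectories] if single else list(trajectories)
    vec = LWPHVectorizer(selection=selection, aggregate="concat", max_scale=max_scale)
    blocks = [vec.transform(t) for t in traj_list]
    X = np.vstack(blocks)
    if X.shape[0] < 2:
        raise ValueError("need at least two frames")
    projector = PCAProjector(n_components=2)
    proj_all = projector.fit_project(X)
    (xmin, ymin), (xmax, ymax) = proj_all.coords.min(axis=0), proj_all.coords.max(axis=0)
    dx, dy = (xmax - xmin) or 1.0, (ymax - ymin) or 1.0
    extent = ((xmin - 0.05 * dx, xmax + 0.05 * dx), (ymin - 0.05 * dy, ymax + 0.05 * dy))
    area_all, grid = occupancy_area(proj_all, bins=bins, threshold=threshold, extent=extent)
    report = {
        "projections": proj_all,
        "eigenvalues": proj_all.eigenvalues,
        "area": area_all,
        "grid": grid,
        "extent": extent,
        "bins": bins,
        "threshold": threshold,
    }
    if pool and not single:
        per_traj = []
        start = 0
        for block in blocks:
            coords = projector.transform(block)
            area, _ = occupancy_area(coords, bins=bins, threshold=threshold, extent=extent)
            per_traj.append({"n_frames": len(block), "area": area, "coords": coords})
            start += len(block)
        report["per_trajectory"] = per_traj
    return report


def preferred_state_count(values, max_components: int = 3, seed: int = 0) -> int:
    """Number of 1-D Gaussian mixture components preferred by BIC."""
    from sklearn.mixture import GaussianMixture

    values = np.asarray(values, dtype=float).reshape(-1, 1)
    bics = []
    for k in range(1, max_components + 1):
        gm = GaussianMixture(n_components=k, n_init=5, random_state=seed)
        gm.fit(values)
        bics.append(gm.bic(values))
    return int(np.argmin(bics)) + 1
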