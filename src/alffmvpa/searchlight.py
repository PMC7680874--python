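"""Searchlight multivariate pattern classification on zALFF maps.

At each in-mask voxel a 9-mm sphere of neighbouring voxel values forms the
feature matrix (subjects x sphere voxels), reduced by PCA to the components
explaining 90% of variance and classified patient-vs-control with a
linear soft-margin SVM (cost 1) under leave-one-out cross-validation. The
per-voxel held-out accuracy forms a 3D accuracy map; "meaningful" clusters
are connected components of accuracy >= 70% larger than 50 voxels, each
reported by its peak accuracy and peak MNI coordinate.

PCA can be fitted per training fold (default; no train/test leakage) or
once globally on all subjects — the two readings of an ambiguous protocol;
both are first-class via ``pca_scope``. The whole module is deterministic:
identical inputs give bit-identical maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _smo
from .alff import ZAlffMap
from .exceptions import DegenerateDataError, InvalidArgumentError
from .spatial import ClusterSet, Mask, VolumeGrid, label_clusters, sphere_offsets

__all__ = [
    "FeatureMatrix",
    "pca_reduce",
    "loocv_accuracy",
    "loocv_decisions",
    "SearchlightClassifier",
    "SearchlightResults",
    "extract_meaningful_clusters",
    "stack_to_matrix",
]


@dataclass
class FeatureMatrix:
    """Subjects-by-features matrix with row/column provenance."""

    values: np.ndarray          # (n_subjects, n_features)
    subject_ids: list[str]
    feature_info: object = None  # e.g. voxel indices the columns came from

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InvalidArgumentError("feature matrix must be 2D")
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError("feature matrix contains missing values")
        if len(self.subject_ids) != v.shape[0]:
            raise InvalidArgumentError("row labels do not match row count")
        self.values = v

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


def pca_reduce(features: FeatureMatrix | np.ndarray, cum_threshold: float = 0.90):
    """Project onto the smallest set of principal components reaching
    ``cum_threshold`` cumulative explained variance.

    Returns ``(scores, k, loadings)`` where loadings has one column per
    retained component (eigenvectors of the column-centred covariance).
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise InvalidArgumentError("need >= 2 rows and >= 1 column for PCA")
    if not (0 < cum_threshold <= 1.0):
        raise InvalidArgumentError("cum_threshold must be in (0, 1]")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ev = s**2
    total = ev.sum()
    if total <= 0:
        raise DegenerateDataError("zero total variance; PCA undefined")
    # numerical rank cut-off, then smallest k reaching the threshold
    nonzero = ev > ev[0] * 1e-12
    frac = np.cumsum(ev) / total
    k = int(np.searchsorted(frac, cum_threshold - 1e-12) + 1)
    k = min(k, int(nonzero.sum()))
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    if isinstance(features, FeatureMatrix):
        scores = FeatureMatrix(scores, features.subject_ids,
                               feature_info=f"top-{k} principal components")
    return scores, k, loadings


def _as_signed_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    uniq = np.unique(y)
    if len(uniq) != 2:
        raise InvalidArgumentError(f"labels must contain exactly 2 classes, got {uniq}")
    if set(uniq.tolist()) == {-1, 1}:
        return y.astype(float)
    # map the larger label to +1 (patient convention: +1 = positive class)
    return np.where(y == uniq[1], 1.0, -1.0)


def loocv_decisions(features, labels, C: float = 1.0) -> np.ndarray:
    """Held-out decision values of a linear SVC under leave-one-out CV."""
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = _as_signed_labels(labels)
    if X.shape[0] != len(y):
        raise InvalidArgumentError("features and labels disagree on subject count")
    if X.shape[0] < 4:
        raise InvalidArgumentError("need at least 4 subjects for LOOCV")
    G = np.ascontiguousarray(X @ X.T)
    return _smo.loocv_decisions(G, y, C, _smo.DEFAULT_TOL)


def loocv_accuracy(features, labels, C: float = 1.0) -> float:
    """Leave-one-out accuracy of a linear SVC (cost ``C``) on the features.

    Decision values of exactly 0 predict the positive class.
    """
    y = _as_signed_labels(labels)
    dec = loocv_decisions(features, labels, C=C)
    pred = np.where(dec >= 0, 1.0, -1.0)
    return float(np.mean(pred == y))


def stack_to_matrix(zalff_stack: list[ZAlffMap] | dict[str, ZAlffMap]):
    """Flatten a stack of zALFF maps to (ids, grid, mask, data (n, x, y, z))."""
    if isinstance(zalff_stack, dict):
        ids = list(zalff_stack.keys())
        maps = [zalff_stack[i] for i in ids]
    else:
        maps = list(zalff_stack)
        ids = [f"subject{i}" for i in range(len(maps))]
    if not maps:
        raise InvalidArgumentError("empty zALFF stack")
    grid = maps[0].grid
    for m in maps[1:]:
        if not m.grid.matches(grid):
            raise InvalidArgumentError("zALFF maps are not on a common grid")
    data = np.stack([m.data for m in maps])
    return ids, grid, maps[0].mask, data


class SearchlightClassifier:
    """Voxelwise searchlight classification model.

    Parameters
    ----------
    zalff_stack : dict or list of ZAlffMap
        One standardized amplitude map per subject.
    labels : array-like
        Binary group labels aligned with the stack (+1 patient, -1 control).
    mask : Mask, optional
        Analysis mask; defaults to the stack's own mask.
    radius_mm : float
        Searchlight sphere radius (default 9 mm).
    cum_threshold : float
        PCA cumulative explained-variance threshold (default 0.90).
    pca_scope : {"per_fold", "global"}
        Fit PCA inside each LOOCV training fold (default) or once on all
        subjects.
    min_sphere_voxels : int
        Spheres truncated by the mask edge below this size are skipped.
    C : float
        SVM cost parameter.
    """

    def __init__(self, zalff_stack, labels, mask: Mask | None = None,
                 radius_mm: float = 9.0, cum_threshold: float = 0.90,
                 pca_scope: str = "per_fold", min_sphere_voxels: int = 10,
                 C: float = 1.0):
        if pca_scope not in ("per_fold", "global"):
            raise InvalidArgumentError(f"unknown pca_scope {pca_scope!r}")
        self.subject_ids, self.grid, stack_mask, self.data = stack_to_matrix(zalff_stack)
        self.mask = mask if mask is not None else stack_mask
        if not self.mask.grid.matches(self.grid):
            raise InvalidArgumentError("mask grid does not match zALFF grid")
        self.mask.require_nonempty()
        self.labels = _as_signed_labels(labels)
        if len(self.labels) != len(self.subject_ids):
            raise InvalidArgumentError("labels do not align with the stack")
        self.radius_mm = float(radius_mm)
        self.cum_threshold = float(cum_threshold)
        self.pca_scope = pca_scope
        self.min_sphere_voxels = int(min_sphere_voxels)
        self.C = float(C)

    def fit(self, verbose: bool = False) -> "SearchlightResults":
        """Run the searchlight over every eligible mask voxel."""
        grid, mask = self.grid, self.mask
        n = len(self.subject_ids)
        offsets = sphere_offsets(self.radius_mm, grid.voxel_size)

        mask_idx = mask.indices  # (m, 3), lexicographic
        dims = np.asarray(grid.dims)
        # map linear voxel index -> column in the in-mask data matrix
        lin_of = np.ravel_multi_index(mask_idx.T, dims)
        col_of = -np.ones(int(np.prod(dims)), dtype=np.int64)
        col_of[lin_of] = np.arange(len(lin_of))
        V = np.ascontiguousarray(
            self.data.reshape(n, -1)[:, lin_of])  # (n, m) in-mask values

        # neighbour columns per centre voxel (vectorised sphere lookup)
        neigh = mask_idx[:, None, :] + offsets[None, :, :]       # (m, o, 3)
        inside = np.all((neigh >= 0) & (neigh < dims), axis=2)
        neigh_lin = np.zeros(neigh.shape[:2], dtype=np.int64)
        neigh_lin[inside] = np.ravel_multi_index(neigh[inside].T, dims)
        neigh_col = np.where(inside, col_of[neigh_lin], -1)      # (m, o)

        flat_acc = _smo.searchlight_accuracies(
            V, np.ascontiguousarray(neigh_col), self.labels.astype(float),
            self.cum_threshold, self.C, _smo.DEFAULT_TOL,
            self.min_sphere_voxels, self.pca_scope == "per_fold")
        acc = np.full(grid.dims, np.nan)
        acc[tuple(mask_idx.T)] = flat_acc
        n_done = int(np.isfinite(flat_acc).sum())
        if verbose:
            print(f"searchlight: {n_done} voxels classified")
        return SearchlightResults(model=self, accuracy_map=acc, n_voxels=n_done)


@dataclass
class SearchlightResults:
    """Voxelwise accuracy map and cluster extraction."""

    model: SearchlightClassifier
    accuracy_map: np.ndarray  # NaN where undefined
    n_voxels: int
    _cluster_cache: dict = field(default_factory=dict, repr=False)

    @property
    def grid(self) -> VolumeGrid:
        return self.model.grid

    def accuracies(self) -> np.ndarray:
        """Defined accuracy values (flat)."""
        return self.accuracy_map[np.isfinite(self.accuracy_map)]

    def meaningful_clusters(self, acc_threshold: float = 0.70, min_size: int = 50,
                            connectivity: int = 26) -> ClusterSet:
        key = (acc_threshold, min_size, connectivity)
        if key not in self._cluster_cache:
            self._cluster_cache[key] = extract_meaningful_clusters(
                self.accuracy_map, self.grid, acc_threshold=acc_threshold,
                min_size=min_size, connectivity=connectivity)
        return self._cluster_cache[key]

    def summary(self, acc_threshold: float = 0.70, min_size: int = 50,
                connectivity: int = 26) -> str:
        vals = self.accuracies()
        cs = self.meaningful_clusters(acc_threshold, min_size, connectivity)
        lines = [
            "Searchlight classification summary",
            "==================================",
            f"subjects:            {len(self.model.subject_ids)}",
            f"voxels classified:   {self.n_voxels}",
            f"sphere radius:       {self.model.radius_mm} mm",
            f"PCA threshold/scope: {self.model.cum_threshold} / {self.model.pca_scope}",
            f"accuracy mean (max): {vals.mean():.3f} ({vals.max():.3f})",
            f"clusters >= {acc_threshold:.0%} and > {min_size} voxels: {len(cs)}",
        ]
        if len(cs):
            lines.append(cs.to_table().to_string(index=False))
        return "\n".join(lines)


def extract_meaningful_clusters(acc_map: np.ndarray, grid: VolumeGrid,
                                acc_threshold: float = 0.70, min_size: int = 50,
                                connectivity: int = 26) -> ClusterSet:
    """Connected components of accuracy >= threshold, strictly larger than
    ``min_size`` voxels, with peak accuracy and peak MNI coordinate."""
    acc_map = np.asarray(acc_map, dtype=float)
    with np.errstate(invalid="ignore"):
        binary = acc_map >= acc_threshold
    cs = label_clusters(binary, grid, values=np.nan_to_num(acc_map, nan=-np.inf),
                        connectivity=connectivity)
    kept = [c for c in cs.clusters if c.size > min_size]
    return ClusterSet(grid=grid, clusters=kept)
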