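"""Overall patient-vs-control classification from meaningful clusters.

Concatenates the zALFF values of every voxel inside the meaningful
classifying clusters into one feature matrix, evaluates a linear SVC under
the same leave-one-out protocol as the searchlight, and reports accuracy,
sensitivity, specificity and AUC with permutation p-values (label shuffles,
add-one rule). Cluster masks are fixed before permutation — they are not
re-derived per shuffle, matching the sequential design of the emulated
analysis; this is a documented optimism source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _smo
from .exceptions import InvalidArgumentError
from .searchlight import FeatureMatrix, _as_signed_labels, stack_to_matrix
from .spatial import ClusterSet

__all__ = [
    "assemble_cluster_features",
    "classification_metrics",
    "permutation_test",
    "permutation_pvalue",
    "ClusterClassifier",
    "ClassificationResults",
]


def assemble_cluster_features(zalff_stack, cluster_set: ClusterSet) -> FeatureMatrix:
    """One column per cluster voxel (cluster order, then lexicographic voxel
    index), one row per subject."""
    if len(cluster_set) == 0:
        raise InvalidArgumentError("cluster set is empty")
    ids, grid, _, data = stack_to_matrix(zalff_stack)
    if not cluster_set.grid.matches(grid):
        raise InvalidArgumentError("cluster grid does not match zALFF grid")
    cols = []
    info = []
    for c in cluster_set:
        cols.append(data[(slice(None),) + tuple(c.voxel_indices.T)])
        info.extend(map(tuple, c.voxel_indices))
    return FeatureMatrix(np.hstack(cols), ids, feature_info=info)


def classification_metrics(labels, predictions, decision_values):
    """(accuracy, sensitivity, specificity, auc).

    Sensitivity is computed on the positive (patient) class, specificity on
    the negative class; AUC is the Mann-Whitney statistic of the decision
    values with ties counted 1/2.
    """
    y = _as_signed_labels(labels)
    pred = np.asarray(predictions, dtype=float)
    dec = np.asarray(decision_values, dtype=float)
    pos = y > 0
    neg = ~pos
    accuracy = float(np.mean(pred == y))
    sensitivity = float(np.mean(pred[pos] == 1))
    specificity = float(np.mean(pred[neg] == -1))
    auc = _rank_auc(dec, pos)
    return accuracy, sensitivity, specificity, auc


def _rank_auc(decision_values: np.ndarray, positive: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U of decision values (ties 1/2)."""
    from scipy.stats import rankdata

    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    ranks = rankdata(decision_values)  # average ranks handle ties as 1/2
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def permutation_pvalue(observed: float, permuted: np.ndarray,
                       larger_is_extreme: bool = True) -> float:
    """Add-one permutation p-value: (1 + #{perm at least as extreme}) / (1 + P)."""
    permuted = np.asarray(permuted, dtype=float)
    if larger_is_extreme:
        count = int(np.sum(permuted >= observed - 1e-12))
    else:
        count = int(np.sum(permuted <= observed + 1e-12))
    return (1 + count) / (1 + len(permuted))


def permutation_test(observed_stat: float, stat_recompute, labels,
                     n_perm: int = 5000, seed: int = 0,
                     larger_is_extreme: bool = True) -> float:
    """Generic label-shuffle permutation test.

    ``stat_recompute`` is called with each permuted label vector and must be
    deterministic given the labels. Permutations are uniform shuffles drawn
    from ``seed``.
    """
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    stats = np.empty(n_perm)
    for i in range(n_perm):
        stats[i] = stat_recompute(rng.permutation(labels))
    return permutation_pvalue(observed_stat, stats, larger_is_extreme)


class ClusterClassifier:
    """Overall linear SVC on concatenated cluster voxels, LOOCV evaluated.

    Parameters
    ----------
    zalff_stack : dict or list of ZAlffMap
    labels : array-like, +1 patient / -1 control
    clusters : ClusterSet
        Meaningful classifying clusters (fixed; not re-derived during
        permutation).
    C : float
        SVM cost parameter (default 1, the LIBSVM default).
    """

    def __init__(self, zalff_stack, labels, clusters: ClusterSet, C: float = 1.0):
        self.features = assemble_cluster_features(zalff_stack, clusters)
        self.labels = _as_signed_labels(labels)
        if len(self.labels) != self.features.n_subjects:
            raise InvalidArgumentError("labels do not align with the stack")
        self.clusters = clusters
        self.C = float(C)
        self._gram = np.ascontiguousarray(self.features.values @ self.features.values.T)

    def fit(self) -> "ClassificationResults":
        dec = _smo.loocv_decisions(self._gram, self.labels, self.C, _smo.DEFAULT_TOL)
        pred = np.where(dec >= 0, 1.0, -1.0)
        acc, sens, spec, auc = classification_metrics(self.labels, pred, dec)
        return ClassificationResults(
            model=self, accuracy=acc, sensitivity=sens, specificity=spec, auc=auc,
            predictions=pred, decision_values=dec)


@dataclass
class ClassificationResults:
    """LOOCV performance of the overall classifier."""

    model: ClusterClassifier
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    predictions: np.ndarray
    decision_values: np.ndarray
    permutation_p_accuracy: float | None = None
    permutation_p_auc: float | None = None
    n_perm: int | None = None
    seed: int | None = None

    def permutation_test(self, n_perm: int = 5000, seed: int = 0) -> "ClassificationResults":
        """Label-shuffle significance of accuracy and AUC (add-one rule).

        The full LOOCV protocol is recomputed for every shuffle; cluster
        masks stay fixed.
        """
        if n_perm < 1:
            raise InvalidArgumentError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        y = self.model.labels
        perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
        G = self.model._gram
        dec = _smo.loocv_decision_perms(G, perms, self.model.C, _smo.DEFAULT_TOL)
        pred = np.where(dec >= 0, 1.0, -1.0)
        accs = (pred == perms).mean(axis=1)
        pos = perms > 0
        aucs = np.empty(n_perm)
        for i in range(n_perm):
            aucs[i] = _rank_auc(dec[i], pos[i])
        self.permutation_p_accuracy = permutation_pvalue(self.accuracy, accs)
        self.permutation_p_auc = permutation_pvalue(self.auc, aucs)
        self.n_perm = n_perm
        self.seed = seed
        return self

    def roc_points(self) -> np.ndarray:
        """(false positive rate, true positive rate) pairs over thresholds."""
        y = self.model.labels
        order = np.argsort(-self.decision_values, kind="stable")
        ys = y[order]
        tp = np.concatenate([[0], np.cumsum(ys > 0)])
        fp = np.concatenate([[0], np.cumsum(ys < 0)])
        return np.column_stack([fp / max(fp[-1], 1), tp / max(tp[-1], 1)])

    def summary(self) -> str:
        lines = [
            "Overall classifier (linear SVC, LOOCV)",
            "======================================",
            f"subjects:     {len(self.model.labels)}",
            f"features:     {self.model.features.values.shape[1]} cluster voxels",
            f"accuracy:     {self.accuracy:.4f}",
            f"sensitivity:  {self.sensitivity:.4f}",
            f"specificity:  {self.specificity:.4f}",
            f"AUC:          {self.auc:.4f}",
        ]
        if self.permutation_p_accuracy is not None:
            lines += [
                f"p(accuracy):  {self.permutation_p_accuracy:.4g} "
                f"({self.n_perm} permutations, seed {self.seed})",
                f"p(AUC):       {self.permutation_p_auc:.4g}",
            ]
        return "\n".join(lines)
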