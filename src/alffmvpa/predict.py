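"""Predicting symptom improvement from regional zALFF with repeated-CV SVR.

A linear epsilon-SVR (cost 1, epsilon 0.1 — the LIBSVM defaults) maps one
region's voxel values to each completer's symptom improvement
(baseline minus post-treatment; positive = improvement). Performance is
summarized per repetition of a fresh random 10-fold cross-validation by

* ``R^2`` — the *squared Pearson correlation* between actual and pooled
  out-of-fold predicted outcomes (the convention of the emulated analysis;
  this is not the coefficient of determination and is always >= 0), and
* ``MSE`` — the mean squared difference.

Because the squared-correlation R^2 is known to be optimistic, the
conventional coefficient of determination is also reported under
``q2`` in the results for transparency. Significance per repetition comes
from outcome shuffles (add-one rule); aggregates are mean +/- SD over
repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _smo
from .classify import permutation_pvalue
from .exceptions import DegenerateDataError, InvalidArgumentError
from .searchlight import FeatureMatrix

__all__ = [
    "r2_and_mse",
    "improvement",
    "EfficacyPredictor",
    "PredictionResults",
]


def r2_and_mse(actual, predicted) -> tuple[float, float]:
    """Squared prediction-outcome correlation and mean squared error.

    Note the squared-correlation definition: a perfectly anti-correlated
    prediction also scores R^2 = 1. MSE is the plain mean of squared
    differences.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise InvalidArgumentError("actual and predicted must be equal-length vectors")
    if len(a) < 3:
        raise InvalidArgumentError("need at least 3 pairs")
    if np.ptp(a) == 0:
        raise DegenerateDataError("actual outcome is constant")
    mse = float(np.mean((a - p) ** 2))
    if np.ptp(p) == 0:
        return 0.0, mse  # degenerate prediction carries no correlation
    r = np.corrcoef(a, p)[0, 1]
    return float(r * r), mse


def improvement(outcome_baseline, outcome_post):
    """Per-subject change, baseline minus post; positive = improvement.

    Subjects with a missing post value are dropped; returns (change vector,
    boolean inclusion mask over the input).
    """
    base = np.asarray(outcome_baseline, dtype=float)
    post = np.asarray(outcome_post, dtype=float)
    if base.shape != post.shape:
        raise InvalidArgumentError("baseline and post vectors differ in length")
    keep = np.isfinite(base) & np.isfinite(post)
    return base[keep] - post[keep], keep


def _coefficient_of_determination(actual: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = np.sum((actual - predicted) ** 2)
    ss_tot = np.sum((actual - actual.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot)


class EfficacyPredictor:
    """Repeated 10-fold SVR prediction of symptom improvement.

    Parameters
    ----------
    features : FeatureMatrix or ndarray
        One region's voxel values, one row per completer.
    outcome_change : array-like
        Improvement scores aligned with the rows.
    n_folds, n_repeats : int
        Cross-validation layout (defaults 10 folds, 100 repetitions).
    n_perm : int
        Outcome shuffles per repetition for the permutation p-values
        (default 500; configurable up to taste).
    C, epsilon : float
        epsilon-SVR parameters (LIBSVM defaults 1 and 0.1).
    """

    def __init__(self, features, outcome_change, n_folds: int = 10,
                 n_repeats: int = 100, n_perm: int = 500,
                 C: float = 1.0, epsilon: float = 0.1):
        X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
        if X.ndim != 2:
            raise InvalidArgumentError("features must be 2D")
        z = np.asarray(outcome_change, dtype=float)
        if len(z) != X.shape[0]:
            raise InvalidArgumentError("outcome length does not match feature rows")
        if np.ptp(z) == 0:
            raise DegenerateDataError("outcome change is constant")
        if n_folds < 2 or n_folds > len(z):
            raise InvalidArgumentError(
                f"n_folds must be in [2, {len(z)}], got {n_folds}")
        self.X = X
        self.z = z
        self.n_folds = int(n_folds)
        self.n_repeats = int(n_repeats)
        self.n_perm = int(n_perm)
        self.C = float(C)
        self.epsilon = float(epsilon)
        self._gram = np.ascontiguousarray(X @ X.T)

    def _fold_ids(self, rng: np.random.Generator) -> np.ndarray:
        """Random unstratified folds with sizes differing by at most 1."""
        n = len(self.z)
        ids = np.arange(n) % self.n_folds
        return rng.permutation(ids).astype(np.int64)

    def fit(self, seed: int = 0) -> "PredictionResults":
        """Run all repetitions; identical seed gives bit-identical results."""
        tol = _smo.DEFAULT_TOL
        n = len(self.z)
        r2s = np.empty(self.n_repeats)
        mses = np.empty(self.n_repeats)
        q2s = np.empty(self.n_repeats)
        p_r2 = np.empty(self.n_repeats)
        p_mse = np.empty(self.n_repeats)
        rep_seeds = seed + np.arange(self.n_repeats)
        last_pred = None
        last_folds = None
        for rep in range(self.n_repeats):
            rng = np.random.default_rng(int(rep_seeds[rep]))
            folds = self._fold_ids(rng)
            pred = _smo.svr_cv_predictions(self._gram, self.z, folds, self.n_folds,
                                           self.C, self.epsilon, tol)
            r2s[rep], mses[rep] = r2_and_mse(self.z, pred)
            q2s[rep] = _coefficient_of_determination(self.z, pred)
            if self.n_perm > 0:
                z_perms = np.stack([rng.permutation(self.z) for _ in range(self.n_perm)])
                pr2, pmse = _smo.svr_cv_perm_stats(self._gram, z_perms, folds,
                                                   self.n_folds, self.C,
                                                   self.epsilon, tol)
                p_r2[rep] = permutation_pvalue(r2s[rep], pr2, larger_is_extreme=True)
                p_mse[rep] = permutation_pvalue(mses[rep], pmse, larger_is_extreme=False)
            else:
                p_r2[rep] = np.nan
                p_mse[rep] = np.nan
            last_pred = pred
            last_folds = folds
        return PredictionResults(
            model=self, r2=r2s, mse=mses, q2=q2s, p_r2=p_r2, p_mse=p_mse,
            seed=seed, last_predictions=last_pred, last_fold_ids=last_folds)


@dataclass
class PredictionResults:
    """Per-repetition prediction performance and aggregates."""

    model: EfficacyPredictor
    r2: np.ndarray
    mse: np.ndarray
    q2: np.ndarray     # coefficient of determination, for transparency
    p_r2: np.ndarray
    p_mse: np.ndarray
    seed: int
    last_predictions: np.ndarray = field(repr=False, default=None)
    last_fold_ids: np.ndarray = field(repr=False, default=None)

    @property
    def r2_mean(self) -> float:
        return float(self.r2.mean())

    @property
    def r2_sd(self) -> float:
        return float(self.r2.std(ddof=1)) if len(self.r2) > 1 else 0.0

    @property
    def mse_mean(self) -> float:
        return float(self.mse.mean())

    @property
    def mse_sd(self) -> float:
        return float(self.mse.std(ddof=1)) if len(self.mse) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "repetition": np.arange(len(self.r2)),
            "r2": self.r2,
            "mse": self.mse,
            "q2": self.q2,
            "p_r2": self.p_r2,
            "p_mse": self.p_mse,
        })

    def scatter_data(self) -> pd.DataFrame:
        """Actual vs pooled out-of-fold predicted values of the last repetition."""
        return pd.DataFrame({
            "actual": self.model.z,
            "predicted": self.last_predictions,
            "fold": self.last_fold_ids,
        })

    def summary(self) -> str:
        reps = len(self.r2)
        lines = [
            "SVR efficacy prediction (linear kernel, repeated 10-fold CV)",
            "============================================================",
            f"subjects:    {len(self.model.z)}",
            f"features:    {self.model.X.shape[1]} voxels",
            f"repetitions: {reps} (seed {self.seed})",
            f"R^2 (squared correlation): {self.r2_mean:.3f} +/- {self.r2_sd:.3f}",
            f"MSE:                       {self.mse_mean:.3f} +/- {self.mse_sd:.3f}",
            f"coefficient of determination: {self.q2.mean():.3f} +/- "
            f"{self.q2.std(ddof=1) if reps > 1 else 0.0:.3f}",
        ]
        if np.isfinite(self.p_r2).any():
            lines += [
                f"p(R^2):  {np.nanmean(self.p_r2):.4f} +/- {np.nanstd(self.p_r2, ddof=1) if reps > 1 else 0.0:.4f} "
                f"({self.model.n_perm} shuffles per repetition)",
                f"p(MSE):  {np.nanmean(self.p_mse):.4f} +/- {np.nanstd(self.p_mse, ddof=1) if reps > 1 else 0.0:.4f}",
            ]
        return "\n".join(lines)
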