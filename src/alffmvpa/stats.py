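"""Voxelwise correlation maps, longitudinal ROI tests, and change-improvement
correlations.

Three analyses around the classifying clusters:

* :func:`voxelwise_correlation` — per-voxel Pearson correlation between
  zALFF and a clinical variable within an analysis mask, thresholded at
  uncorrected p < 0.05 and clustered (size >= 20 by default, the stated
  cluster rule for correlation maps).
* :func:`roi_paired_ttest` — voxelwise paired t-test between pre- and
  post-treatment maps inside a region of interest, family-wise error
  controlled by Bonferroni over the ROI voxels. Differences are
  pre minus post, so a positive t means a decrease after treatment.
* :func:`change_correlation` — Pearson correlation between the per-subject
  ROI-mean zALFF change and the symptom improvement.

p-values come from the exact t-transform of r (n-2 degrees of freedom) and
Student's t, via scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateDataError, InvalidArgumentError
from .searchlight import stack_to_matrix
from .spatial import ClusterSet, Mask, VolumeGrid, label_clusters

__all__ = [
    "CorrelationMap",
    "PairedTestResult",
    "voxelwise_correlation",
    "mean_roi_series",
    "roi_paired_ttest",
    "change_correlation",
]


@dataclass
class CorrelationMap:
    """Per-voxel r and p within the analysis mask, with suprathreshold clusters."""

    grid: VolumeGrid
    r_map: np.ndarray          # NaN outside analysis mask
    p_map: np.ndarray
    clusters: ClusterSet       # components of p < threshold with size >= min_size
    p_threshold: float
    min_size: int

    def to_table(self) -> pd.DataFrame:
        tab = self.clusters.to_table()
        if len(tab):
            tab = tab.rename(columns={"peak_value": "peak_r"})
        return tab


@dataclass
class PairedTestResult:
    """Voxelwise paired t inside an ROI with Bonferroni FWE control."""

    grid: VolumeGrid
    roi: Mask
    t_map: np.ndarray
    p_map: np.ndarray
    alpha: float
    corrected_threshold: float      # per-voxel p threshold after Bonferroni
    significant: ClusterSet         # clusters of FWE-significant voxels (peak |t|)
    n_excluded: int                 # zero-variance voxels outside the corrected family
    pre_means: np.ndarray           # per-subject ROI means, pre
    post_means: np.ndarray

    @property
    def n_significant(self) -> int:
        return self.significant.total_voxels

    def summary(self) -> str:
        return "\n".join([
            "ROI paired t-test (pre vs post treatment)",
            "=========================================",
            f"ROI voxels:          {self.roi.n_voxels}",
            f"pairs:               {len(self.pre_means)}",
            f"alpha (FWE):         {self.alpha} (Bonferroni: p < {self.corrected_threshold:.3g})",
            f"significant voxels:  {self.n_significant}",
            f"zero-variance voxels excluded: {self.n_excluded}",
        ])


def _pearson_with_p(x: np.ndarray, Y: np.ndarray):
    """Pearson r of x against each column of Y, with two-tailed t-transform p."""
    n = len(x)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((Yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ Yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), p, np.where(np.isnan(r), np.nan, 0.0))
    return r, p


def voxelwise_correlation(zalff_stack, clinical_var, analysis_mask: Mask,
                          p_threshold: float = 0.05, min_size: int = 20,
                          connectivity: int = 26) -> CorrelationMap:
    """Voxel-based correlation between zALFF and a per-subject scalar.

    Suprathreshold clusters are connected components of {p < p_threshold}
    with size >= ``min_size``; each carries its peak |r| voxel with the
    signed r as peak value.
    """
    ids, grid, _, data = stack_to_matrix(zalff_stack)
    x = np.asarray(clinical_var, dtype=float)
    if len(x) != len(ids):
        raise InvalidArgumentError("clinical variable does not align with the stack")
    if len(x) < 4:
        raise InvalidArgumentError("need at least 4 subjects")
    if np.ptp(x) == 0:
        raise DegenerateDataError("clinical variable is constant")
    if not analysis_mask.grid.matches(grid):
        raise InvalidArgumentError("analysis mask grid does not match stack grid")
    analysis_mask.require_nonempty()

    mvox = analysis_mask.data
    Y = data[:, mvox]  # (n, voxels)
    r, p = _pearson_with_p(x, Y)

    r_map = np.full(grid.dims, np.nan)
    p_map = np.full(grid.dims, np.nan)
    r_map[mvox] = r
    p_map[mvox] = p

    with np.errstate(invalid="ignore"):
        binary = p_map < p_threshold
    cs = label_clusters(binary, grid, values=np.nan_to_num(np.abs(r_map), nan=-1.0),
                        connectivity=connectivity)
    kept = []
    for c in cs.clusters:
        if c.size >= min_size:
            c.peak_value = float(r_map[c.peak_index])  # report signed r at peak |r|
            kept.append(c)
    return CorrelationMap(grid=grid, r_map=r_map, p_map=p_map,
                          clusters=ClusterSet(grid=grid, clusters=kept),
                          p_threshold=p_threshold, min_size=min_size)


def mean_roi_series(zalff_stack, roi_mask: Mask) -> np.ndarray:
    """Spatial mean over the ROI, one value per subject (stack order)."""
    ids, grid, _, data = stack_to_matrix(zalff_stack)
    if not roi_mask.grid.matches(grid):
        raise InvalidArgumentError("ROI grid does not match stack grid")
    roi_mask.require_nonempty()
    return data[:, roi_mask.data].mean(axis=1)


def roi_paired_ttest(pre_stack, post_stack, roi_mask: Mask, alpha: float = 0.05,
                     connectivity: int = 26) -> PairedTestResult:
    """Voxelwise paired t-test (pre minus post) with Bonferroni FWE control.

    Voxels whose paired differences have zero variance are excluded from the
    corrected family and counted in the report.
    """
    ids_pre, grid, _, pre = stack_to_matrix(pre_stack)
    ids_post, grid2, _, post = stack_to_matrix(post_stack)
    if not grid.matches(grid2):
        raise InvalidArgumentError("pre and post stacks are on different grids")
    if pre.shape[0] != post.shape[0]:
        raise InvalidArgumentError("pre and post stacks have different subject counts")
    if pre.shape[0] < 3:
        raise InvalidArgumentError("need at least 3 pairs")
    if not roi_mask.grid.matches(grid):
        raise InvalidArgumentError("ROI grid does not match stack grid")
    roi_mask.require_nonempty()

    mvox = roi_mask.data
    diff = pre[:, mvox] - post[:, mvox]  # positive mean = decrease after treatment
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    valid = sd > 0
    t = np.full(mean.shape, np.nan)
    t[valid] = mean[valid] / (sd[valid] / np.sqrt(n))
    p = np.full(mean.shape, np.nan)
    p[valid] = 2.0 * sps.t.sf(np.abs(t[valid]), n - 1)

    n_family = int(valid.sum())
    corrected = alpha / n_family if n_family else np.nan

    t_map = np.full(grid.dims, np.nan)
    p_map = np.full(grid.dims, np.nan)
    t_map[mvox] = t
    p_map[mvox] = p
    with np.errstate(invalid="ignore"):
        sig = p_map < corrected
    clusters = label_clusters(sig, grid, values=np.nan_to_num(np.abs(t_map), nan=-1.0),
                              connectivity=connectivity)
    for c in clusters.clusters:
        c.peak_value = float(t_map[c.peak_index])  # signed t at peak |t|

    return PairedTestResult(
        grid=grid, roi=roi_mask, t_map=t_map, p_map=p_map, alpha=alpha,
        corrected_threshold=corrected, significant=clusters,
        n_excluded=int((~valid).sum()),
        pre_means=pre[:, mvox].mean(axis=1), post_means=post[:, mvox].mean(axis=1))


def change_correlation(pre_stack, post_stack, roi_mask: Mask, improvement):
    """Pearson correlation between ROI-mean zALFF change (pre minus post) and
    symptom improvement.

    Returns ``(r, p, scatter)`` with the per-subject pairs as a DataFrame.
    """
    imp = np.asarray(improvement, dtype=float)
    if len(imp) < 4:
        raise InvalidArgumentError("need at least 4 completers")
    pre_m = mean_roi_series(pre_stack, roi_mask)
    post_m = mean_roi_series(post_stack, roi_mask)
    if len(pre_m) != len(imp) or len(post_m) != len(imp):
        raise InvalidArgumentError("stacks and improvement vector disagree in length")
    change = pre_m - post_m
    if np.ptp(change) == 0 or np.ptp(imp) == 0:
        raise DegenerateDataError("constant change or improvement vector")
    res = sps.pearsonr(change, imp)
    scatter = pd.DataFrame({"zalff_change": change, "improvement": imp})
    return float(res.statistic), float(res.pvalue), scatter
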