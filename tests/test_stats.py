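"""Correlation maps, longitudinal ROI tests and change-improvement coupling."""

import numpy as np
import pytest
from scipy import stats as sps

from alffmvpa.alff import ZAlffMap
from alffmvpa.exceptions import DegenerateDataError, InvalidArgumentError
from alffmvpa.spatial import Mask, VolumeGrid
from alffmvpa.stats import (
    change_correlation,
    mean_roi_series,
    roi_paired_ttest,
    voxelwise_correlation,
)

from conftest import full_mask


def make_stack(data, grid, mask=None):
    mask = mask or full_mask(grid)
    return {f"s{i}": ZAlffMap(grid=grid, mask=mask, data=data[i])
            for i in range(len(data))}


GRID = VolumeGrid.isotropic((6, 6, 6), 3.0)


class TestVoxelwiseCorrelation:
    def test_variable_equal_to_voxel_gives_unit_correlation(self, rng):
        data = rng.normal(size=(10, 6, 6, 6))
        stack = make_stack(data, GRID)
        var = data[:, 3, 3, 3]
        cm = voxelwise_correlation(stack, var, full_mask(GRID), min_size=1)
        assert cm.r_map[3, 3, 3] == pytest.approx(1.0)
        assert cm.p_map[3, 3, 3] < 1e-10

    def test_five_pair_closed_form(self, rng):
        # pairs (1,2),(2,1),(3,4),(4,3),(5,6): cov = 2, var_x = 2,
        # var_y = 2.96, so r = 2 / sqrt(2 * 2.96)
        x = np.array([1.0, 2, 3, 4, 5])
        yv = np.array([2.0, 1, 4, 3, 6])
        data = np.zeros((5, 6, 6, 6))
        data[:, 0, 0, 0] = yv
        data[:, 1:, :, :] = rng.normal(size=(5, 5, 6, 6))
        cm = voxelwise_correlation(make_stack(data, GRID), x, full_mask(GRID),
                                   min_size=1)
        assert cm.r_map[0, 0, 0] == pytest.approx(2 / np.sqrt(2 * 2.96))
        r_oracle = sps.pearsonr(x, yv)
        assert cm.r_map[0, 0, 0] == pytest.approx(r_oracle.statistic)
        assert cm.p_map[0, 0, 0] == pytest.approx(r_oracle.pvalue)

    def test_null_suprathreshold_fraction_near_alpha(self, rng):
        hits, total = 0, 0
        for _ in range(10):
            data = rng.normal(size=(20, 6, 6, 6))
            var = rng.normal(size=20)
            cm = voxelwise_correlation(make_stack(data, GRID), var,
                                       full_mask(GRID), min_size=1)
            hits += int((cm.p_map < 0.05).sum())
            total += 216
        assert hits / total == pytest.approx(0.05, abs=0.02)

    def test_cluster_rule_is_inclusive_at_min_size(self, rng):
        # 20-voxel clusters are retained (>= rule, unlike the classifier's
        # strict > rule)
        data = rng.normal(0, 0.01, size=(12, 6, 6, 6))
        var = rng.normal(size=12)
        data[:, 0:5, 0:2, 0:2] += np.outer(var, np.ones(20)).reshape(12, 5, 2, 2)
        cm = voxelwise_correlation(make_stack(data, GRID), var, full_mask(GRID),
                                   min_size=20)
        assert any(c.size >= 20 for c in cm.clusters)

    def test_constant_variable_rejected(self, rng):
        data = rng.normal(size=(8, 6, 6, 6))
        with pytest.raises(DegenerateDataError):
            voxelwise_correlation(make_stack(data, GRID), np.ones(8),
                                  full_mask(GRID))


class TestMeanRoiSeries:
    def test_single_voxel_roi(self, rng):
        data = rng.normal(size=(7, 6, 6, 6))
        m = np.zeros((6, 6, 6), bool)
        m[2, 4, 1] = True
        out = mean_roi_series(make_stack(data, GRID), Mask(GRID, m))
        assert np.allclose(out, data[:, 2, 4, 1])

    def test_uniform_map_returns_its_value(self):
        data = np.full((3, 6, 6, 6), 2.5)
        out = mean_roi_series(make_stack(data, GRID), full_mask(GRID))
        assert np.allclose(out, 2.5)

    def test_equals_direct_average(self, rng):
        data = rng.normal(size=(5, 6, 6, 6))
        m = rng.random((6, 6, 6)) < 0.3
        out = mean_roi_series(make_stack(data, GRID), Mask(GRID, m))
        assert np.allclose(out, data[:, m].mean(axis=1))

    def test_empty_roi_rejected(self, rng):
        data = rng.normal(size=(5, 6, 6, 6))
        with pytest.raises(InvalidArgumentError):
            mean_roi_series(make_stack(data, GRID),
                            Mask(GRID, np.zeros((6, 6, 6), bool)))


class TestRoiPairedTtest:
    def test_closed_form_t_on_known_differences(self, rng):
        # differences {0.3,0.1,0.4,0.2,0.5}: t = mean/(sd/sqrt(5)) = 4.243
        diffs = np.array([0.3, 0.1, 0.4, 0.2, 0.5])
        post = rng.normal(size=(5, 6, 6, 6))
        pre = post.copy()
        pre[:, 2, 2, 2] = post[:, 2, 2, 2] + diffs
        roi = np.zeros((6, 6, 6), bool)
        roi[2, 2, 2] = True
        roi[3, 3, 3] = True
        res = roi_paired_ttest(make_stack(pre, GRID), make_stack(post, GRID),
                               Mask(GRID, roi))
        assert res.t_map[2, 2, 2] == pytest.approx(4.2426, abs=1e-3)

    def test_strong_uniform_decrease_all_significant(self, rng):
        pre = rng.normal(size=(20, 6, 6, 6))
        post = pre - 1.0 + rng.normal(0, 0.1, size=pre.shape)  # zALFF drops
        roi = np.zeros((6, 6, 6), bool)
        roi[1:4, 1:4, 1:4] = True
        res = roi_paired_ttest(make_stack(pre, GRID), make_stack(post, GRID),
                               Mask(GRID, roi))
        assert res.n_significant == roi.sum()
        assert np.all(res.t_map[roi] > 0)  # positive t = decrease

    def test_bonferroni_controls_family_wise_error(self):
        # null replicates (post = pre + symmetric noise): the probability of
        # *any* significant voxel in the ROI stays at or below alpha = 0.05,
        # checked over 200 replicates against a binomial bound
        r = np.random.default_rng(909)
        roi = np.zeros((6, 6, 6), bool)
        roi[2:5, 2:5, 2:5] = True
        fwe_hits = 0
        for _ in range(200):
            pre = r.normal(size=(15, 6, 6, 6))
            post = pre + r.normal(0, 1e-3, size=pre.shape)
            res = roi_paired_ttest(make_stack(pre, GRID), make_stack(post, GRID),
                                   Mask(GRID, roi))
            fwe_hits += res.n_significant > 0
        # Binomial(200, 0.05): P(X > 19) < 1e-3
        assert fwe_hits <= 19

    def test_bonferroni_rejections_subset_of_uncorrected(self, rng):
        pre = rng.normal(size=(10, 6, 6, 6))
        post = pre - rng.normal(0, 0.5, size=pre.shape)
        roi = np.zeros((6, 6, 6), bool)
        roi[1:5, 1:5, 1:5] = True
        res = roi_paired_ttest(make_stack(pre, GRID), make_stack(post, GRID),
                               Mask(GRID, roi))
        corrected = res.significant.union_mask().data
        uncorrected = np.zeros_like(corrected)
        with np.errstate(invalid="ignore"):
            uncorrected[roi] = res.p_map[roi] < res.alpha
        assert np.all(uncorrected[corrected])

    def test_zero_variance_voxels_flagged_and_excluded(self, rng):
        pre = rng.normal(size=(8, 6, 6, 6))
        post = pre.copy()
        post[:, 2, 2, 2] = pre[:, 2, 2, 2] - 1.0 - rng.normal(0, 0.1, size=8)
        roi = np.zeros((6, 6, 6), bool)
        roi[2, 2, :] = True
        res = roi_paired_ttest(make_stack(pre, GRID), make_stack(post, GRID),
                               Mask(GRID, roi))
        assert res.n_excluded == 5  # the five zero-difference voxels
        assert np.isnan(res.t_map[2, 2, 3])

    def test_matches_scipy_paired_ttest(self, rng):
        pre = rng.normal(size=(12, 6, 6, 6))
        post = pre - rng.normal(0, 1.0, size=pre.shape)
        roi = np.zeros((6, 6, 6), bool)
        roi[3, 3, 3] = True
        roi[1, 1, 1] = True
        res = roi_paired_ttest(make_stack(pre, GRID), make_stack(post, GRID),
                               Mask(GRID, roi))
        ref = sps.ttest_rel(pre[:, 3, 3, 3], post[:, 3, 3, 3])
        assert res.t_map[3, 3, 3] == pytest.approx(ref.statistic)
        assert res.p_map[3, 3, 3] == pytest.approx(ref.pvalue)


class TestChangeCorrelation:
    def test_improvement_equal_to_change_gives_unit_r(self, rng):
        pre = rng.normal(size=(10, 6, 6, 6))
        post = pre.copy()
        roi = np.zeros((6, 6, 6), bool)
        roi[2:4, 2:4, 2:4] = True
        shifts = rng.normal(size=10)
        for i in range(10):
            post[i][roi] -= shifts[i]
        r, p, scatter = change_correlation(make_stack(pre, GRID),
                                           make_stack(post, GRID),
                                           Mask(GRID, roi), shifts)
        assert r == pytest.approx(1.0)
        assert len(scatter) == 10

    def test_matches_scipy_pearson(self, rng):
        pre = rng.normal(size=(9, 6, 6, 6))
        post = rng.normal(size=(9, 6, 6, 6))
        roi = np.zeros((6, 6, 6), bool)
        roi[1:3, 1:3, 1:3] = True
        imp = rng.normal(size=9)
        r, p, _ = change_correlation(make_stack(pre, GRID),
                                     make_stack(post, GRID), Mask(GRID, roi), imp)
        change = pre[:, roi].mean(1) - post[:, roi].mean(1)
        ref = sps.pearsonr(change, imp)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_constant_improvement_rejected(self, rng):
        pre = rng.normal(size=(6, 6, 6, 6))
        post = rng.normal(size=(6, 6, 6, 6))
        roi = np.zeros((6, 6, 6), bool)
        roi[2, 2, 2] = True
        with pytest.raises(DegenerateDataError):
            change_correlation(make_stack(pre, GRID), make_stack(post, GRID),
                               Mask(GRID, roi), np.ones(6))
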