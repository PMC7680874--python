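"""Motion QC, detrending, smoothing, spectral amplitude and z-standardization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alffmvpa.alff import (
    FWHM_TO_SIGMA,
    MotionParams,
    compute_alff,
    detrend_and_regress,
    discard_initial_volumes,
    extract_nuisance_signals,
    framewise_displacement,
    gaussian_smooth,
    motion_qc,
    subject_zalff,
    z_transform,
)
from alffmvpa.exceptions import DegenerateDataError, InvalidArgumentError, VolumeFormatError
from alffmvpa.spatial import Bold4D, Mask, VolumeGrid

from conftest import full_mask


def make_bold(data, tr=2.0, voxel=3.0):
    grid = VolumeGrid.isotropic(data.shape[:3], voxel)
    return Bold4D(grid=grid, data=data, tr=tr)


def dft_amplitude_oracle(series, tr, band):
    """Brute-force discrete Fourier amplitude, independent of the FFT path."""
    n = len(series)
    freqs = np.arange(n // 2 + 1) / (n * tr)
    amps = []
    for k, f in enumerate(freqs):
        if k == 0 or not (band[0] - 1e-12 <= f <= band[1] + 1e-12):
            continue
        re = sum(series[t] * np.cos(-2 * np.pi * k * t / n) for t in range(n))
        im = sum(series[t] * np.sin(-2 * np.pi * k * t / n) for t in range(n))
        amps.append(2.0 * np.hypot(re, im) / n)
    return np.mean(amps)


class TestFramewiseDisplacement:
    def test_constant_parameters_give_zero(self):
        fd = framewise_displacement(MotionParams(np.ones((20, 6))))
        assert np.all(fd == 0)

    def test_translation_steps_sum_absolutely(self):
        v = np.zeros((3, 6))
        v[1, :3] = 0.1  # each translation changes by 0.1 mm
        fd = framewise_displacement(MotionParams(v))
        assert fd[0] == 0.0
        assert fd[1] == pytest.approx(0.3)

    def test_rotation_converts_to_arc_length(self):
        v = np.zeros((2, 6))
        v[1, 3] = 0.01  # rad, radius 50 mm
        fd = framewise_displacement(MotionParams(v))
        assert fd[1] == pytest.approx(0.5)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(VolumeFormatError):
            MotionParams(np.zeros((10, 5)))


class TestMotionQC:
    def test_zero_motion_passes(self):
        assert motion_qc(MotionParams(np.zeros((20, 6)))).passed

    def test_mean_fd_above_half_millimetre_fails(self):
        v = np.zeros((20, 6))
        v[1::2, 0] = 0.65  # alternating 0.65-mm jumps -> mean FD > 0.5
        qc = motion_qc(MotionParams(v))
        assert not qc.passed
        assert any("FD" in r for r in qc.reasons)
        assert qc.mean_fd > 0.5

    def test_translation_beyond_one_voxel_fails(self):
        v = np.zeros((20, 6))
        v[10, 1] = 3.5  # 3-mm voxels
        qc = motion_qc(MotionParams(v), displacement_limit=3.0)
        assert not qc.passed
        assert any("displacement" in r for r in qc.reasons)


class TestFriston24:
    def test_expansion_layout(self, rng):
        from alffmvpa.alff import friston24_expansion

        v = rng.normal(size=(30, 6))
        out = friston24_expansion(MotionParams(v))
        assert out.shape == (30, 24)
        assert np.allclose(out[:, :6], v)          # raw parameters
        assert np.allclose(out[0, 6:12], 0.0)      # lag starts at zero
        assert np.allclose(out[1:, 6:12], v[:-1])  # one-lag shift
        assert np.allclose(out[:, 12:18], v**2)    # squares


class TestDiscardInitialVolumes:
    def test_180_minus_10_gives_170(self, rng):
        bold = make_bold(rng.normal(size=(2, 2, 2, 180)))
        out = discard_initial_volumes(bold, 10)
        assert out.n_timepoints == 170
        assert np.array_equal(out.data, bold.data[..., 10:])

    def test_zero_is_identity(self, rng):
        bold = make_bold(rng.normal(size=(2, 2, 2, 30)))
        assert np.array_equal(discard_initial_volumes(bold, 0).data, bold.data)

    def test_discarding_everything_rejected(self, rng):
        bold = make_bold(rng.normal(size=(2, 2, 2, 30)))
        with pytest.raises(InvalidArgumentError):
            discard_initial_volumes(bold, 30)


class TestDetrendAndRegress:
    def test_pure_ramp_reduces_to_zero(self):
        t = np.linspace(0, 5, 40)
        data = np.tile(t, (2, 2, 2, 1))
        out = detrend_and_regress(make_bold(data))
        assert np.abs(out.data).max() < 1e-10

    def test_nuisance_identical_to_voxel_series_removes_it(self, rng):
        s = rng.normal(size=50)
        data = np.tile(s, (2, 2, 2, 1))
        out = detrend_and_regress(make_bold(data), nuisance=s)
        assert np.abs(out.data).max() < 1e-10

    def test_signal_orthogonal_to_design_is_preserved(self, rng):
        # an independent OLS oracle on a 20-point series
        t = 20
        nuis = rng.normal(size=t)
        X = np.column_stack([np.ones(t), np.linspace(-1, 1, t), nuis])
        raw = rng.normal(size=t)
        beta = np.linalg.lstsq(X, raw, rcond=None)[0]
        orth = raw - X @ beta  # residual: orthogonal to the design
        data = np.tile(orth, (1, 1, 1, 1))
        out = detrend_and_regress(make_bold(data), nuisance=nuis)
        assert np.allclose(out.data[0, 0, 0], orth, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        data = rng.normal(size=(3, 3, 3, 40))
        nuis = rng.normal(size=(40, 2))
        out = detrend_and_regress(make_bold(data), nuisance=nuis)
        Y = out.data.reshape(-1, 40)
        X = np.column_stack([np.ones(40), np.linspace(-1, 1, 40), nuis])
        assert np.abs(X.T @ Y.T).max() < 1e-8

    def test_rank_deficient_design_warns(self, rng):
        data = rng.normal(size=(2, 2, 2, 30))
        dup = np.linspace(-1, 1, 30)  # duplicates the ramp column
        with pytest.warns(RuntimeWarning):
            detrend_and_regress(make_bold(data), nuisance=dup)


class TestNuisanceExtraction:
    def test_single_voxel_mask_returns_its_series(self, rng):
        data = rng.normal(size=(3, 3, 3, 25))
        bold = make_bold(data)
        m = np.zeros((3, 3, 3), bool)
        m[1, 2, 0] = True
        cols = extract_nuisance_signals(bold, Mask(bold.grid, m))
        assert np.allclose(cols[:, 0], data[1, 2, 0])

    def test_opposite_series_cancel(self, rng):
        s = rng.normal(size=25)
        data = np.zeros((2, 1, 1, 25))
        data[0, 0, 0] = s
        data[1, 0, 0] = -s
        bold = make_bold(data)
        cols = extract_nuisance_signals(bold, full_mask(bold.grid))
        assert np.abs(cols).max() < 1e-12

    def test_equals_direct_averaging(self, rng):
        data = rng.normal(size=(4, 4, 4, 25))
        bold = make_bold(data)
        m = rng.random((4, 4, 4)) < 0.4
        cols = extract_nuisance_signals(bold, Mask(bold.grid, m))
        assert np.allclose(cols[:, 0], data[m].mean(axis=0))

    def test_empty_mask_rejected(self, rng):
        bold = make_bold(rng.normal(size=(2, 2, 2, 25)))
        with pytest.raises(InvalidArgumentError):
            extract_nuisance_signals(bold, Mask(bold.grid, np.zeros((2, 2, 2), bool)))


class TestGaussianSmooth:
    def test_constant_volume_invariant(self):
        grid = VolumeGrid.isotropic((8, 8, 8), 3.0)
        data = np.full((8, 8, 8), 3.7)
        assert np.allclose(gaussian_smooth(data, grid, 6.0), data)

    def test_zero_fwhm_is_identity(self, rng):
        grid = VolumeGrid.isotropic((6, 6, 6), 3.0)
        data = rng.normal(size=(6, 6, 6))
        assert np.array_equal(gaussian_smooth(data, grid, 0.0), data)

    def test_impulse_peak_matches_analytic_kernel(self):
        # fine 1-mm grid so the discrete kernel approximates the continuous one
        grid = VolumeGrid.isotropic((41, 41, 41), 1.0)
        data = np.zeros(grid.dims)
        data[20, 20, 20] = 1.0
        sm = gaussian_smooth(data, grid, 6.0)
        sigma = 6.0 * FWHM_TO_SIGMA
        analytic = (2 * np.pi * sigma**2) ** -1.5
        assert sm[20, 20, 20] == pytest.approx(analytic, rel=0.02)

    def test_negative_fwhm_rejected(self):
        grid = VolumeGrid.isotropic((4, 4, 4), 3.0)
        with pytest.raises(InvalidArgumentError):
            gaussian_smooth(np.zeros((4, 4, 4)), grid, -1.0)


class TestComputeAlff:
    def test_constant_series_has_zero_amplitude(self):
        bold = make_bold(np.full((2, 2, 2, 64), 5.0))
        assert np.abs(compute_alff(bold)).max() == 0.0

    def test_sinusoid_amplitude_scales_linearly(self):
        t = np.arange(170) * 2.0
        a = np.sin(2 * np.pi * 0.05 * t)
        data = np.stack([a, 2 * a]).reshape(2, 1, 1, 170)
        alff = compute_alff(make_bold(data))
        assert alff[1, 0, 0] / alff[0, 0, 0] == pytest.approx(2.0, rel=0.01)

    def test_out_of_band_sinusoid_leaks_below_one_percent(self):
        t = np.arange(170) * 2.0
        inband = np.sin(2 * np.pi * 0.05 * t)
        outband = np.sin(2 * np.pi * 0.2 * t)
        data = np.stack([inband, outband]).reshape(2, 1, 1, 170)
        alff = compute_alff(make_bold(data))
        assert alff[1, 0, 0] <= 0.01 * alff[0, 0, 0]

    def test_matches_brute_force_dft_oracle(self, rng):
        for _ in range(10):
            s = rng.normal(size=64)
            bold = make_bold(s.reshape(1, 1, 1, 64))
            mine = compute_alff(bold)[0, 0, 0]
            oracle = dft_amplitude_oracle(s, 2.0, (0.01, 0.08))
            assert mine == pytest.approx(oracle, rel=1e-8)

    def test_too_coarse_frequency_resolution_rejected(self):
        bold = make_bold(np.zeros((1, 1, 1, 20)), tr=2.0)
        with pytest.raises(InvalidArgumentError, match="resolution"):
            compute_alff(bold, band=(0.01, 0.02))


class TestZTransform:
    def test_three_values_standardize_with_population_sd(self):
        grid = VolumeGrid.isotropic((3, 1, 1), 3.0)
        mask = full_mask(grid)
        zm = z_transform(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1), mask)
        assert np.allclose(zm.in_mask_values, [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_output_is_standardized_within_tolerance(self, seed):
        grid = VolumeGrid.isotropic((6, 6, 6), 3.0)
        r = np.random.default_rng(seed)
        mask = Mask(grid, r.random(grid.dims) < 0.7)
        if mask.n_voxels < 2:
            return
        vals = r.normal(2.0, 3.0, size=grid.dims)
        zm = z_transform(vals, mask)
        assert abs(zm.in_mask_values.mean()) < 1e-6
        assert abs(zm.in_mask_values.std() - 1.0) < 1e-6
        assert np.isnan(zm.data[~mask.data]).all()

    def test_constant_map_rejected(self):
        grid = VolumeGrid.isotropic((3, 3, 3), 3.0)
        with pytest.raises(DegenerateDataError):
            z_transform(np.ones((3, 3, 3)), full_mask(grid))


class TestEndToEnd:
    def test_larger_inband_amplitude_gives_larger_zalff(self, rng):
        # voxels with larger generated in-band amplitude must rank higher
        from alffmvpa.simulate import generate_band_limited_series

        grid = VolumeGrid.isotropic((4, 4, 4), 3.0)
        targets = rng.uniform(0.5, 3.0, size=grid.dims)
        data = np.empty(grid.dims + (180,))
        for idx in np.ndindex(grid.dims):
            data[idx] = generate_band_limited_series(
                targets[idx], (0.01, 0.08), 2.0, 180, seed=rng)
        data += rng.normal(0, 0.1, size=data.shape)
        bold = Bold4D(grid=grid, data=data, tr=2.0)
        zm = subject_zalff(bold, full_mask(grid), fwhm=0.0)
        from scipy.stats import spearmanr

        rho = spearmanr(targets.ravel(), zm.data.ravel()).statistic
        assert rho > 0.9

    def test_smoothing_order_matters(self, rng):
        # the pipeline smooths before the spectral step; doing it after
        # gives a different map (regression guard on the stage order)
        grid = VolumeGrid.isotropic((6, 6, 6), 3.0)
        data = rng.normal(size=(6, 6, 6, 64))
        bold = Bold4D(grid=grid, data=data, tr=2.0)
        smooth_first = compute_alff(
            Bold4D(grid=grid, data=gaussian_smooth(data, grid, 6.0), tr=2.0))
        smooth_after = gaussian_smooth(compute_alff(bold), grid, 6.0)
        assert not np.allclose(smooth_first, smooth_after, atol=1e-3)
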