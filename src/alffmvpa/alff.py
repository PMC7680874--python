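"""From preprocessed BOLD to the standardized low-frequency amplitude map.

Implements the subject-level spectral pipeline: motion quality control on
rigid-body parameters, initial-volume discard, linear detrend + nuisance
regression, spatial Gaussian smoothing, amplitude of low-frequency
fluctuation (ALFF) over 0.01–0.08 Hz, and within-mask z-standardization
(zALFF).

ALFF here is the *mean* single-sided spectral amplitude over the in-band
frequency bins of the raw periodogram (no taper), with the DC bin always
excluded.  The mean (rather than the sum) makes the value invariant to
series length; only relative values matter downstream because of the
z-transform.  Temporal band-pass filtering and the band-amplitude summary
are one spectral operation here, not two passes.

Framewise displacement follows the Power convention: the sum of absolute
backward differences of the six rigid-body parameters, rotations converted
to arc length on a 50-mm sphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import DegenerateDataError, InvalidArgumentError, VolumeFormatError
from .spatial import Bold4D, Mask, VolumeGrid

__all__ = [
    "MotionParams",
    "QCResult",
    "ZAlffMap",
    "framewise_displacement",
    "motion_qc",
    "discard_initial_volumes",
    "friston24_expansion",
    "extract_nuisance_signals",
    "detrend_and_regress",
    "gaussian_smooth",
    "compute_alff",
    "z_transform",
    "subject_zalff",
    "FWHM_TO_SIGMA",
]

#: FWHM -> Gaussian sigma conversion: sigma = FWHM / sqrt(8 ln 2)
FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))

DEFAULT_BAND = (0.01, 0.08)


@dataclass
class MotionParams:
    """Per-timepoint rigid-body parameters: 3 translations (mm), 3 rotations (rad)."""

    values: np.ndarray  # (t, 6)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 6:
            raise VolumeFormatError(
                f"motion parameters must have 6 columns, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise VolumeFormatError("motion parameters contain non-finite values")
        self.values = v

    @classmethod
    def from_file(cls, path) -> "MotionParams":
        """Read whitespace-delimited rp_*.txt-style motion parameters."""
        return cls(np.loadtxt(str(path), ndmin=2))

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


@dataclass
class QCResult:
    """Outcome of the motion screen with the rules that fired."""

    passed: bool
    mean_fd: float
    max_fd: float
    max_displacement: float
    reasons: list[str] = field(default_factory=list)


def framewise_displacement(motion: MotionParams, head_radius: float = 50.0) -> np.ndarray:
    """Power-style framewise displacement in mm, first frame 0.

    FD(t) = sum |d translation| + head_radius * sum |d rotation|.
    """
    v = motion.values
    if v.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 timepoints for framewise displacement")
    d = np.abs(np.diff(v, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def motion_qc(motion: MotionParams, fd_limit: float = 0.5,
              displacement_limit: float = 3.0, head_radius: float = 50.0) -> QCResult:
    """Subject-exclusion screen on head motion.

    Fails if mean framewise displacement exceeds ``fd_limit`` (default
    0.5 mm) or if the maximum absolute translation on any axis exceeds
    ``displacement_limit`` (default: one 3-mm voxel).
    """
    fd = framewise_displacement(motion, head_radius=head_radius)
    max_disp = float(np.abs(motion.values[:, :3]).max())
    reasons = []
    if fd.mean() > fd_limit:
        reasons.append(f"mean FD {fd.mean():.3f} mm > {fd_limit} mm")
    if max_disp > displacement_limit:
        reasons.append(f"max displacement {max_disp:.3f} mm > {displacement_limit} mm")
    return QCResult(
        passed=not reasons,
        mean_fd=float(fd.mean()),
        max_fd=float(fd.max()),
        max_displacement=max_disp,
        reasons=reasons,
    )


def discard_initial_volumes(bold: Bold4D, n: int = 10) -> Bold4D:
    """Drop the first ``n`` timepoints (scanner equilibration)."""
    if n < 0:
        raise InvalidArgumentError("n must be >= 0")
    if n >= bold.n_timepoints:
        raise InvalidArgumentError(
            f"cannot discard {n} of {bold.n_timepoints} volumes")
    return Bold4D(grid=bold.grid, data=bold.data[..., n:], tr=bold.tr)


def friston24_expansion(motion: MotionParams) -> np.ndarray:
    """24-regressor motion model: params, one-lag shifts, and their squares."""
    v = motion.values
    lag = np.vstack([np.zeros((1, 6)), v[:-1]])
    block = np.hstack([v, lag])
    return np.hstack([block, block**2])


def extract_nuisance_signals(bold: Bold4D, *masks: Mask) -> np.ndarray:
    """Per-timepoint spatial mean over each mask (e.g. WM, CSF), one column each."""
    cols = []
    for m in masks:
        if not m.grid.matches(bold.grid):
            raise InvalidArgumentError("nuisance mask grid does not match BOLD grid")
        m.require_nonempty()
        cols.append(bold.data[m.data].mean(axis=0))
    if not cols:
        raise InvalidArgumentError("at least one nuisance mask required")
    return np.column_stack(cols)


def detrend_and_regress(bold: Bold4D, nuisance: np.ndarray | None = None) -> Bold4D:
    """Per-voxel OLS residual after intercept + linear ramp + nuisance columns."""
    t = bold.n_timepoints
    design = [np.ones(t), np.linspace(-1.0, 1.0, t)]
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.ndim == 1:
            nuisance = nuisance[:, None]
        if nuisance.shape[0] != t:
            raise InvalidArgumentError(
                f"nuisance rows ({nuisance.shape[0]}) != timepoints ({t})")
        design.append(nuisance)
    X = np.column_stack(design)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient nuisance design; using pseudo-inverse",
                      RuntimeWarning, stacklevel=2)
    Y = bold.data.reshape(-1, t).T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return Bold4D(grid=bold.grid, data=resid.T.reshape(bold.data.shape), tr=bold.tr)


def gaussian_smooth(data: np.ndarray, grid: VolumeGrid, fwhm: float = 6.0) -> np.ndarray:
    """Separable spatial Gaussian smoothing with FWHM in mm.

    Applies to a 3D map or each timepoint of a 4D series; constant volumes
    are invariant and fwhm=0 is the identity.
    """
    if fwhm < 0:
        raise InvalidArgumentError("fwhm must be >= 0")
    data = np.asarray(data, dtype=float)
    if data.shape[:3] != grid.dims:
        raise InvalidArgumentError("data shape does not match grid")
    if fwhm == 0:
        return data.copy()
    sigma_vox = [fwhm * FWHM_TO_SIGMA / vs for vs in grid.voxel_size]
    if data.ndim == 3:
        return ndimage.gaussian_filter(data, sigma=sigma_vox, mode="nearest")
    if data.ndim != 4:
        raise InvalidArgumentError("expected 3D or 4D data")
    return ndimage.gaussian_filter(data, sigma=sigma_vox + [0.0], mode="nearest")


def _band_bins(n: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=tr)
    lo, hi = band
    if not (0 <= lo < hi):
        raise InvalidArgumentError(f"invalid band {band}")
    nyquist = 1.0 / (2.0 * tr)
    if hi > nyquist + 1e-12:
        raise InvalidArgumentError(
            f"band {band} exceeds the Nyquist frequency {nyquist:.4f} Hz at TR={tr} s")
    sel = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    sel[0] = False  # DC always excluded
    return np.flatnonzero(sel)


def compute_alff(bold: Bold4D, band: tuple[float, float] = DEFAULT_BAND) -> np.ndarray:
    """Mean in-band single-sided spectral amplitude per voxel.

    The amplitude at bin k is ``2 |X_k| / n`` (the amplitude of the
    corresponding sinusoid), averaged over bins with band_low <= f <=
    band_high, DC excluded. Requires at least 2 bins inside the band.
    """
    n = bold.n_timepoints
    bins = _band_bins(n, bold.tr, band)
    if len(bins) < 2:
        df = 1.0 / (n * bold.tr)
        raise InvalidArgumentError(
            f"fewer than 2 frequency bins inside {band} Hz; frequency resolution "
            f"is {df:.5f} Hz with {n} timepoints at TR={bold.tr} s")
    spec = np.fft.rfft(bold.data, axis=-1)
    amp = 2.0 * np.abs(spec[..., bins]) / n
    return amp.mean(axis=-1)


@dataclass
class ZAlffMap:
    """Within-mask standardized ALFF map (mean 0, SD 1 over the mask)."""

    grid: VolumeGrid
    mask: Mask
    data: np.ndarray  # NaN outside mask

    @property
    def in_mask_values(self) -> np.ndarray:
        return self.data[self.mask.data]


def z_transform(alff: np.ndarray, mask: Mask) -> ZAlffMap:
    """Standardize an ALFF map over the mask: (value - mean) / population SD."""
    alff = np.asarray(alff, dtype=float)
    if alff.shape != mask.grid.dims:
        raise InvalidArgumentError("ALFF map shape does not match mask grid")
    mask.require_nonempty()
    if mask.n_voxels < 2:
        raise InvalidArgumentError("need at least 2 in-mask voxels")
    vals = alff[mask.data]
    sd = vals.std()  # population (1/N) SD
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateDataError("in-mask ALFF is constant; z-transform undefined")
    out = np.full(mask.grid.dims, np.nan)
    out[mask.data] = (vals - vals.mean()) / sd
    return ZAlffMap(grid=mask.grid, mask=mask, data=out)


def subject_zalff(bold: Bold4D, mask: Mask,
                  nuisance: np.ndarray | None = None,
                  n_discard: int = 10,
                  fwhm: float = 6.0,
                  band: tuple[float, float] = DEFAULT_BAND) -> ZAlffMap:
    """Full subject-level chain: discard, detrend/regress, smooth, ALFF, z-transform."""
    if n_discard:
        bold = discard_initial_volumes(bold, n_discard)
        if nuisance is not None:
            nuisance = np.asarray(nuisance)[n_discard:]
    bold = detrend_and_regress(bold, nuisance)
    smoothed = Bold4D(grid=bold.grid, data=gaussian_smooth(bold.data, bold.grid, fwhm),
                      tr=bold.tr)
    alff = compute_alff(smoothed, band)
    return z_transform(alff, mask)
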