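"""Synthetic two-group cohort with planted, recoverable structure.

Generates a patient/control cohort whose standardized amplitude (zALFF)
maps carry localized group differences, and whose post-treatment symptom
change couples linearly to the mean zALFF of a planted region — the two
assumptions the classification and prediction stages are built to detect.
Every cohort carries a truth record (planted masks, effect sizes, slopes)
so downstream estimates can be checked against ground truth.

Two generation modes share identical truth records:

``zalff``
    draws each subject's zALFF map directly (spatially smooth Gaussian
    background, standardized over the mask, plus the planted group shift).
``bold``
    synthesizes full 4D BOLD series whose in-band spectral amplitude
    encodes the same maps, exercising the whole spectral pipeline.

Defaults mirror the emulated study design: 40 patients + 40 controls with
33 patients completing follow-up, TR 2 s, 180 volumes, 3-mm voxels, a
~3,000-voxel desk-scale mask, background smoothness matching the 6-mm
smoothing kernel, and baseline clinical covariates drawn from the reported
cohort means and SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alff as alff_mod
from .exceptions import InvalidArgumentError
from .spatial import Bold4D, Mask, VolumeGrid, sphere_offsets, write_volume

__all__ = [
    "EffectCluster",
    "CohortConfig",
    "SubjectRecord",
    "CohortTruth",
    "Cohort",
    "default_grid",
    "default_mask",
    "generate_band_limited_series",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

# Baseline clinical distributions (mean, SD) of the emulated cohort.
_VAS_BASE = (5.49, 1.14)
_MMD_BASE = (6.63, 6.24)
_DURATION = (53.75, 28.45)
_SYMPTOM_P = {"photophobia": 19 / 40, "phonophobia": 23 / 40,
              "nausea": 20 / 40, "vomiting": 7 / 40}
# Mean observed improvements (baseline minus post-treatment).
_VAS_IMPROVE_MEAN = 5.49 - 3.80
_MMD_IMPROVE_MEAN = 6.63 - 5.18


@dataclass(frozen=True)
class EffectCluster:
    """A planted spherical effect region.

    ``group_effect_d`` shifts patients' zALFF inside the sphere by d
    standardized units relative to controls (on average over the sphere:
    the shift profile is the sphere indicator convolved with the spatial
    smoothing kernel, rescaled so its mean inside the sphere equals d —
    mirroring how a focal amplitude effect looks after the smoothing step
    of a real pipeline). ``outcome_beta`` is the slope linking the region's
    mean zALFF to the named outcome's improvement.
    """

    center_index: tuple[int, int, int]
    radius_mm: float = 12.0
    group_effect_d: float = 2.5
    outcome_beta: float = 0.0
    outcome: str | None = None  # "vas" | "mmd" | None


def default_grid() -> VolumeGrid:
    """Desk-scale 20 x 24 x 20 grid at 3-mm isotropic voxels."""
    return VolumeGrid.isotropic((20, 24, 20), 3.0)


def default_mask(grid: VolumeGrid | None = None) -> Mask:
    """Ellipsoidal gray-matter-like mask (~3,000 voxels on the default grid)."""
    grid = grid or default_grid()
    semi = [(d - 3) / 2.0 for d in grid.dims]
    center = [(d - 1) / 2.0 for d in grid.dims]
    idx = np.indices(grid.dims, dtype=float)
    r2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return Mask(grid, r2 <= 1.0)


def _default_effect_clusters() -> list[EffectCluster]:
    return [
        EffectCluster(center_index=(13, 8, 10), radius_mm=12.0, group_effect_d=2.5,
                      outcome_beta=2.0, outcome="vas"),
        EffectCluster(center_index=(6, 16, 9), radius_mm=12.0, group_effect_d=2.5,
                      outcome_beta=1.5, outcome="mmd"),
    ]


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort."""

    n_patients: int = 40
    n_controls: int = 40
    n_completers: int = 33
    grid: VolumeGrid = field(default_factory=default_grid)
    mask: Mask | None = None
    tr: float = 2.0
    n_timepoints: int = 180
    effect_clusters: list[EffectCluster] = field(default_factory=_default_effect_clusters)
    noise_sd: float = 1.0          # background map noise scale (pre-standardization)
    background_fwhm: float = 6.0   # mm; spatial smoothness of the background
    outcome_noise_sd: float = 0.5  # SD of the improvement noise term
    motion_sd: float = 0.01        # random-walk step SD of translations (mm)
    dropout: str = "random"        # "random" | "tail"
    mode: str = "zalff"            # "zalff" | "bold"
    treatment_scale: float = 0.3   # zALFF decrease per unit improvement (post maps)
    retest_noise_sd: float = 0.3   # per-voxel session-to-session noise of post maps
    seed: int = 0

    def __post_init__(self):
        if min(self.n_patients, self.n_controls) < 1:
            raise InvalidArgumentError("group sizes must be positive")
        if not (0 < self.n_completers <= self.n_patients):
            raise InvalidArgumentError("n_completers must be in (0, n_patients]")
        if self.mode not in ("zalff", "bold"):
            raise InvalidArgumentError(f"unknown mode {self.mode!r}")
        if self.dropout not in ("random", "tail"):
            raise InvalidArgumentError(f"unknown dropout rule {self.dropout!r}")
        if self.mask is None:
            self.mask = default_mask(self.grid)
        elif not self.mask.grid.matches(self.grid):
            raise InvalidArgumentError("mask grid does not match cohort grid")


@dataclass
class SubjectRecord:
    """One subject's clinical record."""

    id: str
    group: str  # "patient" | "control"
    completer: bool
    vas_baseline: float | None = None
    vas_post: float | None = None
    mmd_baseline: float | None = None
    mmd_post: float | None = None
    duration: float | None = None  # months
    photophobia: bool | None = None
    phonophobia: bool | None = None
    nausea: bool | None = None
    vomiting: bool | None = None


@dataclass
class CohortTruth:
    """Ground truth planted in a cohort."""

    cluster_masks: list[Mask]
    effect_sizes: list[float]
    outcome_betas: dict[str, float]       # outcome -> beta
    outcome_cluster: dict[str, int]       # outcome -> index into cluster_masks
    roi_means: dict[str, dict[str, float]]  # outcome -> subject id -> mean zALFF
    improvements: dict[str, dict[str, float]]  # outcome -> subject id -> pre-clip change
    seed: int


@dataclass
class Cohort:
    """A generated cohort: maps (or BOLD), motion, clinical table, truth."""

    config: CohortConfig
    subjects: list[SubjectRecord]
    zalff_maps: dict[str, "alff_mod.ZAlffMap"]
    bold: dict[str, Bold4D]
    motion: dict[str, alff_mod.MotionParams]
    clinical: pd.DataFrame
    truth: CohortTruth
    post_zalff_maps: dict[str, "alff_mod.ZAlffMap"] = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        """+1 for patients, -1 for controls, in subject order."""
        return np.array([1 if s.group == "patient" else -1 for s in self.subjects])

    def patient_ids(self) -> list[str]:
        return [s.id for s in self.subjects if s.group == "patient"]

    def completer_ids(self) -> list[str]:
        return [s.id for s in self.subjects if s.completer]


def generate_band_limited_series(target_alff: float, band: tuple[float, float],
                                 tr: float, n: int, seed=None,
                                 noise_floor: float = 0.0) -> np.ndarray:
    """A time series whose mean in-band spectral amplitude equals ``target_alff``.

    Each in-band frequency bin receives amplitude ``target_alff`` with a
    random phase; out-of-band bins get amplitude ``noise_floor``. The series
    mean is zero.
    """
    if target_alff < 0:
        raise InvalidArgumentError("target amplitude must be >= 0")
    if n < 16:
        raise InvalidArgumentError("need at least 16 timepoints")
    bins = alff_mod._band_bins(n, tr, band)  # validates the band
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_bins = n // 2 + 1
    spec = np.zeros(n_bins, dtype=complex)
    phases = rng.uniform(0, 2 * np.pi, size=n_bins)
    spec[bins] = (target_alff * n / 2.0) * np.exp(1j * phases[bins])
    if noise_floor > 0:
        out = np.setdiff1d(np.arange(1, n_bins), bins)
        spec[out] = (noise_floor * n / 2.0) * np.exp(1j * phases[out])
    # the Nyquist bin of an even-length real FFT must be real
    if n % 2 == 0 and abs(spec[-1]) > 0:
        spec[-1] = abs(spec[-1])
    return np.fft.irfft(spec, n=n)


def _cluster_mask(cluster: EffectCluster, mask: Mask) -> Mask:
    grid = mask.grid
    offs = sphere_offsets(cluster.radius_mm, grid.voxel_size)
    idx = np.asarray(cluster.center_index) + offs
    inside = np.all((idx >= 0) & (idx < np.asarray(grid.dims)), axis=1)
    if not inside.all():
        raise InvalidArgumentError(
            f"effect cluster at {cluster.center_index} extends outside the grid")
    data = np.zeros(grid.dims, dtype=bool)
    data[tuple(idx.T)] = True
    if not mask.data[data].all():
        raise InvalidArgumentError(
            f"effect cluster at {cluster.center_index} extends outside the mask")
    return Mask(grid, data)


def _smooth_background(rng: np.random.Generator, grid: VolumeGrid, mask: Mask,
                       fwhm: float, noise_sd: float) -> np.ndarray:
    raw = rng.standard_normal(grid.dims) * noise_sd
    sm = alff_mod.gaussian_smooth(raw, grid, fwhm)
    vals = sm[mask.data]
    sm = (sm - vals.mean()) / vals.std()
    return sm


def _simulate_motion(rng: np.random.Generator, n: int, motion_sd: float) -> alff_mod.MotionParams:
    steps = np.hstack([
        rng.normal(0, motion_sd, size=(n, 3)),          # translations, mm
        rng.normal(0, motion_sd / 100.0, size=(n, 3)),  # rotations, rad
    ])
    steps[0] = 0.0
    return alff_mod.MotionParams(np.cumsum(steps, axis=0))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort; identical config and seed give identical output."""
    rng = np.random.default_rng(config.seed)
    grid, mask = config.grid, config.mask

    cluster_masks = [_cluster_mask(c, mask) for c in config.effect_clusters]
    outcome_betas: dict[str, float] = {}
    outcome_cluster: dict[str, int] = {}
    for i, c in enumerate(config.effect_clusters):
        if c.outcome is not None:
            if c.outcome not in ("vas", "mmd"):
                raise InvalidArgumentError(f"unknown outcome {c.outcome!r}")
            outcome_betas[c.outcome] = c.outcome_beta
            outcome_cluster[c.outcome] = i

    ids = ([f"sub-P{i + 1:02d}" for i in range(config.n_patients)]
           + [f"sub-C{i + 1:02d}" for i in range(config.n_controls)])
    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls

    # completers among patients
    if config.dropout == "tail":
        completer_set = set(ids[: config.n_completers])
    else:
        pick = rng.choice(config.n_patients, size=config.n_completers, replace=False)
        completer_set = {ids[i] for i in sorted(pick)}

    zalff_maps: dict[str, alff_mod.ZAlffMap] = {}
    bold: dict[str, Bold4D] = {}
    motion: dict[str, alff_mod.MotionParams] = {}
    target_maps: dict[str, np.ndarray] = {}
    # planted shift profile: sphere indicator convolved with the smoothing
    # kernel, rescaled so the mean shift inside the sphere equals d
    effect_template = np.zeros(grid.dims)
    for c, m in zip(config.effect_clusters, cluster_masks):
        profile = alff_mod.gaussian_smooth(m.data.astype(float), grid,
                                           config.background_fwhm)
        effect_template += profile * (c.group_effect_d / profile[m.data].mean())

    for sid, group in zip(ids, groups):
        bg = _smooth_background(rng, grid, mask, config.background_fwhm, config.noise_sd)
        target = bg + (effect_template if group == "patient" else 0.0)
        target_maps[sid] = target
        if config.mode == "zalff":
            data = np.full(grid.dims, np.nan)
            data[mask.data] = target[mask.data]
            zalff_maps[sid] = alff_mod.ZAlffMap(grid=grid, mask=mask, data=data)
        else:
            bold[sid] = _synthesize_bold(rng, target, grid, config)
        motion[sid] = _simulate_motion(rng, config.n_timepoints, config.motion_sd)

    # per-subject region means of the generating (noise-free-pipeline) maps;
    # in BOLD mode the truth is defined on the target zALFF pattern
    roi_means: dict[str, dict[str, float]] = {o: {} for o in outcome_betas}
    for outcome, ci in outcome_cluster.items():
        cm = cluster_masks[ci]
        for sid in ids:
            roi_means[outcome][sid] = float(np.mean(target_maps[sid][cm.data]))

    subjects: list[SubjectRecord] = []
    improvements: dict[str, dict[str, float]] = {o: {} for o in outcome_betas}
    for sid, group in zip(ids, groups):
        rec = SubjectRecord(id=sid, group=group, completer=sid in completer_set)
        if group == "patient":
            rec.vas_baseline = float(np.clip(rng.normal(*_VAS_BASE), 0.5, 10.0))
            rec.mmd_baseline = float(np.clip(rng.normal(*_MMD_BASE), 0.0, 30.0))
            rec.duration = float(np.clip(rng.normal(*_DURATION), 3.0, None))
            for symptom, p in _SYMPTOM_P.items():
                setattr(rec, symptom, bool(rng.random() < p))
            if rec.completer:
                for outcome, beta in outcome_betas.items():
                    d = config.effect_clusters[outcome_cluster[outcome]].group_effect_d
                    base_mean = _VAS_IMPROVE_MEAN if outcome == "vas" else _MMD_IMPROVE_MEAN
                    change = (base_mean
                              + beta * (roi_means[outcome][sid] - d)
                              + rng.normal(0, config.outcome_noise_sd))
                    improvements[outcome][sid] = float(change)
                    if outcome == "vas":
                        rec.vas_post = float(np.clip(rec.vas_baseline - change, 0.0, 10.0))
                    else:
                        rec.mmd_post = float(np.clip(rec.mmd_baseline - change, 0.0, 30.0))
        else:
            rec.completer = False
        subjects.append(rec)

    # follow-up maps for completers (zalff mode): the outcome region's zALFF
    # decreases in proportion to the subject's improvement, plus session-
    # to-session (retest) noise
    post_zalff_maps: dict[str, alff_mod.ZAlffMap] = {}
    if config.mode == "zalff" and outcome_betas:
        unit_profiles = {}
        for outcome, ci in outcome_cluster.items():
            m = cluster_masks[ci]
            profile = alff_mod.gaussian_smooth(m.data.astype(float), grid,
                                               config.background_fwhm)
            unit_profiles[outcome] = profile / profile[m.data].mean()
        for sid in ids:
            if sid not in completer_set:
                continue
            delta = np.zeros(grid.dims)
            for outcome in outcome_betas:
                imp = improvements[outcome].get(sid, 0.0)
                delta += config.treatment_scale * imp * unit_profiles[outcome]
            retest = _smooth_background(rng, grid, mask, config.background_fwhm,
                                        config.noise_sd) * config.retest_noise_sd
            data = np.full(grid.dims, np.nan)
            data[mask.data] = (target_maps[sid] - delta + retest)[mask.data]
            post_zalff_maps[sid] = alff_mod.ZAlffMap(grid=grid, mask=mask, data=data)

    clinical = pd.DataFrame([vars(s) for s in subjects]).rename(columns={"id": "subject_id"})
    truth = CohortTruth(
        cluster_masks=cluster_masks,
        effect_sizes=[c.group_effect_d for c in config.effect_clusters],
        outcome_betas=outcome_betas,
        outcome_cluster=outcome_cluster,
        roi_means=roi_means,
        improvements=improvements,
        seed=config.seed,
    )
    return Cohort(config=config, subjects=subjects, zalff_maps=zalff_maps,
                  bold=bold, motion=motion, clinical=clinical, truth=truth,
                  post_zalff_maps=post_zalff_maps)


def _synthesize_bold(rng: np.random.Generator, target_z: np.ndarray,
                     grid: VolumeGrid, config: CohortConfig) -> Bold4D:
    """BOLD series whose in-band amplitude pattern encodes ``target_z``.

    The per-voxel target amplitude is ``amp0 * (1 + cv * target_z)`` clipped
    to stay positive, so the spectral pipeline recovers a zALFF map close to
    ``target_z`` up to the within-mask standardization.
    """
    amp0, cv = 10.0, 0.25
    n = config.n_timepoints
    bins = alff_mod._band_bins(n, config.tr, alff_mod.DEFAULT_BAND)
    amps = amp0 * np.clip(1.0 + cv * np.nan_to_num(target_z), 0.05, None)
    phases = rng.uniform(0, 2 * np.pi, size=grid.dims + (len(bins),))
    spec = np.zeros(grid.dims + (n // 2 + 1,), dtype=complex)
    spec[..., bins] = (amps[..., None] * n / 2.0) * np.exp(1j * phases)
    series = np.fft.irfft(spec, n=n, axis=-1)
    # white measurement noise + linear scanner drift
    series += rng.normal(0, 0.5, size=series.shape)
    drift = rng.normal(0, 1.0)
    series += drift * np.linspace(-1, 1, n)
    return Bold4D(grid=grid, data=series, tr=config.tr)


def write_cohort(cohort: Cohort, directory, overwrite: bool = False) -> Path:
    """Write a cohort as a file tree: NIfTI + motion text + clinical TSV + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.yaml"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")

    files: list[str] = []
    cfg = cohort.config
    for s in cohort.subjects:
        if cfg.mode == "zalff":
            fname = f"zalff_{s.id}.nii.gz"
            write_volume(directory / fname, np.nan_to_num(cohort.zalff_maps[s.id].data),
                         cfg.grid)
        else:
            fname = f"bold_{s.id}.nii.gz"
            write_volume(directory / fname, cohort.bold[s.id].data, cfg.grid, tr=cfg.tr)
        files.append(fname)
        if s.id in cohort.post_zalff_maps:
            pname = f"zalff_post_{s.id}.nii.gz"
            write_volume(directory / pname,
                         np.nan_to_num(cohort.post_zalff_maps[s.id].data), cfg.grid)
            files.append(pname)
        mname = f"rp_{s.id}.txt"
        np.savetxt(directory / mname, cohort.motion[s.id].values, fmt="%.8f")
        files.append(mname)

    write_volume(directory / "mask.nii.gz", cfg.mask.data.astype(float), cfg.grid)
    files.append("mask.nii.gz")
    for i, m in enumerate(cohort.truth.cluster_masks):
        fname = f"truth_cluster{i}.nii.gz"
        write_volume(directory / fname, m.data.astype(float), cfg.grid)
        files.append(fname)

    cohort.clinical.to_csv(directory / "clinical.tsv", sep="\t", index=False)
    files.append("clinical.tsv")

    manifest = {
        "seed": cfg.seed,
        "mode": cfg.mode,
        "tr": cfg.tr,
        "n_timepoints": cfg.n_timepoints,
        "n_patients": cfg.n_patients,
        "n_controls": cfg.n_controls,
        "n_completers": cfg.n_completers,
        "grid_dims": list(cfg.grid.dims),
        "voxel_size_mm": list(cfg.grid.voxel_size),
        "effect_clusters": [
            {"center_index": list(c.center_index), "radius_mm": c.radius_mm,
             "group_effect_d": c.group_effect_d, "outcome_beta": c.outcome_beta,
             "outcome": c.outcome}
            for c in cfg.effect_clusters
        ],
        "outcome_betas": cohort.truth.outcome_betas,
        "files": files,
    }
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return directory


def read_cohort(directory):
    """Read back a written cohort.

    Returns ``(maps, mask, motion, clinical, manifest, post_maps)`` where
    ``maps`` holds zALFF maps or BOLD series keyed by subject id and
    ``post_maps`` the follow-up zALFF maps of completers (empty if absent).
    """
    from .spatial import read_volume

    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    clinical = pd.read_csv(directory / "clinical.tsv", sep="\t")
    mask_data, grid = read_volume(directory / "mask.nii.gz")
    mask = Mask(grid, mask_data > 0.5)
    maps: dict[str, object] = {}
    post_maps: dict[str, alff_mod.ZAlffMap] = {}
    motion: dict[str, alff_mod.MotionParams] = {}

    def _zalff_from(path):
        data, _ = read_volume(path, expected_grid=grid)
        out = np.full(grid.dims, np.nan)
        out[mask.data] = data[mask.data]
        return alff_mod.ZAlffMap(grid=grid, mask=mask, data=out)

    for sid in clinical["subject_id"]:
        if manifest["mode"] == "zalff":
            maps[sid] = _zalff_from(directory / f"zalff_{sid}.nii.gz")
            post_path = directory / f"zalff_post_{sid}.nii.gz"
            if post_path.exists():
                post_maps[sid] = _zalff_from(post_path)
        else:
            maps[sid] = read_volume(directory / f"bold_{sid}.nii.gz",
                                    expected_grid=grid, tr=manifest["tr"])
        motion[sid] = alff_mod.MotionParams.from_file(directory / f"rp_{sid}.txt")
    return maps, mask, motion, clinical, manifest, post_maps
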