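# Methods

## The analysis chain

The package re-implements a three-stage resting-state fMRI marker analysis
for migraine without aura (MWoA) and acupuncture treatment response.

**Stage 0 — subject-level maps.** Each subject's preprocessed 4D BOLD
series is reduced to one standardized amplitude map. After motion quality
control (Power-convention framewise displacement: sum of absolute backward
differences of the six rigid-body parameters, rotations converted to arc
length on a 50-mm sphere; a subject fails when mean FD > 0.5 mm or any
translation exceeds one voxel), the first 10 volumes are discarded, each
voxel is residualized against an intercept, a linear trend and any supplied
nuisance regressors (white-matter and CSF means; optionally the Friston-24
motion expansion), the volumes are smoothed with a 6-mm-FWHM Gaussian, and
the amplitude of low-frequency fluctuation (ALFF) is computed as the mean
single-sided spectral amplitude (`2|X_k|/n`) over the frequency bins with
0.01 Hz ≤ f ≤ 0.08 Hz, DC excluded. No separate time-domain band-pass
filter is applied: temporal filtering and the band-amplitude summary are a
single spectral operation, which is exact for a raw periodogram. The mean
(rather than the sum) over bins makes the value invariant to series length;
the distinction is immaterial downstream because the map is finally
z-standardized over the gray-matter mask (population SD, so the in-mask
mean is exactly 0 and SD exactly 1). Smoothing precedes the spectral step,
as in the standard DPARSF ordering.

**Stage 1 — searchlight classification.** At every mask voxel a 9-mm
sphere (123 voxels at 3-mm isotropic resolution) collects the subjects'
zALFF values into a features-by-subjects matrix; PCA retains the smallest
set of components reaching 90% cumulative explained variance; a linear
soft-margin SVM (cost 1, no class weights, no further feature scaling —
LIBSVM defaults) is scored by leave-one-out cross-validation, and the
held-out accuracy becomes the voxel's value. "Meaningful classifying
clusters" are connected components (26-connectivity by default,
configurable to 6 or 18) of accuracy ≥ 0.70 with strictly more than 50
voxels, reported by peak accuracy and peak MNI coordinate. The union of
their voxels feeds one overall linear SVC, evaluated with the same LOOCV
protocol and assessed by accuracy, sensitivity (patient class),
specificity, and the rank-statistic AUC (ties counted ½), with label-
shuffle permutation p-values under the add-one rule,
p = (1 + #{perm ≥ obs}) / (1 + n_perm).

**Stage 2 — treatment-response prediction.** For completers, symptom
improvement (baseline − post; positive = better) for headache intensity
(VAS) and attack frequency (monthly migraine days) is predicted from one
region's voxel values with linear ε-SVR (cost 1, ε = 0.1 — LIBSVM
defaults), under 10-fold cross-validation with fresh random unstratified
folds per repetition (fold sizes differ by ≤ 1), repeated 100 times.
Performance per repetition is the squared Pearson correlation between
actual and pooled out-of-fold predictions ("R²" in the field's usage —
*not* the coefficient of determination; it is sign-blind and never
negative) and the mean squared error. Because of that known optimism, the
conventional coefficient of determination is also reported (`q2`).
Significance per repetition comes from outcome shuffles; the default is
500 shuffles per repetition (configurable), since p-values are averaged
over 100 repetitions and the add-one floor of 1/501 is far below any
threshold in use.

**Stage 3 — longitudinal statistics.** Inside a region of interest, each
voxel gets a paired t-test on pre−post differences (positive t = decrease
after treatment); family-wise error is controlled by Bonferroni over the
ROI's testable voxels (zero-variance voxels are excluded from the family
and counted in the report). Bonferroni was chosen over random-field
correction deliberately: the ROIs here are small (10²–10³ voxels) and
random-field theory would require smoothness estimation that buys nothing
at this scale. The ROI-mean zALFF change is correlated with symptom
improvement (Pearson, two-tailed t-transform p). Voxelwise correlation
maps between zALFF and clinical covariates use r's exact t-transform with
n−2 degrees of freedom, thresholded at uncorrected p < 0.05 with a
cluster-size rule of ≥ 20 voxels (inclusive, unlike the classifier's
strict > 50 rule, matching how the two rules are conventionally stated).

## PCA scope: the one consequential ambiguity

Fitting the 90%-variance PCA once on all subjects ("global") or inside
each LOOCV training fold ("per_fold") are both defensible readings of the
protocol, and they differ: global PCA lets the held-out subject influence
the feature basis (mild leakage), per-fold PCA does not. Both are
first-class via `pca_scope`; the library default is `per_fold` (the
leakage-free choice), while the acceptance script runs the full 40+40
cohort in `global` mode — the more natural reading of a pipeline that
assembles feature matrices and reduces them before classifier evaluation,
and roughly 3× cheaper at n = 80. Neither mode is asserted to be "the"
original.

## The SVM solver

All SVM fits run on an in-package SMO solver (numba-compiled) for the
LIBSVM duals of C-SVC and ε-SVR: second-order working-set selection,
box constraints, single equality constraint, KKT stopping tolerance 10⁻³
(the LIBSVM default). Per-fold PCA is carried out in Gram space — the
centred training Gram is eigendecomposed and the SVC trains on the rank-k
truncated kernel, which is mathematically identical to a linear SVC on the
PCA score matrix. The motivation is the fit count: a single searchlight
run performs ~1.3 × 10⁵ SVM fits, and the validation suite performs
millions; a per-call latency of microseconds rather than milliseconds is
the difference between minutes and days. Leave-one-out folds over a fixed
kernel are warm-started from the full-sample dual solution (alpha
seeding); the reference solve uses a loosened tolerance since it only
seeds the folds, and every fold still converges to the strict tolerance,
so results are deterministic and independent of evaluation order. The test
suite pins the solver to sklearn's LIBSVM wrapper (decision-function
agreement on random problems, fold-by-fold LOOCV agreement, and
voxel-for-voxel searchlight equivalence against a naive loop).

## What the synthetic cohort emulates

The generator reproduces the study design: 40 patients + 40 controls, 33
completers, TR 2 s, 180 volumes, 3-mm voxels, and baseline clinical
covariates (VAS 5.49 ± 1.14, monthly migraine days 6.63 ± 6.24, duration
53.75 ± 28.45 months, accompanying-symptom frequencies) drawn from the
reported cohort statistics. Spatial structure lives on a desk-scale
20×24×20 grid with an ellipsoidal ~3,200-voxel "gray-matter" mask; full
MNI-scale grids work but are not the default. The background of each
subject's map is Gaussian noise smoothed to the 6-mm kernel's FWHM and
standardized over the mask, so cluster statistics behave like real zALFF
maps.

Planted group effects are spherical regions (default radius 12 mm, 257
voxels — the size range of reported clusters) whose shift profile is the
sphere indicator convolved with the smoothing kernel, rescaled so the
*mean* shift inside the sphere equals exactly the nominal effect size d
(default 2.5). The apodized edge mirrors how a focal amplitude difference
looks after a smoothing pipeline; a hard-edged shift would saturate
classification accuracy over the searchlight's entire 9-mm smearing halo
and make spatial recovery metrics meaningless. Note the halo is real
either way: any voxel within one sphere radius of an effect sees effect
voxels, so specificity statements are made for voxels *farther than 9 mm*
from the planted region.

Treatment response is planted as improvement = mean change + β ·
(region-mean zALFF − d) + Gaussian noise. Defaults β_VAS = 2.0,
β_MMD = 1.5 with noise SD 0.5 put the prediction signal-to-noise at ≈ 0.8
and ≈ 0.6 — the regime of the reported prediction strengths, with VAS the
better-predicted outcome. Completers additionally get a follow-up map:
baseline minus a treatment effect proportional to their improvement
(localized on the outcome region, 0.3 zALFF units per unit improvement)
plus session-to-session noise (SD 0.3), which gives the longitudinal stage
a decreasing region whose change correlates with improvement.

Two generation modes share identical truth records: `zalff` draws the maps
directly (fast; the default for tests), `bold` synthesizes full 4D series
whose in-band spectral amplitude encodes the same maps (random-phase
harmonic synthesis plus white noise and a linear drift), exercising the
whole spectral pipeline. The generator does *not* model hemodynamics,
physiological noise, scanner artifacts beyond a linear trend, or
registration error — so passing tests demonstrate the statistical
machinery recovers planted structure under idealized spatial noise, not
robustness to real acquisition artifacts.

## Problem sizes used by the validation suite

All validation runs on one CPU. The planted-recovery check runs one
20+20-subject searchlight on the full ~3,200-voxel mask; the 20-seed
null-specificity check runs on a 14×16×14 grid (~820-voxel mask) with the
same subject counts and thresholds, a size chosen to keep twenty full
searchlight runs within a desk-scale test budget. Permutation-validity
simulations use 200 null datasets of 16 subjects at 199 shuffles;
prediction-recovery uses 33 completers with 20 repetitions (high-signal
case) and 100 null cohorts at one repetition × 199 shuffles. The
acceptance script runs the full 40+40 cohort once: global-PCA searchlight,
5,000-permutation overall classifier, 100×10-fold SVR with 200 shuffles
per repetition, and the longitudinal ROI statistics.

## Numerical and degenerate-input conventions

Decision values exactly at 0 predict the patient class. Peak selection
within clusters breaks ties by smallest lexicographic voxel index.
Correlation-cluster peaks maximize |r| and report the signed r; paired-t
peaks likewise for t. PCA component counts are capped at the numerical
rank (eigenvalues below 10⁻¹² of the largest are treated as zero); a
zero-variance sphere yields a zero score matrix, whose SVM predicts the
training majority. Constant outcomes, constant clinical covariates,
empty masks and single-class label vectors raise typed errors rather than
propagating NaNs. The z-transform refuses constant maps. All randomness
flows through explicit seeds (`numpy.random.default_rng`); per-stage seeds
in the CLI derive from the master seed plus fixed offsets so stages are
independently reproducible, and identical seeds give bit-identical outputs
everywhere.

## Known limitations

Upstream preprocessing (slice timing, realignment, normalization,
segmentation) is assumed done; only its motion-exclusion rule is
implemented. The permutation test of the overall classifier keeps the
cluster masks fixed across shuffles — as in the emulated sequential design
— which makes its p-values optimistic relative to re-deriving the masks
per shuffle. The squared-correlation R² overstates prediction quality;
compare `q2` in the same output. Because extracted clusters include the
searchlight's smearing halo (and neighbouring planted regions can merge
through it), the prediction stage's feature set can be several times
larger than the truly coupled region, diluting the outcome signal — a
property of the sequential cluster-then-predict design, not of the SVR. Accuracy values are multiples of 1/N, so
small cohorts quantize the accuracy map coarsely. The synthetic cohort's
idealizations are listed above; no claim about real MRI data follows from
green tests alone.
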