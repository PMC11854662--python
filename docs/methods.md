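# Methods

## Setting and scope

The package analyses baseline ^18F-FDG PET volumes (SUV-calibrated, 3D,
anisotropic spacing allowed) of follicular-lymphoma patients on watchful
waiting, with two acquisition scanners and a time-to-treatment (TTT)
outcome in months. Clinical cohorts of this kind are small (tens of
subjects) and private; every statistical procedure here is therefore
designed for the small-n regime and validated on synthetic phantoms with
known ground truth. The package does not attempt scanner physics,
DICOM reconstruction, gradient-based ("edge") segmentation, texture
(GLCM-type) features, or Cox regression.

## Segmentation

The reference region is a 2 cm-diameter sphere of voxel centres around a
supplied liver coordinate; a clipped sphere is an error because a
truncated reference biases the background statistics. The lesion
threshold is the PERCIST-style background cut-off

    T = 1.5 · liver mean + 2 · liver SD,

an exact affine map with no tolerance. Conventions the clinical
literature leaves open, fixed here and configurable where noted:

- liver SD is the sample SD (ddof = 1);
- the threshold comparison is closed (voxels with SUV exactly `T` are
  tumour), the common reading in PERCIST-style thresholding;
- connectivity is 26-neighbour in 3D, the standard for PET hot spots;
- components smaller than `min_lesion_voxels = 3` are discarded as
  noise — a stand-in for the human rejection of spurious foci, which has
  no algorithmic equivalent. Physiological-uptake rejection is
  represented by caller-supplied exclusion masks for the same reason.

MTV is voxel count × voxel volume (cm³); TMTV is the sum over lesions.
An empty result is a warning, not an error: the caller decides whether a
scan without supra-threshold lesions is admissible.

## Feature set (81 per subject)

Three regions: the pooled tumour burden, the lesion containing the
global SUVmax, and the liver VOI.

- First-order intensity statistics (17): mean, population variance,
  skewness, excess kurtosis, median, min, P10, P90, max, IQR, range,
  mean absolute deviation, robust MAD (values within [P10, P90] about
  their own mean), energy (Σx²), RMS, uniformity and entropy. Pooling:
  computed once over the multiset of all lesion voxels (morphology
  cannot be pooled across disconnected regions, intensity can).
- Morphology (14): volume, mesh surface area, surface-to-volume ratio,
  sphericity, spherical disproportion, asphericity, compactness-2,
  centre-of-mass shift (‖geometric − SUV-weighted centroid‖, mm),
  maximum 3D diameter, PCA major/minor/least axis lengths (4√λ),
  elongation and flatness. Computed per lesion and averaged
  (unweighted). Compactness-1 is deliberately omitted to keep the
  morphology block at 14; it is a monotone transform of the retained
  compactness-2.
- The liver block keeps first-order only — a placed sphere carries no
  shape information.
- Extras: lesion count, TMTV.

The published analysis this mirrors states 81 features in one place and
82 in another; the block arithmetic (17+14 + 17+14 + 17 + 2) gives 81,
which is what the registry implements.

Numerical conventions:

- Skewness and excess kurtosis of a constant region are 0 by definition
  here (the moments are undefined; 0 avoids NaNs reaching the models).
  Exactly-constant input short-circuits the variance to exactly 0.
- Uniformity/entropy discretise intensities into fixed 0.25-SUV bins
  anchored at 0 (the usual PET choice; configurable via `bin_width`).
- Percentiles use linear interpolation (the numpy default).
- Surface area is the triangulated isosurface at level 0.5 of the
  occupancy field smoothed by a σ = 0.5-voxel Gaussian. Meshing the raw
  binary mask overestimates area by ~7–9% (staircase facets), pushing
  digitized-ball sphericity to ~0.91; the light smoothing cuts the bias
  to ~2–4% for radii ≥ 5 voxels. For very small masks (2–4 voxel radii)
  the residual discretization error is a few percent in either
  direction, so near-spherical lesions can score slightly above 1;
  stronger smoothing would over-round such masks much further. Masks too
  small to retain a 0.5-crossing after smoothing (e.g. a single voxel)
  fall back to the raw binary mesh. Smoothing is in voxel units, so
  with anisotropic spacing the physical smoothing differs per axis.
- PCA axis lengths use the population covariance of voxel centres; a
  single voxel has all axis lengths, elongation and flatness 0.
- SUVmax-lesion ties (two lesions sharing the global max) resolve to the
  larger MTV, then the lowest label.
- `F_stat.energy` (sum of squared SUVs) and `F_stat.uniformity`
  (Σ pᵢ² over discretised intensities) are deliberately both present:
  published feature lists sometimes describe "uniformity" with the
  energy formula, and carrying both makes the registry unambiguous.

## Scanner audit and ComBat

The audit is a per-feature two-sided Wilcoxon–Mann–Whitney test between
the two scanner groups — exact when both groups have ≤ 8 subjects and no
ties, otherwise the tie- and continuity-corrected normal approximation —
followed by Benjamini–Hochberg adjustment across features at 0.05. The
same BH routine is shared by the survival screen. The outcome itself is
also rank-sum-tested against scanner (reported, never acted on).

Harmonization is parametric empirical-Bayes ComBat with a single batch
factor and no covariates: standardise each feature by its grand mean
(batch-size-weighted) and pooled variance, estimate per-batch
location/scale, shrink them toward normal / inverse-gamma hyperpriors
fitted across features (method-of-moments), iterate to 1e-4 relative
change or 100 iterations, and back-transform. Two deliberate choices:

- A final per-feature re-centering restores each feature's original
  cohort grand mean exactly. EB shrinkage otherwise leaves a small
  constant offset; the constant carries no scanner information, and the
  re-centering gives downstream code a clean location contract.
- Zero-variance features pass through untouched and are flagged; they
  are excluded from modelling anyway.

Because shrinkage leaves a residual batch offset, ComBat is only
*approximately* idempotent: a second pass changes null data by a few
percent of scale and the batch-mean gap contracts monotonically — the
tests assert this contraction rather than exact idempotence. The
implementation agrees with Bioconductor `sva::ComBat` to the shared
convergence tolerance, up to the documented re-centering constant.

Features still FDR-significant after harmonization are dropped before
modelling; dropping *everything* is a hard error.

## Models and validation

Targets: continuous TTT for linear regression; TTT ≤ cohort median
("early treatment", the positive class; ties at the median count as
early) for an RBF-kernel SVM (C = 1, γ = 1/(p · pooled variance) — the
common library default, exposed in the API; the clinical analysis this
mirrors does not state its values).

Forward selection is greedy and scored on the **full cohort** (R² for
LR, accuracy for SVM), then the fixed nested subsets are LOOCV-validated
— exactly the two-step select-then-validate protocol used in practice,
which leaks selection information into the validation estimate. A
`nested=True` mode re-selects inside every fold for honest estimates.
Ties in the greedy score resolve in feature-registry order, which also
makes exact duplicates (e.g. the burden max and the SUVmax-lesion max,
equal by construction) resolve deterministically to the first.

Within each LOOCV fold, features are re-z-scored with the training
fold's mean/sample-SD (applied to the held-out subject) — affine, so LR
predictions coincide with the full-data PRESS/hat-matrix closed form,
which the tests exploit as an oracle. Test metrics pool the K held-out
predictions (held-out R² is 1 − SSE/SST about the held-out mean and may
be negative); training metrics are fold averages. SVM folds whose
training set degenerates to one class are skipped with a warning and
reported. ROC-AUC uses the rank (Mann–Whitney, ties = ½) formulation on
signed decision scores oriented toward the early-treatment class.

Censored (never-treated) subjects: the clinical protocol this follows
did not say how they entered the regression/classification targets; the
default uses all subjects with their observed time (treatment or
censoring), and the survival screen restricts to treated subjects.

## Survival screen

Per feature: median split over analysed subjects (ties to the ≤-median
group), two-group log-rank on TTT (1-df chi-square; an optional
permutation p-value exists for very small n), BH across all screened
features at 0.05. Degenerate splits (a constant feature) are skipped
with a warning. Kaplan–Meier estimation and the log-rank statistic are
delegated to lifelines.

A power note: at hazard ratio 3 with 13 + 13 all-event subjects the
two-sided log-rank's finite-sample power at 0.05 is ≈ 0.74 (the
asymptotic approximation says 0.80). Simulation studies at this design
point should expect ~74% detection, not 80%; the package's own power
test documents this.

## The phantom: what it emulates, and what it does not

Each subject: quasi-spherical lesions (spheres in continuous space, so
true sphericity and volume are analytic) rasterised to the grid,
PSF-blurred with each lesion's amplitude rescaled so its post-blur peak
equals the drawn peak SUV, additive Gaussian background noise, and an
ellipsoidal liver painted with independent N(mean, SD) draws — exact
control over the reference statistics that drive the threshold.
Lesions are placed with enforced separation from each other and the
liver, so ground-truth lesion count equals the segmentable count.

Defaults mirror the emulated clinical setting: 38 subjects, 16/22
scanner split, ~7 lesions per subject (±3), lesion radii 6–14 mm, peak
SUV 7–14, background 1.0 ± 0.15 SUV, liver 2.2 ± 0.25 SUV, PSF σ 2.5 mm,
3 mm isotropic voxels, ~32% never-treated. Scanner effects are applied
in *image space* (gain and offset on voxels) so they propagate through
segmentation and extraction the way real scanner differences would.

TTT = intercept + Σ coefficient × ground-truth feature + N(0, σ),
clamped at 1 month. Ground-truth features come from the noiseless
volume and true masks, separating outcome-model recovery from
segmentation error. The default designated features are TMTV, lesion
count and burden kurtosis with coefficients (−1.5, −6, +7), intercept
87 and σ = 10 months — higher burden and more lesions shorten TTT, on
the months scale of the emulated cohort. Censored subjects carry a
uniform 24–120-month follow-up time.

Not emulated: scatter/attenuation/reconstruction artefacts, respiratory
motion, physiological uptake (no false-positive foci — which is why the
minimum-size filter, not the exclusion masks, is exercised by default),
non-spherical or heterogeneous lesions, and between-subject liver-mean
variation. Consequently, passing tests demonstrate correctness of the
*computations* and recoverability of *injected* structure; they do not
certify predictive performance on clinical data.

### Identifiability of designated outcome features

The 81 features are strongly collinear functions of a few generative
latents (lesion sizes, peaks, count, positions). Recovery experiments
therefore designate features chosen by an identifiability analysis:
TMTV, lesion count and burden kurtosis are each the best proxy of their
own latent (maximum correlation with any other feature ≤ ~0.87), whereas
e.g. the burden maximum is unusable as a designated feature because
`range = max − threshold` duplicates it almost exactly. Even so, lesion
*count* and mean lesion *size* are informationally interchangeable given
TMTV, which caps exact three-feature recovery at roughly 70–75% of
seeds; the recovery test asserts the median-seed behaviour. For the
overfitting experiment at n = 38 the signature is read from the SVM
(training accuracy improves with more features while held-out accuracy
peaks below four): with correlated informative proxies a fourth LR
predictor usually still helps slightly, matching the marginal (~1.5%)
LR degradation seen in the clinical analysis, while the SVM pattern is
robust. The weak-signal regime for that experiment uses σ = 30 months,
putting held-out R² in the 0.05–0.3 range of the emulated study.

## Problem sizes and runtime

The test suite and the acceptance script scale the simulations to a
single core: repeated-cohort studies use a 40³-voxel grid at 3 mm with
3 ± 1 lesions (~20 ms per subject through segmentation and extraction);
the showcase pipeline uses the full 64³ default phantom at n = 20–38.
The whole suite runs in ~7 minutes; `scripts/acceptance.py` in ~1.
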