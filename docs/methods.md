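# Methods

This note documents the models, conventions and numerical choices behind
`voxelrad`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Voxel-wise features and aggregation

For every ROI voxel v, a cubic window (default 9 voxels per edge, an odd
integer so the window is centred) is intersected with the ROI and the 77
engineered features are computed on that voxel set: 18 first-order, 24
GLCM, 14 GLDM, 16 GLRLM and 5 NGTDM features, following the standard
engineered-radiomics catalog. Design choices that the catalog leaves open:

- **Window masking.** Only in-ROI voxels contribute (prevents signal
  leaking in from outside the tumor). The unmasked variant is available
  behind `masked=False` for toolkits that slide an unmasked cube.
- **Matrix accumulation.** GLCM pair counts (symmetric, distance 1) and
  GLRLM runs are accumulated over all 13 unique 3D directions into a
  single matrix, normalized after accumulation, with no distance
  weighting. GLDM uses dependence threshold α = 0 at Chebyshev distance 1,
  a voxel's dependence counting itself plus equal-level in-mask
  neighbours. NGTDM uses the 26-neighbourhood; voxels without in-mask
  neighbours are excluded from N_vp.
- **Gray levels.** Texture matrices use the image-wide discretized levels
  restricted to the levels present in the window — no per-window
  re-binning — so values are comparable across windows. Levels absent
  from a window contribute zero probability, which leaves every feature
  value unchanged relative to carrying the full level axis.
- **First-order split.** Intensity statistics (mean, percentiles, energy,
  …) use raw intensities; Entropy and Uniformity use the discretized
  histogram. Energy remains an unnormalized sum and therefore scales with
  the in-window voxel count; it is kept as defined in the catalog.
- **Degenerate windows.** Constant windows define Skewness = Kurtosis = 0
  and GLCM Correlation = 1 (the limits of the ratio conventions).
  Windows holding fewer than 2 in-ROI voxels cannot support texture
  matrices; such voxels copy the nearest computable voxel's values so the
  mean aggregation is defined at every ROI voxel.

The patient-level feature is the plain ROI mean of each map. This
linearity is load-bearing: it is what makes the decision-map identity
below exact.

The 14 shape descriptors (mesh/voxel volume, surface area and ratio,
sphericity, max 3D and three max 2D diameters, PCA axis lengths,
elongation, flatness) are computed from the resampled binary mask. The
marching-cubes surface is extracted from a Gaussian-smoothed (σ = 0.8
voxel) copy of the zero-padded mask: the raw binary surface overestimates
the area of a digital ball by roughly 10 % through staircase faceting,
which would bias sphericity; masks small enough that smoothing would
erase them fall back to the raw binary surface. Axis lengths are 4·√λ of
the physical-coordinate covariance eigenvalues (population convention).
Max 2D diameters are the largest in-plane distance between boundary voxel
centres within any slab perpendicular to the named axis. A single-voxel
mask returns zero diameters and axis lengths and unit elongation/flatness
rather than erroring.

## Preprocessing conventions

- All standard deviations are population SDs (divide by N), recorded in
  output metadata.
- Fat-reference normalization pools all fat-sphere voxels of a patient
  and maps intensities affinely to mean 0 / SD 1 of that pool; ROI
  z-scoring does the same with tumor-ROI statistics. Both are affine, so
  within-image intensity ordering is exactly preserved. Fat statistics
  are computed on the native-grid image before resampling.
- CT ROI conditioning keeps the closed HU band [−230, 600]; the bounds
  themselves are retained ("less than" / "greater than" read strictly).
- Fixed-bin-size discretization anchors bins at multiples of the width
  (the in-ROI minimum always lands in level 1); fixed-bin-count spans a
  cohort-wide range with an inclusive top edge, clamping out-of-range
  values with a logged warning.
- Images resample with order-3 B-splines, masks with nearest neighbour.
  Default target spacings: PET 3 mm, CT/T1/T2fs 1 mm.

## The ASB score and the selection pipeline

ASB = 1 − (SB_C0 + SB_C1)/2, where SB_Ck is the mean squared error of the
predicted probability within class k. Anchors (asserted exactly in the
tests): perfect 1, always-wrong 0, constant-0.5 0.75, majority-class
dummy 0.5. CV scores are the pooled out-of-fold ASB per repeat,
mean ± SD over repeats; pooling over folds keeps the per-repeat score
defined even when a 5-fold split leaves few minority cases per fold.

The logistic model is L1-penalized with class-balanced cross-entropy,
solved by the deterministic liblinear coordinate-descent solver
(tol 1e-4, max 100 iterations; the intercept is penalized through the
solver's augmented-feature formulation). The inner CV and bootstrap loops
call the solver binding directly with precomputed class weights — the
identical objective without per-call estimator overhead — and fall back
to the public estimator on any signature mismatch; a cross-solver test
checks the fitted coefficients against an independent penalized-likelihood
optimizer (L-BFGS-B on a nonnegative split) to 1e-4.

Forward selection greedily adds the candidate maximizing mean CV ASB,
with z-scoring refit inside every training fold (a deliberate-leak test
asserts that full-table scaling changes the scores). The C grid is 10
log-spaced values in [0.1, 100]. The retained (C, k) is chosen by a
one-SD parsimony rule — smallest k, then smallest C, among configurations
within one SD of the global best — replacing a manual tradeoff with a
reproducible rule; the full grid is returned for manual override.

The permutation test reruns the entire selection + grid search on
shuffled labels and uses the plus-one estimator
p = (1 + #{null ≥ observed}) / (1 + n_perm), so the smallest attainable
p at n permutations is 1/(n+1).

Bagging draws class-stratified bootstrap resamples (guaranteeing both
classes in every fit at small n), refits scaling and model per resample,
and averages standardized-space coefficients; per-feature SDs quantify
stability. OOB ROC AUC is computed per resample, and the same resample
stream (same seed) scores the conventional biomarkers — ATV, SUVmax,
MTV (SUV ≥ 40 % SUVmax; threshold configurable) and TLG (MTV × its mean
SUV) — so model/biomarker comparisons are paired. Averaging coefficients
in a single full-cohort standardized space is a simplification: each
bootstrap's coefficients assume its own resample scaling; the residual
inconsistency is inherited by any coefficient-averaging scheme that
reports β ± SD.

## Decision maps

Selected features' maps are standardized with the cohort mean/SD of the
aggregated features (the same statistics the model's coefficients
assume), multiplied by the coefficients and summed with the intercept.
On the native extraction grid the ROI mean of the map plus the
non-mappable (shape) offset reproduces the tabular decision value and
probability exactly (asserted to 1e-6 end to end; the identity is linear
algebra, the tolerance covers float accumulation). Resampling maps to a
common 1 mm display grid necessarily breaks the exact identity; the
residual is computed and stored on the exported map rather than hidden.
Voxels outside the ROI are NaN in exports: the decision value is
undefined there.

## Surrogate features and distillation

Necrosis-oriented sub-volumes are defined by PET < 40 % SUVmax
("inactive"), CT < 20 or < 30 HU ("hypodense"), and their unions and
intersections; each yields an absolute volume V (ml) and a relative
volume rV = V/ATV. log10 transforms are added for all of them and the
shape features, flooring volumes at 0.01 ml and ratios at 1e-3 to keep
the transform finite. Distillation binarizes a teacher model's
probabilities at 0.5 (the continuous-target variant is a caller-side
choice; a logistic student needs a binary target) and reruns the same
reduction/selection/bagging pipeline on the surrogate set, reporting the
teacher–student probability correlation.

## The phantom generator

Phantoms emulate the two sub-regional patterns the method is designed to
surface: an axis-aligned ellipsoidal tumor (default semi-axis ratios
1 : 0.85 : 0.7, so shape descriptors are informative) with a concentric
necrotic core and a viable rim, on a co-registered grid for all four
modalities. Class 1 draws a larger necrotic volume fraction
(0.35 vs 0.10, SD 0.06) and higher rim uptake (SUVmax 9 vs 5, SD 1.2);
the tumor radius varies mildly per case (SD 1.5 mm) so anatomical volume
is a non-degenerate comparison biomarker. Core intensities sit at 1 SUV /
10 HU / dark T1 / bright T2fs and the rim at 40–80 HU, so the 20/30 HU
and 40 %-SUVmax thresholds segment the core and the surrogate features
can be validated against the generator's recorded truths. Twenty ~240 mm³
fat spheres with fixed-SD texture are planted outside the tumor in T1 to
exercise fat-reference normalization. Additive Gaussian noise per
modality (defaults 0.2 SUV, 8 HU, 10/10 a.u.) is the only noise model.

What the phantoms do *not* emulate — partial-volume effects, scanner
point-spread functions, registration error, intensity non-uniformity,
anatomically realistic heterogeneity — bounds what green tests mean:
they verify the machinery (feature definitions, CV hygiene, identities,
effect recovery under known truths), not clinical performance.

## Problem sizes and tolerances

The suite runs phantoms at 24³ voxels (≈ 270-voxel ROIs) and the
acceptance script one 40³ case (≈ 2000-voxel ROI), sizes at which the
full 77-map extraction of a case takes seconds. Statistical checks use
20×5-fold CV with 100 permutations on a 50-phantom separable cohort
(0.0099 is then the smallest resolvable p) and 19-permutation tests at
5×5-fold CV across 20 label-shuffled null cohorts. Oracle-equivalence
tests compare the vectorized engine with a loop-based brute-force
reference at 1e-6 relative; exact identities (ASB anchors, map means,
affine normalizations) are asserted at 1e-6 to 1e-12 as noted in each
test. The correlation-matrix "null determinant" is operationalized as
|det| < 1e-12, and a non-finite determinant is treated as singular.

## Known limitations

- Per-voxel window extraction is pure Python/NumPy; wall time scales
  linearly with ROI voxels (a few ms each). Large clinical ROIs at 1 mm
  will want coarser grids or patience.
- First-order Energy's window-occupancy dependence (above) makes its map
  values near the ROI boundary occupancy-driven.
- Maximum 2D diameter definitions are slab-based (see above); other
  toolkits use mesh-vertex projections and may differ slightly.
- The grid-search parsimony rule is a heuristic stand-in for expert
  judgement; inspect `GridSearchResult.results` when it matters.
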