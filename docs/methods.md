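# Methods

This note documents the models, conventions and parameter choices behind
`fetrad`, in enough detail to reproduce or critique every number the
package computes.

## Dynamic acquisition model

A dynamic brain-PET study is represented as a 4D voxel grid with a
contiguous frame schedule in minutes post-injection. The default schedule —
five 1-minute frames to 5 min, three 5-minute frames to 20 min, two
10-minute frames to 40 min (10 frames) — is a package choice, made so that
every time-to-peak group boundary (5, 10, 15, 20, 30, 40 min) coincides
with a frame boundary; it is fully configurable, and nothing downstream
assumes it.

## Parametric images

**TBR.** The 20–40 min summation image is the duration-weighted mean of the
frames inside the window (window edges must align with frame boundaries;
misalignment is an error, not a silent crop). It is divided by the mean
activity of the background VOI — in clinical practice a manually drawn
crescent in the contralateral healthy hemisphere, here an analytic crescent
produced by the phantom generator. Tumor segmentation thresholds the TBR
map at 1.6 (inclusive) and keeps the largest 26-connected component, since
the target is a single lesion and pure thresholding can pick up specks
(configurable off). An empty mask is a reported outcome, not an error.

**TTP.** Each voxel's TAC is classified by the frame in which it peaks:

1. frames whose **midpoint** falls before 2.7 min p.i. are excluded — the
   midpoint is taken as the frame's representative time; with the default
   schedule this removes the first three 1-minute frames;
2. the late slope is the OLS slope of frame values against frame midpoints
   over midpoints in [15, 40] min; if it is strictly positive the voxel is
   assigned group 6 regardless of its nominal peak (the tracer is still
   accumulating), i.e. the late-slope rule *overrides* an early peak;
3. otherwise the earliest frame attaining the maximum (ties broken toward
   the earlier frame) defines the peak, and its midpoint is mapped through
   the intervals [0,5)→1, [5,10)→2, [10,15)→3, [15,20)→4, [20,30)→5,
   [30,40]→6.

Whether peak assignment should use the frame index, start or midpoint is a
genuine convention choice; the midpoint is used consistently (classification
and exclusion) and both the cut-off and the late window are parameters.
The TTP map is invariant under any positive per-voxel rescaling of the TAC,
and exactly one group in 1..6 is produced for every non-degenerate TAC.

## Radiomic features

107 features in seven classes: 18 first-order, 14 shape, 24 GLCM, 16 GLRLM,
16 GLSZM, 14 GLDM, 5 NGTDM, named `<class>_<FeatureName>` in a canonical
order (class order as listed, alphabetical within class). That order is part
of the contract: the redundancy filter removes the *later* feature of a
correlated pair, so reordering would change selections.

Conventions that materially affect values:

- **Resampling**: trilinear for intensities, nearest-neighbour for the mask
  (masks stay binary), to 2.03 mm isotropic voxels; the image is cropped to
  the mask bounding box plus a 3-voxel margin first, which supplies
  interpolation context at the ROI boundary.
- **Discretization** is min-of-ROI referenced:
  `level = floor((x − min)/w) + 1`. Texture features are therefore invariant
  under adding a constant to all intensities. Default bin widths: 0.13 for
  TBR images (the cohort-mean interquartile range divided by 4, the
  published value for this tracer; `compute_bin_width_iqr4` recomputes it
  for any cohort), and 5 for TTP maps (the smallest frame duration among
  the group definitions, in minutes). Applied to ordinal groups 1–6 the
  width-5 rule collapses them to two gray levels ({1..5} vs {6}); because
  published practice is ambiguous about whether the width applies to group
  indices or minutes, `extract_all(..., ttp_group_levels=True)` instead
  keeps one level per group (width 1). The default follows the literal rule.
- **Quartiles/percentiles** use linear interpolation of order statistics
  (affects the bin width, IQR and robust-MAD features).
- **GLCM**: distance 1, the 13 unique 3D directions, symmetrized and
  normalized per direction, features averaged over directions with at least
  one voxel pair. **GLRLM**: runs per direction, averaged the same way.
  **GLSZM**: zones are 26-connected components of equal gray level.
  **GLDM**: a 26-neighbour is dependent if its level differs by at most
  alpha (default 0); the dependence size counts the center voxel, so sizes
  run 1..27. **NGTDM**: neighbourhood means over in-mask 26-neighbours;
  voxels with no in-mask neighbour are excluded.
- **Degenerate single-gray-level ROIs**: Correlation and MCC are defined as
  1, Imc1/Imc2 as 0, NGTDM Contrast as 0 and Coarseness is capped at 1e6.
  Each convention is unit-tested.
- **Shape** uses a marching-cubes surface of the binary mask at the 0.5
  iso-level. Note two geometric facts of this estimator: the iso-surface of
  an isolated voxel is the octahedron through its face midpoints (volume
  spacing³/6, diameter = spacing), and the surface of a digitized sphere
  retains ~8% staircase excess area at any radius, bounding measured
  sphericity near 0.92 rather than 1. Axis lengths are 4·√eigenvalue of the
  covariance of physical voxel-center coordinates; maximum 2D diameters are
  the largest pairwise vertex distances in the three coordinate planes
  (Slice: x–y, Column: y–z, Row: x–z).

Every texture and first-order feature is checked against an independent
brute-force implementation (explicit pair enumeration, line walking, flood
fill) to 1e-9 relative on small ROIs.

## Synthetic cohorts

The generator exists so the whole pipeline can be tested with known ground
truth; it emulates the *structure* of a dynamic FET-PET study, not scanner
physics (no count statistics, attenuation, partial-volume or motion).

**Kinetics.** Voxel TACs are normalized gamma-variates
`c(t) = A·uᵅ·exp(α(1−u))`, `u = (t−t₀)/(t_p−t₀)`, zero before onset t₀ and
peaking at exactly `t_p` with value `A` — chosen precisely because the peak
time is analytic, giving TTP classification an oracle. Frame values are
exact interval averages of `c(t)` (PET frames integrate activity); the
integral is evaluated in closed form via the regularized lower incomplete
gamma function, and a test verifies agreement with adaptive quadrature to
better than 1e-8 relative. Noise is additive Gaussian with sd
`noise_sd · A` per frame (default 5%).

**Phantoms.** A 32³ grid of 2 mm voxels holds a spherical tumor (radius 5
voxels) over a uniform background (broad plateau kinetics: A=1, t_p=20 min,
α=0.25) plus a crescent background VOI in the contralateral half. Tumor
voxels draw per-voxel peak times and amplitudes from a phenotype field:

- *aggressive*: t_p ~ U(6.5, 9.5) min, α=0.25, A=4 — early peak with slow
  washout (TTP group 2; TBR₂₀₋₄₀ ≈ 2.3–2.6);
- *indolent*: t_p ~ U(26, 36) min, α=2, A=4 — continued accumulation
  (groups 5–6; TBR₂₀₋₄₀ ≈ 3.9).

Amplitude heterogeneity is 10% CV. The aggressive peak-time range starts at
6.5 min because for broader curves peaking earlier the 4–5 min frame
average can exceed the 5–10 min frame average, which would put the *frame*
peak in group 1 while the analytic peak is in group 2; the chosen range
keeps the two definitions in exact agreement on noiseless phantoms.

**Clinical covariates and label.** Six covariates with marginals typical of
an IDH-wildtype glioblastoma cohort (60% male, 78% TERTp-mutant, 48%
MGMT-methylated, 67% grade 4, age ~N(58, 13²) clipped to 19–78, KPS
distribution with median 80). The short-term-survival label is Bernoulli
with logit `b₀ + Σ βⱼxⱼ + β_kin·[aggressive]`; age and KPS enter
standardized ((age−58)/13, (KPS−80)/20), binaries as 0/1, WHO grade as a
grade-4 indicator. Default log-odds: age +0.4, male +0.2, KPS −0.5, grade 4
+0.3, MGMT methylation −0.6, TERTp mutation +0.4, aggressive phenotype
+1.5 — signs follow clinical direction, magnitudes chosen once as moderate,
realistic effects. The intercept `b₀` is calibrated by bisection (tolerance
1e-6 on the mean event probability) to hit the requested prevalence
(default 0.284). The phenotype influences the label, never the reverse.
Cohorts can be generated lazily (covariates and phantom seeds only), and
`SimulatedPatient.realize()` reproduces the images bit-identically on
demand, keeping memory flat for large simulation studies.

What passing tests on these phantoms shows: the pipeline's arithmetic,
conventions and leakage-freedom are correct, and the modelling stack can
recover a planted kinetic signal of stated strength. What it does not show:
performance on real scanners (reconstruction noise, partial volume, motion,
manual VOIs) or the clinical effect sizes of real cohorts.

## Modelling

- **Split**: training size = round(0.7·n); per-class allocation proportional
  with largest-remainder rounding (141 patients with 40 events → 99/42 with
  28/12 events), membership randomized per seed.
- **Standardization**: z-scores with training-cohort mean and *population*
  (divide-by-n) standard deviation — the convention is documented because
  it is not universal; constant training columns are dropped with a logged
  warning. Radiomic features and the continuous covariates (age, KPS) are
  standardized; binary covariates stay 0/1.
- **Redundancy filter**: iterate pairs (i, j), i < j, in canonical feature
  order; if |Pearson r| > 0.99 (strictly) remove feature j; removed
  features skip further comparisons. Absolute correlation is used so
  anti-duplicates are also removed; zero-variance columns are treated as
  removable duplicates.
- **RFE**: importance is the absolute standardized coefficient of a
  class-balanced L2 logistic regression (weights n/(2n_c), unit
  regularization strength, liblinear solver, max 1000 iterations); one
  feature is removed per step, so a single elimination pass yields nested
  candidate sets for every k. The feature count k ∈ 1..15 is chosen to
  maximize mean validation AUC over a 3-repeat 5-fold stratified CV
  (smallest k on ties — parsimony); the final set comes from RFE on the
  full training data at the chosen k.
- **Signatures and variants**: a radiomic signature is the fitted TBR or
  TTP model's linear predictor (intercept + Σ coef·feature), one scalar per
  patient. Combined variants use signature scalars, never raw radiomic
  features: clinical = 6 covariates; clinical-TBR/TTP = 6 + 1 signature;
  TBR-TTP = 2 signatures; clinical-TBR-TTP = 6 + 2. Six clinical covariates
  are used throughout (age, gender, KPS, WHO grade, MGMT, TERTp).
- **No leakage**: every estimator (scaler, filter, RFE, model) sees
  training rows only; a test verifies that deleting the test rows before
  fitting reproduces all parameters bit-identically.

## Evaluation

AUC is the midrank Mann–Whitney statistic (invariant under strictly
monotone score transforms). Confusion metrics use the probability cut-off
0.5 — the natural threshold under class-balanced weighting; an ROC-optimal
cut-off would be an alternative and the threshold is a parameter.
Confidence intervals are 95% percentile bootstrap over patients (default
1000 resamples); resamples containing a single class are redrawn so the
resample count stays exact, and redraws are logged. IDI between a baseline
and an extended model is the difference of mean predicted probabilities in
events minus that in non-events, with z = IDI/SE,
SE = √(var(d|events)/n₊ + var(d|non-events)/n₋) and a two-sided normal
p-value. Nested cross-validation reruns the entire selection + training
pipeline inside each of 5 outer stratified splits and reports per-split
held-out AUCs and selected features; variability is reported both as the
standard deviation and the range, since "variability" alone is ambiguous.

## Problem sizes in the shipped studies

The repeated-simulation comparison (`replicate_comparison`) uses 50
replicates of n = 200 patients on 32³ phantom grids with TTP features only;
at these sizes a full run completes in roughly 8 minutes on one CPU. The
single worked study uses n = 141 with both TBR and TTP feature blocks and
1000 bootstrap resamples. Both are choices of the package's demonstration
studies; all sizes are parameters.

## Known limitations

- The phantom geometry (single sphere, fixed radius) makes most shape
  features constant across patients; they are dropped by the zero-variance
  guard during standardization in simulation studies. Real cohorts vary in
  shape; the features are still computed and tested.
- Gamma-variate kinetics cannot represent biphasic TACs; the late-slope
  rule is still exercised because indolent phantoms keep rising at 40 min.
- The TTP width-5 discretization reduces TTP texture to a two-level
  pattern; the per-group alternative is provided but not the default.
- Bootstrap CIs are percentile (no bias correction); at n = 42 they are
  noticeably wide, which is faithful to the method.
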