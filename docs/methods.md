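# Methods

This note documents the statistical model, the synthetic phantom, the
numerical conventions, and the design choices made where the design was
genuinely open. It complements the API documentation in the module
docstrings.

## Preprocessing

Scans are assumed co-registered to a common template grid. The fixed
order of operations is **smooth → mask → vectorize → demean →
L2-normalize**:

- *Smoothing*: separable Gaussian, specified as FWHM in millimetres
  (default 1.6 mm); per-axis σ in voxels is FWHM/(2√(2 ln 2) ·
  voxel_size). Boundary handling is renormalized (mass-conserving)
  convolution — the image is convolved with zero padding and divided by
  the identically convolved domain indicator — which preserves constants
  exactly and avoids edge darkening in small phantoms.
- *Demean support*: the spatial mean is taken over **masked voxels
  only**; voxels outside the brain carry no uptake signal, so including
  them would make the demean depend on the field of view.
- *Normalization*: division by the L2 norm of the demeaned masked
  vector. Every feature vector then has zero mean and unit sum of
  squares (asserted to 1e−10), and multiplying a raw scan by any
  positive constant leaves its feature vector unchanged — the property
  that removes injected-dose and global-metabolism differences.
- *Voxel order*: C-order raster scan of mask voxels, recorded as an
  explicit index; any fixed order works but it must be shared by every
  scan and the pattern.
- A constant (zero-variance) scan is rejected as degenerate rather than
  silently producing NaNs.

## PCA in subject space

With N ≈ 18 scans of D ≈ 10⁴ voxels, the D×D covariance is never
formed. Rows are centred by the voxel-wise mean across subjects (this is
distinct from the per-scan spatial demean above; both are needed), the
N×N Gram matrix G = X_c X_cᵀ/(N−1) is eigendecomposed, and eigenvectors
are mapped to voxel space as v = X_cᵀu/√((N−1)λ). The nonzero
eigenvalues coincide with those of the voxel-space sample covariance
(denominator N−1), which the test suite verifies directly at small D.
All components with eigenvalue > 1e−10 × λ_max are retained — component
selection is left entirely to the SVM weighting, not to a variance
cutoff. Eigenvector signs are fixed by making the largest-magnitude
voxel loading positive, so refits are bit-reproducible.

## SVM training by SMO

Both the L1-soft-margin classifier and the ε-insensitive L1-loss
regressor are solved in one canonical dual form

    min ½γᵀQγ − pᵀγ   s.t.  yᵀγ = 0,  0 ≤ γ ≤ C,

with Q_ij = y_i y_j k(x_i, x_j) and the linear kernel k(x, x′) =
⟨x/s, x′/s⟩ (s = kernel scale). Classification uses γ = α, p = 1;
ε-SVR is rewritten on 2N variables (α, α*) with p = (t − ε, −t − ε).
The solver is maximal-violating-pair SMO: at each step the most
KKT-violating pair (i ∈ I_up, j ∈ I_low) is updated analytically with
box clipping, until the violation m − M drops below `tol`. Defaults:
tol = 1e−3, iteration cap 1e5 (exceeded → explicit non-convergence
error with diagnostics). Tests that compare against a generic QP solver
run at tol = 1e−8, where the dual objective agrees to 1e−6.

Numerical conventions:

- *Bias recovery*: b = mean of −y_i·grad_i over free (strictly
  inside-box) points; when none exist, the midpoint of the KKT interval
  [M, m]. In the degenerate SVR case where the ε-tube covers the whole
  target spread (w = 0, no support vectors), this midpoint is the
  midrange of the feasible tube, which is always inside it (the median
  of the targets need not be).
- *Default ε*: 0.1 × the target standard deviation when not given.
- *Decision tie-break*: a decision value of exactly 0 maps to the
  positive (disease) class; pinned by a test.
- *Scale consistency*: doubling the kernel scale is exactly equivalent
  to halving every coordinate (the weight vector lives in the scaled
  feature space).

## Hyperparameter selection

Grid search over C ∈ {10⁻³ … 10³} (7 points) and kernel scale ∈
{2⁻³ … 2³} (7 points), scored by k-fold cross-validated
misclassification rate (classification, stratified folds) or mean
absolute error (regression, plain folds); fold assignment is seeded and
ties break toward smaller C, then smaller scale. `grid_search_nested_cv`
refuses fold counts exceeding the smallest class (a stratified fold
would otherwise lose a class); the pipeline facade lowers the requested
k = 10 to the smallest class size (8 controls) for classification. ε
may optionally join the grid; by default it is set from the target
spread.

## Patterns, expression scores, Z-values

The voxel pattern is p = Aᵀ(w/s), honouring the kernel scale used in
training. Sign convention: the disease training group must have positive
mean raw score; if violated the pattern is flipped and the flip recorded
in provenance. Expression scores are ⟨p, x − m⟩ with m the PCA training
mean, carried inside the pattern object so scores are always computed
against the centering the pattern was derived with. The SVM bias b is
**excluded** from expression scores — the score measures pattern
expression, not class membership, and the subsequent standardization
absorbs constant offsets (so group statistics are unaffected either
way). Z-values standardize raw scores by the mean and SD (N−1
denominator) of all control scans pooled across all timepoints.

## Longitudinal analysis

The pattern is derived at the final timepoint. Classifier accuracy is
estimated by leave-one-out cross-validation in which **everything** —
training mean, PCA basis, SVM, sign convention — is refit on the N−1
retained subjects; the held-out scan influences nothing in its fold
model (asserted by a perturbation test). Final-timepoint expression
scores are the held-out fold scores, for the regression pattern as well
as the classifier, standardized against the full-pattern control
reference. Earlier timepoints are scored with the full final-timepoint
pattern.

Group differences per timepoint use a two-sided Wilcoxon rank-sum test:
exact (dynamic programming over rank subsets, equivalent to full
enumeration) for tie-free pooled samples of size ≤ 25; otherwise a
normal approximation with midranks, tie correction and continuity
correction. Two-sided p doubles the smaller tail, capped at 1. α = 0.05
throughout, with no correction across the five timepoints.

### Known limitation: rank tests on cross-validated scores

Leave-one-out scores are mutually dependent (their training sets share
N−2 subjects), so the rank-sum test at the derivation timepoint is
anti-conservative under the null: same-group scores are positively
correlated and cross-group scores negatively, inflating the variance of
the rank-sum statistic beyond its exchangeable-null value. This is
intrinsic to testing CV scores with a two-sample test and is inherited
from the method being implemented; in-sample scoring would be far worse
(the training criterion itself separates the groups). Consequently the
type-I calibration tests in the acceptance suite cover the timepoints
scored by projecting independent scans onto the final-timepoint pattern
(baseline through week 6), plus a permutation null of the LOOCV
*accuracy*, which is unaffected. Week-9 p-values should be read as
descriptive of the (strong) observed separation, not as calibrated null
probabilities.

## The phantom

The generator emulates the statistical structure the analysis relies
on, not PET physics.

- *Geometry*: 32³ isotropic 1 mm voxels; an ellipsoidal brain mask
  (semi-axes 0.4 × grid) of ≈ 8.7k voxels, partitioned into 15
  contiguous Voronoi parcels from seeded points. This keeps the
  N ≪ D regime of the real data (18 scans vs ~10⁴ masked voxels) at
  desk-scale cost; the scanner's native 128×128×95 geometry is
  configurable but not the default.
- *Signal*: a planted **multiplicative** regional effect — uptake in
  region r is scaled by (1 + schedule(t) · amplitude_r). Because each
  scan is demeaned and unit-normalized, only relative regional uptake
  is identifiable, so a multiplicative relative effect is the right
  generative primitive. Default amplitudes: +0.1 in five regions
  (relative hypermetabolism), −0.1 in five (hypometabolism), 0 in the
  rest; the near-balance keeps the planted map approximately zero-mean
  over the brain, which is the component the normalized analysis can
  recover.
- *Schedule*: 0 (baseline), 0 (week 3), 0.6 (week 4), 0.9 (week 6),
  1.0 (week 9) — expression emerges at week 4 and is near-complete and
  stable from week 6, matching the disease model's course. Validation
  requires a zero baseline, monotone non-decreasing multipliers, and a
  final value of 1 unless the schedule is identically zero (the null
  schedule used for calibration studies).
- *Nuisance*: per-subject global scale N(0, 0.1) persisting across
  timepoints (cancelled by normalization, by design); i.i.d. voxel
  noise with SD 5 on a within-brain mean of 100 (5% — a realistic
  regional noise level for reconstructed small-animal FDG images);
  scanner-resolution blur of 1.35 mm FWHM applied after noise.
- *Motor scores*: cylinder-test-like percent impaired-forelimb use.
  Controls: 50 ± 6 (symmetric use); disease: 50 − 35·schedule(t) ± 6,
  clipped to [0, 100] — i.e. dropping to ≈ 15% at full expression,
  typical of strongly lesioned unilateral models. These are plausible
  placeholders, not values calibrated to any particular cohort.

What the phantom does **not** emulate: attenuation, scatter, Poisson
counting and reconstruction artefacts; anatomically realistic parcel
shapes; spatially structured physiological covariance beyond the single
planted pattern; and any **within-region** weight texture — the planted
truth is piecewise-constant, so within a parcel the derived weights vary
only by estimation noise. Passing tests therefore demonstrate recovery
of regional covariance structure and correct behaviour of the inference
machinery, not performance on real PET data; in particular, region-wise
voxel-weight correlations between the two derived patterns are low on
the phantom (noise-on-noise within parcels) even though the patterns
agree almost perfectly at the regional and whole-brain scale, whereas
real data with smooth within-region topography yields high region-wise
correlations.

## Regional summaries

Positive weighting of region r is 100 × Σ_{v∈r, p_v>0} p_v / Σ_v |p_v|
(and symmetrically for negative), so the positive and negative columns
share one scale and total 100% over a mask-covering atlas. The
denominator choice (whole-pattern |p| mass) is one of several defensible
readings of "relative to the whole brain pattern"; it is configurable in
principle but fixed here for comparability. Predominance: "+" when
pos ≥ ratio × neg, "−" when neg ≥ ratio × pos, "/" otherwise, with
ratio = 2.0 by default — chosen inside the bracket implied by published
tables of this kind (undecided entries sit near ratio ≈ 1.5, decided
ones beyond ≈ 2.5) and exposed as a parameter. Raising the ratio can
only turn a decided call into "/", never flip its sign (tested).

## Problem sizes used in the test suite

Solver-vs-QP comparisons use ≥ 50 random instances with N ≤ 30, K ≤ 10;
exact-Wilcoxon enumeration covers all group sizes ≤ 6; Gram-vs-direct
PCA uses D ≤ 50. The calibration study runs 200 null phantoms (zero
planted amplitude) at fixed hyperparameters C = 1, s = 1 — the
calibration property concerns the scoring/testing path, not
hyperparameter selection, and a fixed setting keeps 200 simulated
studies cheap — and 100 label permutations for the LOOCV null. The
fixed-seed integration checks use seed 0, the package's default demo
seed.
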