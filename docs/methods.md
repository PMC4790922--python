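# Methods

## The statistical problem

The package compares two groups of spatially normalized tissue-density
volumes (RAVENS-style mass-preserving maps: the voxel value integrates to
regional tissue volume, so a localized gray-matter loss appears as a local
density reduction) and asks where in the brain the groups differ.  The
motivating application is a randomized two-arm design — hormone therapy vs
placebo in older women — where the scientific claim is a localized
treatment-associated volume deficit.

Conventional voxel-based morphometry smooths every subject with a fixed
isotropic Gaussian kernel and runs a univariate test per voxel.  The fixed
kernel is a known liability: it blurs sharp effect boundaries (false
negatives at edges, false positives in halos).  The method implemented here
replaces the fixed kernel with a *learned, locally adaptive, non-negative
filter* per neighborhood, then aggregates filter weights into a whole-brain
statistic map that is tested nonparametrically.

## The discriminative map

**Neighborhoods.**  The analysis mask is covered by Euclidean balls of
radius `radius_mm` (default 2 mm = 2 voxels at desk scale) centered on a
stride lattice of in-mask voxels (default stride 1: one neighborhood per
voxel).  Construction fails loudly if any in-mask voxel is uncovered or any
ball contains fewer than two in-mask voxels.

**Per-neighborhood learning.**  For members of one neighborhood, with
subject data X (subjects × members) and class means m0 (placebo), m1
(treated), define

    S_b = (m0 − m1)(m0 − m1)',      rank-one between-class scatter
    S_w = Σ_c Σ_{s∈c} (x_s − m_c)(x_s − m_c)' / (n − 2),  pooled within-class

and maximize the Fisher-style difference criterion

    f(w) = w' S_b w − λ w' S_w w    over  {w ≥ 0, ‖w‖₂ = 1}.

λ defaults to the scale-free heuristic `trace(S_b)/trace(S_w)`, which
balances the two terms regardless of the data's units.  The non-negativity
constraint is what makes w an anisotropic *averaging* filter rather than an
arbitrary contrast: the projected value y = Xw is a weighted local mean, so
the neighborhood statistic remains interpretable as a local density
difference and the tallied map stays spatially faithful.

**Solver.**  The objective is an indefinite quadratic on the non-negative
unit sphere — non-convex, with stationary points on coordinate faces.  We
use projected gradient ascent (clip negatives, renormalize) with a
backtracking/growing step, run from three deterministic starts: the clipped
between-class direction `clip(±(m0−m1), 0)` (both signs) and the best
single coordinate `argmax_i f(e_i)`.  The best stationary point wins.  A
single fixed start (e.g. uniform) demonstrably stalls on inferior faces of
indefinite instances; the three-start scheme matches a refined dense-grid
brute force to better than 1e-3 on seeded low-dimensional instances (see
`tests/test_odvba.py` and `scripts/acceptance.py`).  Per accepted iteration
the objective is non-decreasing.  Degenerate cases are explicit: identical
class means (S_b = 0) skip the solve and score 0; a zero-variance projected
sample also scores 0.

**Neighborhood statistic and tally.**  Each neighborhood is scored by the
pooled-variance two-sample t of the projected values, signed so that the
hypothesized deficit ("treated < placebo" by default) is positive.  The
whole-brain map tallies

    φ_i = Σ_{k : i ∈ neighborhood k} w_{k,i} · s_k .

The per-neighborhood solve runs inside a numba kernel that applies S_w
through the class-centered data matrix (`w'S_w w = ‖Cw‖²/(n−2)`), keeping
the cost at O(subjects × members) per gradient step; the pure-numpy
reference solver is retained and cross-checked in tests.

## Inference

**Voxel p-values.**  Group labels are exchangeable under the null, so the
labels are permuted (group sizes preserved) and the *entire* map —
including every neighborhood's learned w — is recomputed per permutation.
Freezing the learned weights would condition the null on the observed
labeling and inflate error; a frozen fast path exists (`relearn=False`) but
is labeled approximate and used only in smoke tests.  The voxel p is the
add-one estimator p_i = (1 + #{φ*_i ≥ φ_i})/(n_perm + 1), implemented as
the rank of the observed value in the pooled set of observed + permuted
maps; ties count toward the null (conservative), and the smallest
achievable p is 1/(n_perm+1).  The pipeline default is 2,000 permutations.

**Cluster-wise FWE.**  The same pooled rank rule thresholds every permuted
map at the primary (cluster-forming) level — uncorrected p < 0.05 by
default, configurable — and the maximum suprathreshold cluster size
(26-connectivity by default) is recorded per permutation.  An observed
cluster of size N gets corrected_p = (1 + #{null max ≥ N})/(n_perm + 1).
Because observed and permuted maps are ranked by one exchangeable rule,
this correction is exactly calibrated; the acceptance suite verifies a
family-wise rate ≈ 0.03–0.05 on 100 null cohorts.

**Exhaustive mode.**  For tiny designs all C(n, n₁) assignments are
enumerated (the observed labeling is one of them) and p = #{≥}/count —
exactly the exhaustive permutation test, verified voxel-for-voxel against
independent enumeration.

## Nuisance-covariate removal

Before mapping, maps are corrected voxelwise for intracranial volume, age,
clinic site and time from randomization to scan by OLS on the pooled
cohort: continuous covariates centered at their sample means, sites coded
as k−1 indicators against the alphabetically first site.  Adjusted maps
are `residual + per-voxel cohort mean`, keeping them on the density scale;
negative adjusted values are not clipped by default so residuals stay
exactly orthogonal to the design (clipping is an explicit option; the
pipeline clips only the copies used for region-level density means).

The default fit contains **no group term**.  In a randomized design the
covariates are independent of assignment in expectation, but in any finite
sample the group contrast has leverage ρ² ≈ k/n on the nuisance span, and
the unprotected fit shrinks the group effect by exactly (1 − ρ²) while
removing covariate-imbalance bias.  Both facts are asserted in the tests.
A `protect=` option includes a centered group indicator in the fit (slopes
estimated adjusting for group, group effect not removed), which preserves
the effect unbiasedly.

## Baseline-balance statistics and site dispersion

Balance tables use the Pearson chi-square test of homogeneity, no
continuity correction, expected counts `row·col/grand`, p reported in
percent; missing values are excluded per variable (complete-case
denominators).  This convention reproduces the published multi-category
rows of the WHIMS-MRI characteristics table to the printed two decimals
(seven values checked to ±0.01).  The published 2×2 Diabetes row does not
match this (or any obvious) convention and is not asserted.  Single-
category variables report "not applicable" rather than a p-value.

Site dispersion follows the diagnostic used for multi-site harmonization:
the sample mean of whole-volume density per site, then IQR
(linear-interpolation quantiles), mean absolute deviation about the mean,
range, and sample SD (ddof = 1) across site means.  With planted site
offsets, all four measures drop essentially to the noise floor after
residualization.

## The synthetic cohort generator

Real trial imaging sits behind a data use agreement, so the generator is a
first-class module that emulates the *output* of the upstream pipeline
(registration/segmentation/RAVENS are out of scope).  Subject s, voxel v:

    x_s(v) = baseline(v) + Σ_c β_c (c_s − c_ref) + offset(site_s)
             + ε_s(v) − Δ·[s treated]·[v ∈ effect mask],   clipped at 0

* baseline: fixed template, 0.5 + low-frequency cosine ripples (smooth,
  brain-like heterogeneity without external templates);
* ε: white Gaussian noise convolved to FWHM 2 mm, rescaled to σ = 0.08
  density units (≈ the planted effect scale, giving per-voxel d ≈ 1 at the
  default Δ = 0.1);
* covariates: age ~ U(65, 80) y, ICV ~ N(1400, (0.10·1400)²), site uniform
  over 4 sites, time-to-scan ~ U(1.4, 3.0) y (the two trials' recruitment
  lags); slopes β default to {ICV: 2e-4, age: −4e-3, time: −1e-2} density
  units per covariate unit, applied to covariates centered at nominal
  values (72.5 y, 1400, 2.2 y) so defaults cannot push densities negative;
* site offsets: evenly spaced in ±0.03; sensitivity flags (low cognition,
  diabetes) Bernoulli(0.06) per subject, the order of the trial's excluded
  fractions;
* analysis mask: ellipsoid with semi-axes 0.42 × grid shape; default grid
  24³ at 1 mm with the mm origin at the grid center (so left/right is the
  sign of x);
* effect: Δ subtracted in the treated arm inside a 3-voxel-radius ball.

Everything planted is returned as ground truth, and detection is scored by
sensitivity, in-mask specificity and Dice.  A seeded region-growing atlas
(connected 6-neighbor wavefronts from random in-mask seeds) stands in for
an anatomical parcellation in region reports.

What the generator does *not* emulate: registration error, cortical
topology and folding, spatially varying noise, site-by-scanner interactions
beyond additive offsets, and covariate distributions beyond the documented
ranges.  Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the stated model, not that the method is
validated on real morphometry.

## Problem sizes and numerical choices

Study-condition sizes used by the test suite and `scripts/acceptance.py`,
chosen so a full run completes in minutes on one core:

* null calibration: 100 cohorts, 16³ grid, 15/group, 99 permutations;
* detection benchmark: 24³ grid, 20/group, Δ/σ = 1, 500 permutations,
  baseline = Gaussian smoothing at FWHM 4 mm (the neighborhood diameter)
  with the identical permutation scheme, both thresholded at uncorrected
  p < 0.05 and scored by Dice against the planted mask;
* solver oracle: 100 seeded scatter instances of dimension ≤ 4, refined
  dense-grid search (21 points/axis, 6 halving rounds).

Tolerances: solver convergence `tol = 1e-6` relative objective change,
`max_iter = 100`; feasibility asserted to 1e-9; scatter symmetry to 1e-8.
Ties in permutation ranks count toward the null.  Cluster ids are ordered
by size, ties broken by smallest flat voxel index.  All randomness flows
from explicit integer seeds via `numpy.random.default_rng`.

## Known limitations

* The detection benchmark's advantage over the smoothed-t baseline is a
  property of the default seeded scenario, not a theorem: at d ≈ 1 with 20
  subjects per arm both methods' Dice scores are noisy, and on some
  generator seeds the fixed-kernel baseline comes out ahead.  The benchmark
  is tracked as a fixed-seed regression test.
* Cluster-wise FWE at the liberal default cluster-forming threshold has
  limited power at desk scale: relearned permutation maps are spatially
  smooth, so null maximum clusters are large relative to a 100–200-voxel
  planted effect.  Trend-level (uncorrected) maps carry the detection
  benchmark; on full-size cohorts the corrected maps are the headline
  output.
* Coordinates are reported in the working template's mm frame; no
  Talairach/MNI conversion is embedded.
* The per-neighborhood λ heuristic is scale-free but not data-optimal; λ
  is exposed for cross-validation if desired.
* No mixed-effects site modeling; sites enter as fixed additive offsets.
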