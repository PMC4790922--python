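# odvbm — optimally-discriminative voxel-based morphometry

Whole-brain group comparison of tissue-density (RAVENS-style) maps for
neuroimaging trials, built around a spatially adaptive alternative to the
fixed Gaussian kernel of conventional VBM.  Written for analysts comparing
two randomized arms (the motivating design is hormone therapy vs placebo in
older women) who need voxel-level localization with honest nonparametric
error control.

## What it computes

For subjects-by-voxels data X with binary labels, every local neighborhood
(Euclidean ball on the analysis mask) learns a non-negative unit filter

    w* = argmax { w'S_b w − λ w'S_w w :  w ≥ 0, ‖w‖₂ = 1 },

with rank-one between-class scatter S_b = (m₀−m₁)(m₀−m₁)' and pooled
within-class scatter S_w, scores the neighborhood by the pooled two-sample
t of the projected values Xw*, and tallies a whole-brain statistic map

    φᵢ = Σ_{k ∋ i} w_{k,i} · s_k .

Significance is assigned by label permutation with full re-learning per
permutation (voxelwise p = (1 + #{φ* ≥ φ})/(n_perm + 1), 2,000 permutations
by default) and cluster-wise family-wise-error correction from the
permutation distribution of maximum suprathreshold cluster size.  Around
the core map the package provides:

* voxelwise nuisance regression (intracranial volume, age, clinic site,
  time-to-scan) with an optional protected group term;
* baseline-balance tables (Pearson chi-square homogeneity, p in percent)
  and multi-site dispersion diagnostics (IQR/MAD/range/SD of site means);
* atlas-partitioned region reports (region, side, center-of-mass mm
  coordinates, voxel count N, region-level t);
* a synthetic cohort generator with known ground truth (planted effect
  mask, covariate slopes, site offsets) and detection scoring
  (sensitivity/specificity/Dice), plus a conventional smoothed-t baseline
  for benchmarking;
* a `vbm` command-line pipeline (`simulate`, `adjust`, `odvba`, `infer`,
  `report`, `run`, `table1`, `dispersion`) writing NIfTI maps, CSV tables
  and a JSON run manifest.

Estimators follow scikit-learn conventions (`ODVBA(...).fit(X, y)` exposes
`stat_map_`; `NuisanceRegressor().fit(X, design).transform(X)`;
`PermutationTest(est, scheme).fit(X, y)` exposes `p_map_`, `clusters_`).

## Worked example

```python
import numpy as np
from odvbm import (SynthConfig, generate_cohort, stack_cohort,
                   ODVBA, PermutationTest, PermutationScheme,
                   threshold_map, score_detection)
from odvbm.grid import GridGeometry

cfg = SynthConfig(grid=GridGeometry.centered((24, 24, 24)),
                  n_per_group=20, effect_size=0.08, noise_sigma=0.08, seed=1)
cohort, truth = generate_cohort(cfg)
maps = [r.volume for r in cohort]
y = np.array([r.covariates.group for r in cohort])

test = PermutationTest(
    ODVBA(mask=maps[0].mask, grid=cfg.grid),
    PermutationScheme(n_perm=500, seed=2),
).fit(stack_cohort(maps), y)

det = threshold_map(test.p_map_, 0.05)
print("trend voxels:", int(det.sum()))
print("dice vs truth:", round(score_detection(det, truth, maps[0].mask).dice, 3))
```

prints

```
trend voxels: 131
dice vs truth: 0.761
```

i.e. at the uncorrected p < 0.05 threshold the adaptive map recovers the
planted 123-voxel deficit with Dice 0.76 (the fixed-kernel smoothed-t
comparison on the same data and permutation scheme reaches 0.63).  The same
cohort run through the full CLI pipeline
(`vbm run --n-per-group 20 --effect-size 0.08 --seed 1 --out out/`) adds
covariate adjustment, cluster-FWE correction and the per-region report.

Scientific details — the model and its assumptions, solver, calibration
properties, what the generator does and does not emulate — are in
`docs/methods.md`.

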