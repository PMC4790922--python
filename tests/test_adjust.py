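"""Voxelwise nuisance regression: design, fit, residualization."""

import numpy as np
import pandas as pd
import pytest

from odvbm.adjust import NuisanceRegressor, build_design, fit_nuisance, residualize
from odvbm.cohort_stats import site_dispersion
from odvbm.grid import GridGeometry, stack_cohort
from odvbm.synthetic import SynthConfig, cohort_to_frame, generate_cohort


def _frame(n, n_sites=1, seed=0):
    rng = np.random.default_rng(seed)
    sites = [f"S{i % n_sites + 1:02d}" for i in range(n)]
    return pd.DataFrame(
        {
            "icv": rng.normal(1400, 100, n),
            "age": rng.uniform(65, 80, n),
            "time_to_scan": rng.uniform(1.4, 3.0, n),
            "site": sites,
        }
    )


class TestBuildDesign:
    def test_single_site_no_site_columns(self):
        d = build_design(_frame(12, n_sites=1))
        assert d.columns == ["intercept", "icv", "age", "time_to_scan"]

    def test_three_sites_two_indicators(self):
        d = build_design(_frame(18, n_sites=3))
        assert sum(c.startswith("site[") for c in d.columns) == 2

    def test_continuous_columns_centered(self):
        d = build_design(_frame(20, n_sites=2))
        for name in ("icv", "age", "time_to_scan"):
            j = d.columns.index(name)
            assert d.values[:, j].sum() == pytest.approx(0.0, abs=1e-9)

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError, match="subjects"):
            build_design(_frame(4, n_sites=1))

    def test_collinear_design_raises(self):
        f = _frame(15, n_sites=2, seed=1)
        f["age"] = f["icv"]  # exact collinearity
        with pytest.raises(ValueError, match="degenerate|collinear"):
            build_design(f)


class TestFitAndResidualize:
    def test_constant_voxel_gives_zero_slopes(self):
        f = _frame(15, n_sites=2)
        d = build_design(f)
        X = np.full((15, 4), 0.7)
        model = fit_nuisance(X, d)
        nuis = [i for i, c in enumerate(d.columns) if c != "intercept"]
        assert np.allclose(model.coef_[nuis], 0.0, atol=1e-10)
        assert np.allclose(model.grand_mean_, 0.7)

    def test_exact_linear_age_recovered(self):
        f = _frame(20, n_sites=1)
        d = build_design(f)
        j = d.columns.index("age")
        X = 0.5 + 0.01 * d.values[:, [j]]  # exactly linear in centered age
        model = fit_nuisance(X, d)
        assert model.coef_[j, 0] == pytest.approx(0.01, abs=1e-12)

    def test_zero_slope_model_is_identity(self):
        f = _frame(12, n_sites=1)
        d = build_design(f)
        rng = np.random.default_rng(3)
        X = rng.uniform(0.3, 0.7, (12, 5))
        model = NuisanceRegressor()
        model.design_ = d
        model.coef_ = np.zeros((len(d.columns), X.shape[1]))
        model.grand_mean_ = X.mean(axis=0)
        assert np.allclose(residualize(X, model), X, atol=1e-12)

    def test_residuals_orthogonal_to_design(self):
        f = _frame(25, n_sites=3, seed=2)
        d = build_design(f)
        rng = np.random.default_rng(4)
        X = 0.5 + 0.1 * rng.standard_normal((25, 30))
        adj = residualize(X, fit_nuisance(X, d))
        centered = adj - adj.mean(axis=0)
        for j, c in enumerate(d.columns):
            if c == "intercept":
                continue
            z = d.values[:, j] - d.values[:, j].mean()
            assert np.max(np.abs(z @ centered)) < 1e-8

    def test_idempotence_after_refit(self):
        f = _frame(30, n_sites=2, seed=5)
        d = build_design(f)
        rng = np.random.default_rng(6)
        X = 0.5 + 0.05 * rng.standard_normal((30, 20))
        once = residualize(X, fit_nuisance(X, d))
        twice = residualize(once, fit_nuisance(once, d))
        assert np.allclose(twice, once, atol=1e-10)

    def test_underdetermined_raises(self):
        f = _frame(12, n_sites=2)
        d = build_design(f)
        with pytest.raises(ValueError, match="align|underdetermined"):
            fit_nuisance(np.ones((3, 4)), d)


class TestOnSyntheticCohort:
    def _fit_on_cohort(self, cfg):
        cohort, truth = generate_cohort(cfg)
        frame = cohort_to_frame(cohort)
        X = stack_cohort([r.volume for r in cohort])
        design = build_design(frame)
        return cohort, truth, frame, X, design

    def test_planted_slope_recovery_within_3se(self):
        """OLS recovers the generator's covariate slopes and site offsets."""
        cfg = SynthConfig(
            grid=GridGeometry.centered((10, 10, 10)),
            n_per_group=30, effect_size=0.0, noise_sigma=0.02,
            n_sites=3, seed=21,
        )
        cohort, truth, frame, X, design = self._fit_on_cohort(cfg)
        model = fit_nuisance(X, design)
        Z = design.values
        # per-column standard errors from the design and residual variance
        XtXinv = np.linalg.inv(Z.T @ Z)
        resid = X - Z @ np.linalg.lstsq(Z, X, rcond=None)[0]
        s2 = (resid**2).sum(axis=0) / (Z.shape[0] - Z.shape[1])
        for name, true_val in [
            ("icv", truth.covariate_effects["icv"]),
            ("age", truth.covariate_effects["age"]),
            ("time_to_scan", truth.covariate_effects["time_to_scan"]),
        ]:
            j = design.columns.index(name)
            se = np.sqrt(XtXinv[j, j] * s2)
            est = model.coef_[j]
            frac_in = np.mean(np.abs(est - true_val) <= 3 * se)
            assert frac_in > 0.95, f"{name}: {frac_in:.2f} of voxels within 3 SE"
        # site offsets: indicator coefficients estimate offset differences
        sites = sorted(truth.site_offsets)
        for s in sites[1:]:
            j = design.columns.index(f"site[{s}]")
            true_delta = truth.site_offsets[s] - truth.site_offsets[sites[0]]
            se = np.sqrt(XtXinv[j, j] * s2)
            frac_in = np.mean(np.abs(model.coef_[j] - true_delta) <= 3 * se)
            assert frac_in > 0.95

    def test_site_dispersion_strictly_reduced(self):
        cfg = SynthConfig(
            grid=GridGeometry.centered((10, 10, 10)),
            n_per_group=25, effect_size=0.0, noise_sigma=0.02,
            n_sites=4, seed=22,
        )
        cohort, truth, frame, X, design = self._fit_on_cohort(cfg)
        Xa = residualize(X, fit_nuisance(X, design))
        before = site_dispersion(X.mean(axis=1), frame.site.to_numpy())
        after = site_dispersion(Xa.mean(axis=1), frame.site.to_numpy())
        for k in ("iqr", "mad", "range", "std"):
            assert after.as_dict()[k] < before.as_dict()[k]

    def test_group_difference_preserved(self):
        """Residualization removes covariate-imbalance bias but keeps the
        planted group effect.  The default (no group term) fit shrinks the
        effect by exactly the group contrast's leverage on the nuisance
        span, 1 - rho^2; the protected fit preserves it unbiasedly."""
        cfg = SynthConfig(
            grid=GridGeometry.centered((10, 10, 10)),
            n_per_group=40, effect_size=0.15, noise_sigma=0.05,
            n_sites=3, seed=23,
        )
        cohort, truth, frame, X, design = self._fit_on_cohort(cfg)
        y = frame.group.to_numpy()
        mask = cohort[0].volume.mask
        em = truth.effect_mask[mask]
        n = cfg.n_per_group

        def gap_and_se(M):
            ball = M[:, em].mean(axis=1)  # per-subject mean over effect region
            g0, g1 = ball[y == 0], ball[y == 1]
            se = np.sqrt(g0.var(ddof=1) / n + g1.var(ddof=1) / n)
            return g0.mean() - g1.mean(), se

        Z = design.values
        a = np.where(y == 0, 1.0 / n, -1.0 / n)
        Ha = Z @ np.linalg.solve(Z.T @ Z, Z.T @ a)
        rho2 = (Ha @ Ha) / (a @ a)

        gap_def, se_def = gap_and_se(residualize(X, fit_nuisance(X, design)))
        assert abs(gap_def - (1 - rho2) * cfg.effect_size) < 3 * se_def

        gap_prot, se_prot = gap_and_se(
            residualize(X, fit_nuisance(X, design, protect=y))
        )
        assert abs(gap_prot - cfg.effect_size) < 3 * se_prot
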