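"""Discriminative core: neighborhoods, scatter, NDP solver, tally, full map."""

import numpy as np
import pytest

from odvbm.grid import GridGeometry, stack_cohort, unstack_values
from odvbm.odvba import (
    ODVBA,
    OdvbaParams,
    ScatterPair,
    build_neighborhoods,
    neighborhood_statistic,
    odvba_map,
    scatter_matrices,
    solve_ndp,
    tally_map,
)
from odvbm.synthetic import SynthConfig, generate_cohort


def grid_max_quadratic(A: np.ndarray, n: int = 21, rounds: int = 6) -> float:
    """Brute-force oracle: max of w' A w over {w >= 0, ||w|| = 1} by a dense
    grid on the non-negative orthant, refined around the incumbent."""
    d = A.shape[0]
    lo, hi = np.zeros(d), np.ones(d)
    best, best_w = -np.inf, None
    for r in range(rounds):
        axes = [np.linspace(lo[i], hi[i], n) for i in range(d)]
        W = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, d)
        nrm = np.linalg.norm(W, axis=1)
        W = W[nrm > 1e-12] / nrm[nrm > 1e-12, None]
        vals = np.einsum("ij,jk,ik->i", W, A, W)
        i = int(np.argmax(vals))
        if vals[i] > best:
            best, best_w = float(vals[i]), W[i]
        width = 0.5 ** (r + 1)
        lo = np.clip(best_w - width, 0, 1)
        hi = np.clip(best_w + width, 0, 1)
    return best


class TestBuildNeighborhoods:
    def _params(self, **kw):
        return OdvbaParams(**kw)

    def test_degenerate_radius_raises(self):
        grid = GridGeometry.centered((5, 5, 5))
        mask = np.ones(grid.shape, bool)
        with pytest.raises(ValueError, match="coverage"):
            build_neighborhoods(mask, grid, self._params(radius_mm=0.5))

    def test_stride_one_gives_one_per_voxel(self):
        grid = GridGeometry.centered((5, 5, 5))
        mask = np.ones(grid.shape, bool)
        nbs = build_neighborhoods(mask, grid, self._params(radius_mm=1.0))
        assert len(nbs) == mask.sum()

    def test_face_ball_member_count(self):
        """radius = 1 voxel -> interior neighborhoods are 7-member 6-face balls."""
        grid = GridGeometry.centered((5, 5, 5))
        mask = np.ones(grid.shape, bool)
        nbs = build_neighborhoods(mask, grid, self._params(radius_mm=1.0))
        by_center = {nb.center: nb for nb in nbs}
        assert len(by_center[(2, 2, 2)].members) == 7
        assert by_center[(2, 2, 2)].center == tuple(by_center[(2, 2, 2)].members[0])

    def test_every_voxel_covered_and_center_in_members(self):
        grid = GridGeometry.centered((8, 8, 8))
        rng = np.random.default_rng(0)
        mask = rng.random(grid.shape) < 0.7
        mask[4, 4, 4] = True
        nbs = build_neighborhoods(mask, grid, self._params(radius_mm=2.0))
        covered = set()
        for nb in nbs:
            assert tuple(nb.members[0]) == nb.center
            covered.update(map(tuple, nb.members))
        assert covered == set(map(tuple, np.argwhere(mask)))

    def test_excessive_stride_raises(self):
        grid = GridGeometry.centered((9, 9, 9))
        mask = np.ones(grid.shape, bool)
        with pytest.raises(ValueError, match="coverage"):
            build_neighborhoods(mask, grid, self._params(radius_mm=1.0, stride=4))


class TestScatterMatrices:
    def test_identical_class_means_zero_Sb(self):
        X = np.array([[1.0, 2.0], [3.0, 0.0], [1.0, 2.0], [3.0, 0.0]])
        sc = scatter_matrices(X, [0, 0, 1, 1])
        assert np.allclose(sc.S_b, 0)

    def test_all_identical_zero_both(self):
        X = np.ones((6, 3))
        sc = scatter_matrices(X, [0, 0, 0, 1, 1, 1])
        assert np.allclose(sc.S_b, 0) and np.allclose(sc.S_w, 0)

    def test_hand_computed_two_members(self):
        X = np.array([[1.0, 0.0], [3.0, 2.0], [5.0, 1.0], [7.0, 3.0]])
        y = [0, 0, 1, 1]
        sc = scatter_matrices(X, y)
        d = np.array([2.0 - 6.0, 1.0 - 2.0])
        assert np.allclose(sc.S_b, np.outer(d, d))
        # centered rows all (+-1, +-1): S_w = [[4,4],[4,4]]/2
        assert np.allclose(sc.S_w, np.array([[2.0, 2.0], [2.0, 2.0]]))

    def test_small_class_raises(self):
        with pytest.raises(ValueError, match="class"):
            scatter_matrices(np.ones((3, 2)), [0, 1, 1])

    def test_psd_and_rank_one(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((12, 4))
        sc = scatter_matrices(X, [0] * 6 + [1] * 6)
        assert np.linalg.matrix_rank(sc.S_b, tol=1e-10) <= 1
        assert np.linalg.eigvalsh(sc.S_w).min() > -1e-10


class TestSolveNDP:
    def _solve(self, S_b, S_w, lam):
        return solve_ndp(ScatterPair(S_b=S_b, S_w=S_w), OdvbaParams(lam=lam))

    def test_dominant_axis(self):
        res = self._solve(np.diag([2.0, 1.0]), np.zeros((2, 2)), 0.0)
        assert res.objective == pytest.approx(2.0, abs=1e-6)
        assert np.allclose(res.weights, [1.0, 0.0], atol=1e-3)

    def test_isotropic_objective(self):
        res = self._solve(np.eye(3), np.zeros((3, 3)), 0.0)
        assert res.objective == pytest.approx(1.0, abs=1e-9)

    def test_feasibility_and_monotonicity(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m = rng.integers(2, 5)
            X = rng.standard_normal((10, m))
            sc = scatter_matrices(X, [0] * 5 + [1] * 5)
            res = solve_ndp(sc, OdvbaParams())
            assert (res.weights >= 0).all()
            assert np.linalg.norm(res.weights) == pytest.approx(1.0, abs=1e-9)

    def test_non_symmetric_raises(self):
        with pytest.raises(ValueError, match="symmetric"):
            ScatterPair(S_b=np.array([[1.0, 2.0], [0.0, 1.0]]), S_w=np.eye(2))

    def test_identical_means_degenerate_uniform(self):
        res = self._solve(np.zeros((3, 3)), np.eye(3), 1.0)
        assert res.degenerate
        assert np.allclose(res.weights, 1 / np.sqrt(3))

    def test_objective_matches_brute_force_oracle(self):
        """Seeded random scatter instances: solver objective within 1e-3 of a
        refined dense-grid search over the non-negative unit sphere."""
        rng = np.random.default_rng(123)
        worst = 0.0
        for _ in range(100):
            m = int(rng.integers(2, 5))
            X = rng.standard_normal((8, m))
            sc = scatter_matrices(X, [0] * 4 + [1] * 4)
            lam = float(np.trace(sc.S_b) / max(np.trace(sc.S_w), 1e-12))
            res = solve_ndp(sc, OdvbaParams(lam=lam))
            oracle = grid_max_quadratic(sc.S_b - lam * sc.S_w)
            worst = max(worst, abs(res.objective - oracle))
        assert worst < 1e-3


class TestNeighborhoodStatistic:
    def test_identical_projections_zero(self):
        X = np.ones((6, 2))
        assert neighborhood_statistic(X, [0, 0, 0, 1, 1, 1], [1, 0]) == 0.0

    def test_degenerate_zero_variance_maps_to_zero(self):
        y = [0, 0, 0, 1, 1, 1]
        X = np.array(y, float)[:, None] * np.ones((1, 2))
        assert neighborhood_statistic(X, y, [1.0, 0.0]) == 0.0

    def test_hand_computed_pooled_t(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 6.0, 8.0]
        X = np.array([[v, 0.0] for v in a + b])
        y = [0, 0, 0, 1, 1, 1]
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t_hand = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert neighborhood_statistic(X, y, [1.0, 0.0]) == pytest.approx(t_hand)
        assert neighborhood_statistic(X, y, [1.0, 0.0], direction="greater") == pytest.approx(-t_hand)


class TestTally:
    def _line_fixture(self):
        grid = GridGeometry.centered((4, 1, 1))
        mask = np.ones(grid.shape, bool)
        return grid, mask

    def test_single_neighborhood_one_term(self):
        from odvbm.odvba import NDPResult, Neighborhood

        grid, mask = self._line_fixture()
        nb = Neighborhood(
            center=(0, 0, 0),
            members=np.array([[0, 0, 0], [1, 0, 0]]),
            member_cols=np.array([0, 1]),
        )
        res = NDPResult(weights=np.array([0.6, 0.8]), statistic=2.0,
                        objective=0.0, converged=True, iterations=1)
        sm = tally_map([nb], [res], grid, mask)
        assert sm.phi[0, 0, 0] == pytest.approx(1.2)
        assert sm.phi[1, 0, 0] == pytest.approx(1.6)

    def test_overlapping_neighborhoods_sum(self):
        from odvbm.odvba import NDPResult, Neighborhood

        grid, mask = self._line_fixture()
        nbs = [
            Neighborhood(center=(0, 0, 0), members=np.array([[0, 0, 0], [1, 0, 0]]),
                         member_cols=np.array([0, 1])),
            Neighborhood(center=(1, 0, 0), members=np.array([[1, 0, 0], [2, 0, 0]]),
                         member_cols=np.array([1, 2])),
        ]
        results = [
            NDPResult(weights=np.array([0.6, 0.8]), statistic=2.0,
                      objective=0.0, converged=True, iterations=1),
            NDPResult(weights=np.array([1.0, 0.0]), statistic=3.0,
                      objective=0.0, converged=True, iterations=1),
        ]
        sm = tally_map(nbs, results, grid, mask)
        assert sm.phi[1, 0, 0] == pytest.approx(0.8 * 2.0 + 1.0 * 3.0)

    def test_zero_statistics_zero_map(self):
        from odvbm.odvba import NDPResult, Neighborhood

        grid, mask = self._line_fixture()
        nb = Neighborhood(center=(0, 0, 0), members=np.array([[0, 0, 0], [1, 0, 0]]),
                          member_cols=np.array([0, 1]))
        res = NDPResult(weights=np.array([0.6, 0.8]), statistic=0.0,
                        objective=0.0, converged=True, iterations=1)
        assert np.allclose(tally_map([nb], [res], grid, mask).phi, 0.0)

    def test_length_mismatch_raises(self):
        grid, mask = self._line_fixture()
        with pytest.raises(ValueError, match="one NDPResult"):
            tally_map([], [None], grid, mask)


class TestOdvbaMap:
    def test_identical_groups_zero_map(self):
        grid = GridGeometry.centered((8, 8, 8))
        cfg = SynthConfig(grid=grid, n_per_group=3, effect_size=0.0,
                          noise_sigma=0.0, covariate_effects={},
                          site_offsets={"S01": 0.0}, n_sites=1, seed=0)
        cohort, _ = generate_cohort(cfg)
        maps = [r.volume for r in cohort]
        y = [r.covariates.group for r in cohort]
        sm = odvba_map(maps, y)
        assert np.allclose(sm.phi, 0.0)

    def test_deterministic(self, tiny_cohort, labels_of):
        _, cohort, _ = tiny_cohort
        maps = [r.volume for r in cohort]
        y = labels_of(cohort)
        a = odvba_map(maps, y)
        b = odvba_map(maps, y)
        assert np.array_equal(a.phi, b.phi)

    def test_planted_effect_elevates_phi_inside_mask(self, tiny_cohort, labels_of):
        _, cohort, truth = tiny_cohort
        maps = [r.volume for r in cohort]
        sm = odvba_map(maps, labels_of(cohort))
        mask = maps[0].mask
        inside = sm.phi[truth.effect_mask & mask].mean()
        outside = sm.phi[mask & ~truth.effect_mask].mean()
        assert inside > outside

    def test_kernel_matches_reference_solver(self, tiny_cohort, labels_of):
        """The compiled map equals the tally of per-neighborhood reference
        solves (same algorithm, numpy path) to solver tolerance."""
        _, cohort, _ = tiny_cohort
        maps = [r.volume for r in cohort]
        y = labels_of(cohort)
        X = stack_cohort(maps)
        grid, mask = maps[0].grid, maps[0].mask
        params = OdvbaParams()
        est = ODVBA(mask=mask, grid=grid).fit(X, y)
        nbs = est.neighborhoods_
        from odvbm.odvba import NDPResult

        results = []
        for nb in nbs:
            sc = scatter_matrices(X[:, nb.member_cols], y)
            r = solve_ndp(sc, params)
            s = (
                0.0
                if r.degenerate
                else neighborhood_statistic(X[:, nb.member_cols], y, r.weights)
            )
            results.append(NDPResult(weights=r.weights, statistic=s,
                                     objective=r.objective, converged=r.converged,
                                     iterations=r.iterations))
        ref = tally_map(nbs, results, grid, mask)
        # both paths find stationary points of the same objective; phi agrees
        # closely wherever weights are identifiable
        corr = np.corrcoef(ref.phi[mask], est.stat_map_.phi[mask])[0, 1]
        assert corr > 0.999
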