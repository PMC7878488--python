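import numpy as np
import pytest

from grazecap import kriging
from grazecap.grid import GridSpec
from grazecap.kriging import Semivariogram


class TestEmpiricalSemivariogram:
    def test_constant_field_has_zero_semivariance(self, rng):
        pts = rng.uniform(0, 50, (30, 2))
        lags, gammas, counts = kriging.empirical_semivariogram(pts, np.full(30, 3.3), 5.0, 60.0)
        assert np.all(gammas == 0.0)
        assert counts.sum() == 30 * 29 // 2

    def test_two_point_hand_computation(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0]])
        lags, gammas, counts = kriging.empirical_semivariogram(pts, np.array([0.0, 2.0]), 5.0, 10.0)
        assert len(lags) == 1
        assert gammas[0] == pytest.approx(2.0)  # 0.5 * (2-0)^2
        assert counts[0] == 1

    def test_matches_brute_force_pair_enumeration(self, rng):
        pts = rng.uniform(0, 40, (20, 2))
        vals = rng.normal(size=20)
        lag_width, max_lag = 6.0, 42.0
        lags, gammas, counts = kriging.empirical_semivariogram(pts, vals, lag_width, max_lag)
        # O(n^2) oracle
        sums = {}
        for i in range(20):
            for j in range(i + 1, 20):
                h = float(np.hypot(*(pts[i] - pts[j])))
                if h > max_lag:
                    continue
                b = int(h // lag_width)
                s, n = sums.get(b, (0.0, 0))
                sums[b] = (s + 0.5 * (vals[i] - vals[j]) ** 2, n + 1)
        expected = {b: s / n for b, (s, n) in sums.items()}
        got = {int(l // lag_width): g for l, g in zip(lags, gammas)}
        assert set(got) == set(expected)
        for b in expected:
            assert got[b] == pytest.approx(expected[b], rel=1e-12)

    def test_coincident_points_rejected(self):
        pts = np.zeros((5, 2))
        with pytest.raises(ValueError, match="coincident"):
            kriging.empirical_semivariogram(pts, np.arange(5.0), 1.0, 5.0)


class TestFitSemivariogram:
    def test_recovers_exact_spherical_parameters(self):
        true = Semivariogram("spherical", nugget=0.0, sill=1.0, range_km=10.0)
        lags = np.linspace(0.5, 15.0, 25)
        fitted, diag = kriging.fit_semivariogram(lags, true(lags), np.full(25, 100), "spherical")
        assert fitted.nugget == pytest.approx(0.0, abs=1e-3)
        assert fitted.sill == pytest.approx(1.0, abs=1e-3)
        assert fitted.range_km == pytest.approx(10.0, abs=1e-2)
        assert not diag["pure_nugget"]

    def test_white_noise_flagged_as_pure_nugget(self, rng):
        pts = rng.uniform(0, 100, (200, 2))
        vals = rng.normal(0, 2.0, 200)
        lags, gammas, counts = kriging.empirical_semivariogram(pts, vals, 10.0, 80.0)
        fitted, diag = kriging.fit_semivariogram(lags, gammas, counts)
        assert fitted.sill == pytest.approx(4.0, rel=0.3)  # ~ sample variance
        assert diag["pure_nugget"] or fitted.nugget / fitted.sill > 0.8

    @pytest.mark.parametrize("model", ["spherical", "exponential", "gaussian"])
    def test_fitted_model_is_nondecreasing(self, model):
        sv = Semivariogram(model, nugget=0.2, sill=1.5, range_km=12.0)
        h = np.linspace(0.01, 40.0, 500)
        assert np.all(np.diff(sv(h)) >= -1e-12)
        assert sv(np.array([1e9]))[0] == pytest.approx(1.5, rel=1e-6)


class TestKrige:
    def grid(self):
        return GridSpec(xmin=0.0, ymax=20.0, cell_size=5.0, nrows=4, ncols=4)

    def test_single_point_predicts_its_value_everywhere(self):
        sv = Semivariogram("spherical", 0.0, 1.0, 10.0)
        res = kriging.krige(np.array([[10.0, 10.0]]), np.array([4.2]), sv, self.grid())
        assert np.all(res.prediction.values == 4.2)

    def test_exact_interpolation_at_data_points_with_zero_nugget(self, rng):
        sv = Semivariogram("spherical", 0.0, 2.0, 15.0)
        grid = self.grid()
        X, Y = grid.center_mesh()
        # data located exactly at some cell centres
        idx = [(0, 0), (1, 2), (3, 3), (2, 1)]
        pts = np.array([[X[r, c], Y[r, c]] for r, c in idx])
        vals = rng.uniform(0.5, 3.0, len(pts))
        res = kriging.krige(pts, vals, sv, grid)
        for (r, c), v in zip(idx, vals):
            assert res.prediction.values[r, c] == pytest.approx(v, abs=1e-8)
            assert res.variance.values[r, c] == pytest.approx(0.0, abs=1e-8)

    def test_weights_match_dense_variogram_form_solve(self):
        """Moving-neighbourhood covariance-form weights equal those of the
        directly assembled variogram-form augmented system."""
        sv = Semivariogram("spherical", 0.1, 1.5, 12.0)
        pts = np.array([[0.0, 0.0], [8.0, 1.0], [3.0, 7.0]])
        vals = np.array([1.0, 2.0, 0.5])
        target = np.array([4.0, 3.0])
        lam, pred, var = kriging._ok_weights(pts, vals, target, sv)
        # oracle: gamma-form system [[Gamma, 1],[1,0]] [lam, -mu] = [gamma0, 1]
        n = 3
        A = np.zeros((n + 1, n + 1))
        for i in range(n):
            for j in range(n):
                A[i, j] = sv(np.array([np.hypot(*(pts[i] - pts[j]))]))[0]
            A[i, n] = 1.0
            A[n, i] = 1.0
        b = np.append([sv(np.array([np.hypot(*(pts[i] - target))]))[0] for i in range(n)], 1.0)
        sol = np.linalg.solve(A, b)
        np.testing.assert_allclose(lam, sol[:3], atol=1e-10)
        assert pred == pytest.approx(float(sol[:3] @ vals), abs=1e-10)
        # gamma-form variance: sum lam_i gamma0_i + mu
        assert var == pytest.approx(float(sol[:3] @ b[:3] + sol[3]), abs=1e-10)
        assert lam.sum() == pytest.approx(1.0, abs=1e-12)

    def test_variance_nonnegative_and_negative_predictions_clamped(self, rng):
        sv = Semivariogram("exponential", 0.05, 1.0, 8.0)
        pts = rng.uniform(0, 20, (40, 2))
        vals = rng.normal(0.1, 1.0, 40)  # negative values force clamping somewhere
        res = kriging.krige(pts, vals, sv, self.grid())
        assert np.all(res.variance.values >= 0.0)
        assert np.all(res.prediction.values >= 0.0)
        assert res.n_clamped >= 0

    def test_denser_sampling_reduces_recovery_error(self, rng):
        """Kriging a smooth surface from a denser sample must not be worse."""
        grid = GridSpec(xmin=0.0, ymax=40.0, cell_size=5.0, nrows=8, ncols=8)

        def surface(x, y):
            return 2.0 + np.sin(x / 12.0) + np.cos(y / 15.0)

        sv = Semivariogram("gaussian", 1e-4, 1.0, 25.0)
        rmses = []
        for n in (25, 120):
            pts = rng.uniform(0, 40, (n, 2))
            vals = surface(pts[:, 0], pts[:, 1])
            res = kriging.krige(pts, vals, sv, grid, clamp_negative=False)
            X, Y = grid.center_mesh()
            rmses.append(float(np.sqrt(np.mean((res.prediction.values - surface(X, Y)) ** 2))))
        assert rmses[1] < rmses[0]


class TestCrossValidate:
    def test_constant_field_has_zero_rmse(self, rng):
        pts = rng.uniform(0, 30, (12, 2))
        sv = Semivariogram("spherical", 0.0, 1.0, 10.0)
        cv = kriging.cross_validate(pts, np.full(12, 5.0), sv)
        assert cv["rmse"] == pytest.approx(0.0, abs=1e-9)

    def test_white_noise_rmse_near_noise_sd_and_unbiased(self, rng):
        pts = rng.uniform(0, 100, (200, 2))
        sigma = 1.5
        vals = rng.normal(0.0, sigma, 200)
        sv = Semivariogram("spherical", sigma**2, sigma**2 + 1e-9, 10.0)  # pure nugget
        cv = kriging.cross_validate(pts, vals, sv)
        assert cv["rmse"] == pytest.approx(sigma, rel=0.15)
        se = cv["rmse"] / np.sqrt(200)
        assert abs(cv["mean_error"]) < 3 * se
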