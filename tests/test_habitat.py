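import numpy as np
import pytest
from scipy.stats import spearmanr

from grazecap import habitat, synthetic
from grazecap.grid import GridSpec, Raster


class TestBuildFeatures:
    def test_one_covariate_gives_linear_and_quadratic(self, small_grid, rng):
        covs = {"elev": Raster(small_grid, rng.normal(4500, 100, (4, 4)))}
        fs = habitat.build_features(covs)
        assert fs.names == ["elev", "elev^2"]
        np.testing.assert_allclose(fs.matrix.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(fs.matrix.std(axis=0), 1.0, atol=1e-12)

    def test_aspect_encoded_circularly(self, small_grid, rng):
        covs = {"aspect": Raster(small_grid, rng.uniform(0, 360, (4, 4)))}
        fs = habitat.build_features(covs)
        assert fs.names == ["aspect_sin", "aspect_cos"]
        assert np.all(np.abs(fs.matrix) <= np.abs(fs.matrix).max() + 1e-15)

    def test_restandardization_is_idempotent(self, small_grid, rng):
        covs = {"elev": Raster(small_grid, rng.normal(0, 1, (4, 4)))}
        fs = habitat.build_features(covs)
        again = (fs.matrix - fs.matrix.mean(axis=0)) / fs.matrix.std(axis=0)
        np.testing.assert_allclose(again, fs.matrix, atol=1e-12)

    def test_constant_covariate_dropped_with_warning(self, small_grid, rng):
        covs = {
            "flat": Raster(small_grid, np.full((4, 4), 2.0)),
            "elev": Raster(small_grid, rng.normal(0, 1, (4, 4))),
        }
        with pytest.warns(UserWarning, match="constant"):
            fs = habitat.build_features(covs)
        assert fs.names == ["elev", "elev^2"]


class TestFitMaxent:
    def four_cell_grid(self):
        return GridSpec(xmin=0.0, ymax=10.0, cell_size=5.0, nrows=2, ncols=2)

    def test_zero_coefficients_give_uniform_distribution(self):
        F = np.array([[1.0], [1.0], [0.0], [0.0]])
        model = habitat.fit_maxent(np.array([0, 2]), F, beta=1e9, grid=self.four_cell_grid())
        # enormous L1 weight shrinks the coefficient to 0 -> uniform Gibbs law
        assert model.coef[0] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(model.raw_probabilities(), 0.25, atol=1e-12)

    def test_moment_matching_on_four_cell_fixture(self):
        """At beta=0 the fitted expectation of a binary feature equals the
        presence mean; a coefficient-grid search cannot beat the solution."""
        F = np.array([[1.0], [1.0], [0.0], [0.0]])
        model = habitat.fit_maxent(np.array([0, 1]), F, beta=0.0, grid=self.four_cell_grid())
        p = model.raw_probabilities()
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert float(p @ F[:, 0]) == pytest.approx(1.0, abs=1e-6)
        # brute-force oracle over a coefficient grid
        fbar = 1.0
        ws = np.linspace(-10.0, 60.0, 7001)
        objs = ws * fbar - np.logaddexp(np.log(2.0) + ws, np.log(2.0))
        achieved = float(model.coef[0] * fbar - np.logaddexp(np.log(2.0) + model.coef[0], np.log(2.0)))
        assert achieved >= objs.max() - 1e-9

    def test_objective_trace_monotone_and_normalized(self, default_county):
        fs = habitat.build_features(default_county.covariates)
        rng = np.random.default_rng(4)
        presence = rng.integers(0, fs.matrix.shape[0], 120)
        model = habitat.fit_maxent(presence, fs, beta=0.5)
        trace = np.array(model.objective_trace)
        assert np.all(np.diff(trace) >= -1e-10)
        assert model.max_normalization_error < 1e-9

    def test_recovers_known_logistic_suitability_ranking(self, default_county):
        """Presences sampled from a known logistic suitability: the fitted
        suitability must rank cells consistently with the truth."""
        fs = habitat.build_features(default_county.covariates)
        for i, params in enumerate(synthetic.default_species_params()):
            truth = synthetic.make_truth(
                default_county.grid, default_county.covariates, params, seed=101 + i
            )
            pres = synthetic.sample_presence_cells(truth.suitability_prob, 300, seed=5)
            rows, cols = default_county.grid.cell_of(pres["x"].to_numpy(), pres["y"].to_numpy())
            presence_rows = fs.row_of_cells(rows, cols)
            model = habitat.fit_maxent(presence_rows, fs, beta=0.5)
            rho = spearmanr(
                model.suitability().values.ravel(), truth.suitability_prob.values.ravel()
            ).statistic
            assert rho > 0.8

    def test_empty_presence_rejected(self, small_grid):
        with pytest.raises(ValueError, match="presence"):
            habitat.fit_maxent(np.array([], dtype=int), np.ones((16, 1)), grid=small_grid)


class TestThresholdRange:
    @pytest.fixture(scope="class")
    def fitted(self):
        county = synthetic.make_county(synthetic.CountySpec(seed=0))
        fs = habitat.build_features(county.covariates)
        rng = np.random.default_rng(8)
        presence = rng.integers(0, fs.matrix.shape[0], 200)
        return habitat.fit_maxent(presence, fs, beta=0.5), presence

    def test_zero_threshold_keeps_every_cell(self, fitted):
        model, presence = fitted
        mask = habitat.threshold_range(model, presence, rule="fixed", threshold=0.0)
        assert mask.suitable_area_km2 == pytest.approx(25_600.0)

    def test_presence_percentile_keeps_at_least_ninety_percent(self, fitted):
        model, presence = fitted
        mask = habitat.threshold_range(model, presence, percentile=10.0)
        suit = model.suitability().values.ravel()[presence]
        inside = (suit >= mask.threshold).mean()
        assert inside >= 0.9

    def test_raising_threshold_never_grows_the_range(self, fitted):
        model, presence = fitted
        areas = [
            habitat.threshold_range(model, presence, rule="fixed", threshold=t).suitable_area_km2
            for t in np.linspace(0.0, 1.0, 11)
        ]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestMaskDensity:
    def test_full_mask_is_identity_and_empty_mask_zeroes(self, small_grid, rng):
        dens = Raster(small_grid, rng.uniform(0, 5, (4, 4)))
        ones = habitat.RangeMask(Raster(small_grid, np.ones((4, 4))), "fixed", 0.0)
        zeros = habitat.RangeMask(Raster(small_grid, np.zeros((4, 4))), "fixed", 1.0)
        same, removed = habitat.mask_density(dens, ones)
        np.testing.assert_array_equal(same.values, dens.values)
        assert removed == 0.0
        none, removed = habitat.mask_density(dens, zeros)
        assert np.all(none.values == 0.0)
        assert removed == pytest.approx(dens.total())

    def test_masked_total_never_exceeds_unmasked(self, small_grid, rng):
        for _ in range(20):
            dens = Raster(small_grid, rng.uniform(0, 5, (4, 4)))
            m = habitat.RangeMask(Raster(small_grid, (rng.random((4, 4)) > 0.5).astype(float)), "fixed", 0.5)
            clipped, removed = habitat.mask_density(dens, m)
            assert clipped.total() <= dens.total() + 1e-9
            outside_mass = float((dens.values * (1 - m.mask.values)).sum())
            if outside_mass == 0:
                assert clipped.total() == pytest.approx(dens.total())
            else:
                assert clipped.total() < dens.total()

    def test_grid_mismatch_rejected(self, small_grid, rng):
        other = GridSpec(xmin=0.0, ymax=10.0, cell_size=5.0, nrows=2, ncols=2)
        dens = Raster(small_grid, rng.uniform(0, 5, (4, 4)))
        m = habitat.RangeMask(Raster(other, np.ones((2, 2))), "fixed", 0.0)
        with pytest.raises(ValueError, match="different grids"):
            habitat.mask_density(dens, m)
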