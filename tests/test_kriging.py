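"""Variograms and ordinary kriging against brute-force solves."""

import numpy as np
import pytest

from oracles import ok_system_oracle
from savannagrad.kriging import (
    InsufficientDataError,
    VariogramModel,
    empirical_variogram,
    fit_variogram,
    krige,
    kriging_weights,
    impute_grid,
)


class TestEmpiricalVariogram:
    def test_constant_field_zero_semivariance(self, rng):
        pts = rng.uniform(0, 100, size=(30, 2))
        emp = empirical_variogram(pts, np.full(30, 7.0))
        assert np.allclose(emp["semivariance"], 0.0)

    def test_two_point_semivariance(self):
        # 0.5 * (0 - 2)^2 = 2: the pair at lag 4 sits alone in its bin
        line = np.column_stack([100.0 + 7.3 * np.arange(10), np.full(10, 200.0)])
        pts = np.vstack([[[0.0, 0.0], [0.0, 4.0]], line])
        vals = np.concatenate([[0.0, 2.0], np.zeros(10)])
        emp = empirical_variogram(pts, vals, n_lags=30, max_dist=60)
        bin_idx = np.argmin(np.abs(emp["lag"] - 4.0))
        assert emp["lag"][bin_idx] == pytest.approx(4.0)
        assert emp["semivariance"][bin_idx] == pytest.approx(2.0)

    def test_white_noise_sill_near_variance(self, rng):
        """Monte-Carlo: the sill of an uncorrelated field is its variance."""
        sills = []
        for _ in range(10):
            pts = rng.uniform(0, 1000, size=(150, 2))
            vals = rng.normal(0, 2.0, size=150)
            emp = empirical_variogram(pts, vals, n_lags=8)
            sills.append(np.average(emp["semivariance"], weights=emp["n_pairs"]))
        assert np.mean(sills) == pytest.approx(4.0, rel=0.15)

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            empirical_variogram(np.zeros((3, 2)), np.full(3, np.nan))


class TestFitVariogram:
    def test_recovers_spherical_from_noiseless_values(self):
        truth = VariogramModel("spherical", 0.2, 1.3, 900.0)
        lags = np.linspace(50, 1800, 12)
        emp = {"lag": lags, "semivariance": truth(lags), "n_pairs": np.full(12, 40)}
        fit = fit_variogram(emp)
        assert fit.family == "spherical"
        assert fit.nugget == pytest.approx(truth.nugget, abs=0.1 * truth.sill)
        assert fit.psill == pytest.approx(truth.psill, rel=0.1)
        assert fit.range_ == pytest.approx(truth.range_, rel=0.1)

    def test_all_zero_semivariances_give_flat_model(self):
        emp = {"lag": np.array([1.0, 2, 3, 4]), "semivariance": np.zeros(4),
               "n_pairs": np.full(4, 10)}
        fit = fit_variogram(emp)
        assert fit.nugget == 0.0 and fit.sill == 0.0

    def test_two_bins_insufficient(self):
        emp = {"lag": np.array([1.0, 2.0]), "semivariance": np.array([0.5, 0.9]),
               "n_pairs": np.array([5, 5])}
        with pytest.raises(InsufficientDataError):
            fit_variogram(emp)


class TestKrige:
    model = VariogramModel("exponential", 0.1, 1.0, 500.0)

    def test_three_point_system_matches_dense_solve(self, rng):
        pts = rng.uniform(0, 300, size=(3, 2))
        vals = rng.normal(size=3)
        tgt = rng.uniform(0, 300, size=2)
        w_oracle = ok_system_oracle(lambda h: float(self.model(h)), pts, tgt)
        pred, _ = krige(self.model, pts, vals, [tgt])
        assert pred[0] == pytest.approx(float(w_oracle @ vals), abs=1e-10)

    def test_weights_sum_to_one(self, rng):
        pts = rng.uniform(0, 500, size=(25, 2))
        for _ in range(20):
            w, _, _ = kriging_weights(self.model, pts, rng.uniform(0, 500, 2))
            assert w.sum() == pytest.approx(1.0, abs=1e-8)

    def test_exact_interpolation_with_zero_nugget(self, rng):
        m0 = VariogramModel("spherical", 0.0, 1.0, 400.0)
        pts = rng.uniform(0, 300, size=(12, 2))
        vals = rng.normal(size=12)
        pred, var = krige(m0, pts, vals, pts)
        assert np.allclose(pred, vals, atol=1e-8)

    def test_constant_field_constant_prediction(self, rng):
        pts = rng.uniform(0, 300, size=(15, 2))
        pred, _ = krige(self.model, pts, np.full(15, 3.3), rng.uniform(0, 300, (10, 2)))
        assert np.allclose(pred, 3.3, atol=1e-8)

    def test_duplicate_points_are_deduplicated(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        vals = np.array([1.0, 3.0, 2.0, 4.0])
        pred, _ = krige(self.model, pts, vals, [[50.0, 50.0]])
        assert np.isfinite(pred[0])


class TestImputeGrid:
    def test_observed_values_untouched_and_gaps_filled(self, small_grid):
        out = impute_grid(small_grid, columns=["grass_cover"], max_neighbors=16, seed=0)
        obs = small_grid.df["grass_cover"].notna()
        np.testing.assert_allclose(
            out.df.loc[obs, "grass_cover"], small_grid.df.loc[obs, "grass_cover"]
        )
        assert out.df["grass_cover"].isna().sum() == 0
        prov = out.df["grass_cover_provenance"]
        assert set(prov.unique()) == {"observed", "imputed"}
        assert (prov == "observed").sum() == obs.sum()

    def test_bounded_covariates_stay_in_range(self, small_grid):
        out = impute_grid(small_grid, columns=["grass_color"], max_neighbors=16, seed=0)
        assert out.df["grass_color"].between(1.0, 5.0).all()
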