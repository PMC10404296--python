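import json

import numpy as np
import pandas as pd
import pytest

import carbonflux as cf
from carbonflux.raster import RasterGrid
from carbonflux.uncertainty import SDLayer, pure_nugget


def grids(lo, hi, shape=(2, 2)):
    q05 = RasterGrid(np.full(shape, float(lo)))
    q95 = RasterGrid(np.full(shape, float(hi)))
    return q05, q95


class TestIntervalToSD:
    def test_zero_width_gives_zero(self):
        for mode in ("corrected", "literal"):
            layer = cf.sd_from_interval(*grids(3.0, 3.0), mode=mode)
            np.testing.assert_array_equal(layer.sd.data, 0.0)

    def test_corrected_mode(self):
        layer = cf.sd_from_interval(*grids(-10.0, 10.0))
        assert layer.sd.data[0, 0] == pytest.approx(6.0790, abs=1e-3)

    def test_literal_mode(self):
        layer = cf.sd_from_interval(*grids(-10.0, 10.0), mode="literal")
        assert layer.sd.data[0, 0] == pytest.approx(16.4)

    def test_crossed_quantiles_raise_with_pixel(self):
        q05, q95 = grids(1.0, 0.0)
        with pytest.raises(ValueError, match=r"\(0, 0\)"):
            cf.sd_from_interval(q05, q95)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            cf.sd_from_interval(*grids(0, 1), mode="exact")


class TestStandardizedResiduals:
    def make_prediction(self, mean, sd, shape=(10, 10)):
        from carbonflux.ensemble import EnsemblePrediction

        m = RasterGrid(np.full(shape, float(mean)))
        s = RasterGrid(np.full(shape, float(sd)))
        return EnsemblePrediction(mean_flux=m, q05=m, q95=m, sd_flux=s)

    def make_plots(self, fluxes):
        df = pd.DataFrame(
            {
                "plot_id": [f"p{i}" for i in range(len(fluxes))],
                "x": np.arange(len(fluxes)) * 100.0 + 50.0,
                "y": 50.0,
                "flux_obs": fluxes,
                "flux_var": 1.0,
                "source": "NFI",
                "forest_change_flag": False,
                "edge_flag": False,
            }
        )
        return cf.ReferenceSet(df)

    def test_perfect_prediction_gives_zero_residuals(self):
        pred = self.make_prediction(mean=2.0, sd=3.0)
        out = cf.standardized_residuals(pred, self.make_plots([2.0] * 5))
        np.testing.assert_allclose(out["residual"], 0.0)

    def test_unit_residual_when_error_equals_sd(self):
        pred = self.make_prediction(mean=0.0, sd=4.0)
        out = cf.standardized_residuals(pred, self.make_plots([4.0]))
        assert out["residual"].iloc[0] == pytest.approx(1.0)

    def test_calibrated_sd_layer_gives_unit_variance(self, rng):
        # residual field with known SD; SD layer set to exactly that SD
        truth_sd = 7.0
        pred = self.make_prediction(mean=0.0, sd=truth_sd, shape=(10, 40))
        obs = rng.normal(0, truth_sd, 40)
        df = pd.DataFrame(
            {
                "plot_id": [f"p{i}" for i in range(40)],
                "x": np.arange(40) * 100.0 + 50.0,
                "y": 250.0,
                "flux_obs": obs,
                "flux_var": 1.0,
                "source": "NFI",
                "forest_change_flag": False,
                "edge_flag": False,
            }
        )
        out = cf.standardized_residuals(pred, cf.ReferenceSet(df))
        assert 0.8 <= out["residual"].std() <= 1.2


class TestEmpiricalVariogram:
    def test_white_noise_is_flat_at_unit_sill(self, rng):
        n = 400
        pts = pd.DataFrame(
            {
                "x": rng.uniform(0, 10000, n),
                "y": rng.uniform(0, 10000, n),
                "residual": rng.standard_normal(n),
            }
        )
        emp = cf.empirical_variogram(pts, n_lags=10)
        assert (np.abs(emp["semivariance"] - 1.0) < 0.15).all()

    def test_hand_counted_collinear_points(self):
        pts = pd.DataFrame(
            {"x": [0.0, 1.0, 2.0, 3.0], "y": 0.0,
             "residual": [0.0, 1.0, 0.0, 1.0]}
        )
        emp = cf.empirical_variogram(pts, n_lags=3, max_dist_m=3.5,
                                     min_points=4)
        # pairs at distance 1: (0,1),(1,0),(0,1) → γ = mean(1,1,1)/2 = 0.5
        gamma_1 = emp.loc[emp["n_pairs"] == 3, "semivariance"].iloc[0]
        assert gamma_1 == pytest.approx(0.5)

    def test_zero_distance_pairs_excluded(self):
        pts = pd.DataFrame(
            {"x": [0.0, 0.0, 5.0, 5.0], "y": 0.0,
             "residual": [0.0, 9.0, 1.0, 1.0]}
        )
        emp = cf.empirical_variogram(pts, n_lags=2, max_dist_m=6.0,
                                     min_points=4)
        # the two coincident pairs contribute nothing; distance-5 pairs only
        assert emp["n_pairs"].sum() == 4

    def test_too_few_points(self):
        pts = pd.DataFrame({"x": [0.0, 1.0], "y": 0.0, "residual": [0, 1]})
        with pytest.raises(ValueError):
            cf.empirical_variogram(pts)


def simulate_exponential_field(n, eff_range, total_sill, nugget, seed,
                               extent=10000.0):
    """Draw residuals from an exponential-covariance Gaussian process."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, extent, (n, 2))
    from scipy.spatial.distance import pdist, squareform

    h = squareform(pdist(xy))
    psill = total_sill - nugget
    cov = psill * np.exp(-3.0 * h / eff_range) + nugget * np.eye(n)
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    r = L @ rng.standard_normal(n)
    return pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "residual": r})


class TestFitCorrelogram:
    def test_recovers_exponential_parameters(self):
        ranges, sills = [], []
        for seed in range(5):
            pts = simulate_exponential_field(400, 2000.0, 1.0, 0.2, seed)
            emp = cf.empirical_variogram(pts, n_lags=15, max_dist_m=6000)
            m = cf.fit_correlogram(emp)
            ranges.append(m.effective_range_m)
            sills.append(m.total_sill)
        assert np.median(ranges) == pytest.approx(2000, rel=0.25)
        assert np.median(sills) == pytest.approx(1.0, rel=0.15)

    def test_white_noise_is_near_pure_nugget(self):
        fracs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pts = pd.DataFrame(
                {
                    "x": rng.uniform(0, 10000, 500),
                    "y": rng.uniform(0, 10000, 500),
                    "residual": rng.standard_normal(500),
                }
            )
            emp = cf.empirical_variogram(pts, n_lags=12)
            m = cf.fit_correlogram(emp)
            fracs.append(m.partial_sill / m.total_sill)
        assert np.median(fracs) <= 0.2

    def test_fitted_semivariance_monotone(self):
        pts = simulate_exponential_field(300, 2000.0, 1.0, 0.2, seed=1)
        emp = cf.empirical_variogram(pts, n_lags=12, max_dist_m=6000)
        m = cf.fit_correlogram(emp)
        h = np.linspace(1, 8000, 200)
        gamma = m.semivariance(h)
        assert (np.diff(gamma) >= -1e-12).all()

    def test_rho_properties(self):
        m = cf.CorrelogramModel("exponential", nugget=0.2, partial_sill=0.8,
                                range_param=600.0)
        assert m.rho(0.0) == 1.0
        h = np.linspace(1, m.effective_range_m, 50)
        r = m.rho(h)
        assert (np.diff(r) <= 1e-12).all()
        assert m.rho(m.effective_range_m + 1) == 0.0

    def test_too_few_bins(self):
        emp = pd.DataFrame({"lag": [1, 2], "semivariance": [1, 1],
                            "n_pairs": [5, 5]})
        with pytest.raises(ValueError):
            cf.fit_correlogram(emp)


class TestClassVariance:
    def test_two_pixel_hand_expansion(self):
        # 2 adjacent pixels, per-pixel SD 1 Mg C, rho = 0.5 at their distance
        sd = SDLayer(RasterGrid(np.array([[1.0, 1.0]]), cell_size_m=100.0))
        m = cf.CorrelogramModel("exponential", nugget=0.0, partial_sill=1.0,
                                range_param=100.0 / np.log(2))  # rho(100)=0.5
        out = cf.aggregate_class_variance(
            sd, np.ones((1, 2), bool), m, cell_area_ha=1.0, mode="correlated"
        )
        assert out.variance_TgC2 * 1e12 == pytest.approx(3.0, rel=1e-10)
        assert out.sd_TgC * 1e6 == pytest.approx(np.sqrt(3.0), rel=1e-10)

    def test_independence_limit(self, rng):
        sd = SDLayer(RasterGrid(rng.uniform(0.5, 2.0, (10, 10))))
        mask = rng.uniform(size=(10, 10)) > 0.3
        out = cf.aggregate_class_variance(sd, mask, mode="independent")
        expected = float((sd.sd.data[mask] ** 2).sum()) / 1e12
        assert out.variance_TgC2 == pytest.approx(expected, rel=1e-12)

    def test_perfect_correlation_limit(self):
        n = 7
        sd = SDLayer(RasterGrid(np.full((1, n), 2.0), cell_size_m=10.0))
        m = cf.CorrelogramModel("exponential", nugget=0.0, partial_sill=1.0,
                                range_param=1e9)
        out = cf.aggregate_class_variance(
            sd, np.ones((1, n), bool), m, mode="correlated"
        )
        assert out.sd_TgC * 1e6 == pytest.approx(n * 2.0, rel=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_windowed_sum_matches_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        shape = (15, 20)
        sd = SDLayer(RasterGrid(rng.uniform(0.1, 3.0, shape),
                                cell_size_m=100.0))
        mask = rng.uniform(size=shape) > 0.4
        m = cf.CorrelogramModel("exponential", nugget=0.3, partial_sill=0.7,
                                range_param=250.0)
        fast = cf.aggregate_class_variance(sd, mask, m, cell_area_ha=1.0,
                                           mode="correlated")
        slow = cf.aggregate_class_variance_bruteforce(sd, mask, m,
                                                      cell_area_ha=1.0)
        assert fast.variance_TgC2 == pytest.approx(slow.variance_TgC2,
                                                   rel=1e-10)

    def test_sd_monotone_in_range(self, rng):
        sd = SDLayer(RasterGrid(rng.uniform(0.5, 1.5, (12, 12)),
                                cell_size_m=100.0))
        mask = np.ones((12, 12), bool)
        sds = []
        for rng_param in (50.0, 300.0, 1500.0):
            m = cf.CorrelogramModel("exponential", nugget=0.2,
                                    partial_sill=0.8, range_param=rng_param)
            sds.append(
                cf.aggregate_class_variance(sd, mask, m,
                                            mode="correlated").sd_TgC
            )
        assert sds[0] < sds[1] < sds[2]

    def test_cell_area_scales_sd_linearly(self, rng):
        sd = SDLayer(RasterGrid(rng.uniform(0.5, 1.5, (8, 8))))
        mask = np.ones((8, 8), bool)
        a = cf.aggregate_class_variance(sd, mask, cell_area_ha=1.0,
                                        mode="independent")
        b = cf.aggregate_class_variance(sd, mask, cell_area_ha=2.0,
                                        mode="independent")
        assert b.sd_TgC == pytest.approx(2 * a.sd_TgC, rel=1e-12)

    def test_correlated_without_model_raises(self, rng):
        sd = SDLayer(RasterGrid(rng.uniform(0.5, 1.5, (4, 4))))
        with pytest.raises(ValueError, match="correlogram"):
            cf.aggregate_class_variance(sd, np.ones((4, 4), bool),
                                        mode="correlated")


class TestClosingVariance:
    def make(self, sd, cls="mixed"):
        return cf.ClassVariance(unseea_class=cls, n_pixels=10,
                                variance_TgC2=sd**2, mode="independent")

    def test_three_four_five(self):
        out = cf.closing_stock_variance(self.make(3.0), self.make(4.0))
        assert out.sd_TgC == pytest.approx(5.0)

    def test_zero_flux_variance(self):
        out = cf.closing_stock_variance(self.make(2.5), self.make(0.0))
        assert out.sd_TgC == pytest.approx(2.5)

    def test_closing_dominates_components(self, rng):
        for _ in range(5):
            a, b = rng.uniform(0, 10, 2)
            out = cf.closing_stock_variance(self.make(a), self.make(b))
            assert out.sd_TgC >= max(a, b) - 1e-12

    def test_class_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            cf.closing_stock_variance(self.make(1.0, "mixed"),
                                      self.make(1.0, "coniferous"))
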