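import numpy as np
import pandas as pd
import pytest

import carbonflux as cf
from carbonflux.covariates import DesignMatrix
from carbonflux.ensemble import QuantileRegressionForest, _concat_ranges


def toy_design(n=120, p=4, seed=0, response=None):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, p)),
                     columns=[f"v{i}" for i in range(p)])
    if response is None:
        response = 3 * X["v0"].to_numpy() + rng.normal(0, 0.5, n)
    return DesignMatrix(
        X=X,
        response=np.asarray(response, float),
        weights=np.ones(n),
        coords=rng.uniform(0, 1000, (n, 2)),
        column_groups={c: [c] for c in X.columns},
    )


class TestTuning:
    def test_single_combination_identity(self):
        spec = cf.LearnerSpec("bagged_trees",
                              {"n_estimators": [50], "max_features": [1.0]})
        tuned = cf.tune_base_learner(spec, toy_design(), k=3, seed=0)
        assert tuned.tuned_values == {"n_estimators": 50, "max_features": 1.0}

    def test_deep_interaction_prefers_deep_trees(self):
        rng = np.random.default_rng(1)
        n = 300
        X = pd.DataFrame(rng.standard_normal((n, 3)),
                         columns=["a", "b", "c"])
        y = 5 * np.sign(X["a"]) * np.sign(X["b"]) * np.sign(X["c"])
        d = DesignMatrix(
            X=X, response=y.to_numpy(), weights=np.ones(n),
            coords=rng.uniform(0, 1000, (n, 2)),
            column_groups={c: [c] for c in X.columns},
        )
        spec = cf.LearnerSpec(
            "gradient_boosted_trees",
            {"n_estimators": [100], "max_depth": [1, 8],
             "learning_rate": [0.1]},
        )
        tuned = cf.tune_base_learner(spec, d, k=3, seed=0)
        assert tuned.tuned_values["max_depth"] == 8

    def test_deterministic_selection(self):
        spec = cf.LearnerSpec("kernel_margin",
                              {"C": [0.1, 1.0], "gamma_mult": [0.5, 1.0]})
        a = cf.tune_base_learner(spec, toy_design(), k=3, seed=5)
        b = cf.tune_base_learner(spec, toy_design(), k=3, seed=5)
        assert a.tuned_values == b.tuned_values


class TestStacking:
    def test_constant_response_predicts_constant(self):
        d = toy_design(response=np.zeros(120))
        res = cf.CarbonFluxModel(d, seed=0).fit()
        pred = res.meta.predict(res.oof_base)
        np.testing.assert_allclose(pred, 0.0, atol=1e-6)

    def test_oracle_covariate_yields_near_perfect_meta(self):
        # one covariate IS the response: interpolation-friendly, noise-free
        rng = np.random.default_rng(2)
        n = 200
        y = rng.normal(0, 10, n)
        X = pd.DataFrame({"truth": y, "junk": rng.standard_normal(n)})
        d = DesignMatrix(
            X=X, response=y, weights=np.ones(n),
            coords=rng.uniform(0, 1000, (n, 2)),
            column_groups={c: [c] for c in X.columns},
        )
        res = cf.CarbonFluxModel(d, seed=0).fit()
        assert res.cv_result.mean("r2") >= 0.9

    @pytest.mark.parametrize("seed", range(3))
    def test_shuffled_response_has_no_skill(self, seed):
        rng = np.random.default_rng(seed)
        d = toy_design(seed=seed)
        d = DesignMatrix(
            X=d.X, response=rng.permutation(d.response), weights=d.weights,
            coords=d.coords, column_groups=d.column_groups,
        )
        res = cf.CarbonFluxModel(d, seed=seed).fit()
        assert res.cv_result.mean("r2") <= 0.1

    def test_stacking_close_to_best_base_learner(self):
        """Under study-like conditions (2:1 signal:noise landscape with
        heteroscedastic plot error), meta CV RMSE stays within 5% of the
        best base learner's on the same folds (3-seed median)."""
        ratios = []
        for seed in range(3):
            spec = cf.ScenarioSpec(grid_shape=(60, 60), n_plots=250,
                                   seed=seed)
            sc = cf.generate_scenario(spec)
            plots = cf.prepare(sc.plots)
            stack = cf.CovariateStack.from_scenario(sc)
            retained = cf.screen_collinearity(stack, seed=seed)
            d = cf.extract_at_plots(stack, plots, retained=retained)
            res = cf.CarbonFluxModel(d, seed=seed).fit()
            y = d.response
            base_rmse = min(
                np.sqrt(np.mean((y - res.oof_base[:, b]) ** 2))
                for b in range(3)
            )
            meta_rmse = np.sqrt(np.mean((y - res.cv_pred) ** 2))
            ratios.append(meta_rmse / base_rmse)
        assert np.median(ratios) <= 1.05

    def test_too_few_plots_raises(self):
        with pytest.raises(ValueError, match="at least"):
            cf.CarbonFluxModel(toy_design(n=8), k=5)

    def test_fit_deterministic(self):
        d = toy_design()
        a = cf.CarbonFluxModel(d, seed=3).fit()
        b = cf.CarbonFluxModel(d, seed=3).fit()
        np.testing.assert_array_equal(a.cv_pred, b.cv_pred)
        np.testing.assert_array_equal(a.oof_base, b.oof_base)


class TestPrediction:
    def test_prediction_raster_geometry(self, fitted_small):
        stack, design, plots, results = fitted_small
        pred = results.predict_flux(stack)
        assert pred.mean_flux.shape == stack.grid.shape
        valid = pred.q05.valid_mask()
        assert (pred.q05.data[valid] <= pred.q95.data[valid]).all()
        assert (pred.sd_flux.data[pred.sd_flux.valid_mask()] >= 0).all()

    def test_nodata_propagates(self, fitted_small):
        stack, *_ , results = fitted_small
        pred = results.predict_flux(stack)
        # texture layers are nodata on the border ⇒ predictions must be too
        assert not pred.mean_flux.valid_mask()[0].any()

    def test_missing_layer_raises(self, fitted_small):
        stack, *_, results = fitted_small
        crippled = stack.subset([n for n in stack.names if n != "cov00"])
        with pytest.raises(ValueError, match="cov00"):
            results.predict_flux(crippled)

    def test_degenerate_level_pair(self, fitted_small):
        stack, *_, results = fitted_small
        pred = results.predict(stack, levels=(0.5, 0.5))
        valid = pred.q05.valid_mask()
        np.testing.assert_array_equal(pred.q05.data[valid],
                                      pred.q95.data[valid])

    def test_levels_outside_unit_interval(self, fitted_small):
        *_, results = fitted_small
        with pytest.raises(ValueError, match="levels"):
            results.meta.predict_quantiles(results.oof_base, levels=(0.0, 1.0))

    def test_median_between_interval_bounds(self, fitted_small):
        stack, *_, results = fitted_small
        pred = results.predict(stack, levels=(0.05, 0.95))
        Xpix_valid = pred.q05.valid_mask()
        med = results.predict(stack, levels=(0.5, 0.5)).q05
        ok = (pred.q05.data[Xpix_valid] <= med.data[Xpix_valid] + 1e-9) & (
            med.data[Xpix_valid] <= pred.q95.data[Xpix_valid] + 1e-9
        )
        assert ok.mean() >= 0.99


class TestQRF:
    def test_concat_ranges(self):
        out = _concat_ranges(np.array([0, 5, 9]), np.array([2, 3, 1]))
        np.testing.assert_array_equal(out, [0, 1, 5, 6, 7, 9])

    def test_interval_width_tracks_noise(self):
        # pure noise response: the 5–95 interval of the leaf-pooled
        # distribution should approximate the marginal quantiles
        rng = np.random.default_rng(0)
        n = 600
        X = rng.standard_normal((n, 2))  # uninformative
        y = rng.normal(0, 10, n)
        qrf = QuantileRegressionForest(n_estimators=100,
                                       random_state=0).fit(X, y)
        qq = qrf.predict_quantiles(rng.standard_normal((200, 2)),
                                   levels=(0.05, 0.95))
        width = (qq[:, 1] - qq[:, 0]).mean()
        assert 2 * 1.645 * 10 * 0.7 <= width <= 2 * 1.645 * 10 * 1.3


class TestImportance:
    def test_informative_covariate_scores_100(self, fitted_small):
        *_, results = fitted_small
        imp = results.permutation_importance()
        assert max(imp.per_covariate.values()) == 100.0
        # cov00 carries the largest coefficient in the generator
        assert max(imp.per_covariate, key=imp.per_covariate.get) == "cov00"

    def test_pure_noise_covariate_negligible(self):
        rng = np.random.default_rng(4)
        scores = []
        for seed in range(5):
            d = toy_design(n=200, seed=seed)  # v0 drives, v1..v3 noise
            res = cf.CarbonFluxModel(d, seed=seed).fit()
            imp = res.permutation_importance()
            scores.append(imp.per_covariate["v3"])
        assert np.median(scores) <= 5.0

    def test_invariant_to_column_order(self):
        d = toy_design(n=150, seed=9)
        res1 = cf.CarbonFluxModel(d, seed=1).fit()
        imp1 = res1.permutation_importance()
        cols = list(d.X.columns)[::-1]
        d2 = DesignMatrix(
            X=d.X[cols], response=d.response, weights=d.weights,
            coords=d.coords, column_groups={c: [c] for c in cols},
        )
        res2 = cf.CarbonFluxModel(d2, seed=1).fit()
        imp2 = res2.permutation_importance()
        for name in imp1.per_covariate:
            assert imp1.per_covariate[name] == pytest.approx(
                imp2.per_covariate[name], abs=15.0
            )
        assert (max(imp1.per_covariate, key=imp1.per_covariate.get)
                == max(imp2.per_covariate, key=imp2.per_covariate.get))


class TestAggregateImportance:
    def test_single_category_takes_all(self):
        table = cf.ImportanceTable({"a": 100.0, "b": 40.0})
        cats, supers = cf.aggregate_importance(
            table, {"a": "CCI", "b": "CCI"}
        )
        assert cats == {"CCI": 1.0}
        assert supers == {"global-AGB-maps": 1.0}

    def test_shares_sum_to_one(self):
        table = cf.ImportanceTable({"a": 60.0, "b": 30.0, "c": 10.0})
        cats, supers = cf.aggregate_importance(
            table, {"a": "CCI", "b": "envi", "c": "topo"}
        )
        assert sum(cats.values()) == pytest.approx(1.0)
        assert sum(supers.values()) == pytest.approx(1.0)

    def test_equal_scores_split_evenly(self):
        table = cf.ImportanceTable({"a": 50.0, "b": 50.0})
        cats, _ = cf.aggregate_importance(table, {"a": "CCI", "b": "topo"})
        assert cats == {"CCI": 0.5, "topo": 0.5}

    def test_untagged_covariate_raises(self):
        with pytest.raises(ValueError, match="category"):
            cf.aggregate_importance(cf.ImportanceTable({"a": 1.0}), {})
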