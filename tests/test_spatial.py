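"""Regression stage: standardization, GLMs, stepwise AIC, Moran's I, SEM."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from orophylo import (SpatialErrorRegression, SpatialWeights, build_design,
                      filter_collinear, fit_glm, fit_sem_ml, knn_weights,
                      loo_importance, minmax_standardize, morans_i,
                      random_coords, simulate_sem_response, step_aic,
                      standardized_coefficients)
from orophylo.spatial import CollinearityFilter, DegenerateColumnError


class TestMinMax:
    @pytest.mark.parametrize("col,expected", [
        ([2, 4, 6], [0, 0.5, 1]),
        ([-1, 0, 3], [0, 0.25, 1]),
        ([0, 0.5, 1], [0, 0.5, 1]),   # idempotent on [0,1] data
    ])
    def test_formula(self, col, expected):
        out = minmax_standardize(pd.DataFrame({"x": col}))
        assert out["x"].tolist() == pytest.approx(expected)

    def test_constant_column_named_in_error(self):
        with pytest.raises(DegenerateColumnError, match="elev"):
            minmax_standardize(pd.DataFrame({"elev": [3, 3, 3]}))


class TestCollinearityFilter:
    def test_duplicate_column_dropped_once(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=200)})
        kept, dropped = filter_collinear(df)
        assert len(dropped) == 1 and dropped[0] in {"a", "b"}
        assert "c" in kept.columns

    def test_independent_columns_survive(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(1000, 5)),
                          columns=list("abcde"))
        kept, dropped = filter_collinear(df)
        assert dropped == []

    def test_threshold_one_keeps_near_duplicates(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x + rng.normal(0, 1e-3, 100)})
        kept, dropped = filter_collinear(df, threshold=1.0)
        assert dropped == []

    def test_sklearn_transform_api(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=50)})
        f = CollinearityFilter().fit(df)
        assert list(f.transform(df).columns) == f.kept_


class TestGLM:
    def test_noiseless_fit_recovers_coefficients(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.normal(size=50)})
        y = 2.0 + 3.0 * df["x"]
        fit = fit_glm(y, df, ["x"])
        assert fit.deviance_explained == pytest.approx(100.0, abs=1e-8)
        assert fit.params["Intercept"] == pytest.approx(2.0, abs=1e-8)
        assert fit.params["x"] == pytest.approx(3.0, abs=1e-8)

    def test_intercept_only_explains_nothing(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": rng.normal(size=50)})
        y = rng.normal(size=50)
        fit = fit_glm(y, df, [])
        assert fit.deviance_explained == pytest.approx(0.0, abs=1e-10)

    def test_deviance_explained_equals_r_squared(self, landform_table):
        rng = np.random.default_rng(6)
        y = rng.normal(size=len(landform_table)) + landform_table["TCQ"]
        fit = fit_glm(y, landform_table, ["landform", "TCQ"])
        r = np.corrcoef(fit.fitted, y)[0, 1]
        assert fit.deviance_explained == pytest.approx(100 * r**2, abs=1e-10)

    def test_reference_coding_against_danxia(self, landform_table):
        design, term_map = build_design(landform_table, ["landform"])
        assert "landform[Danxia]" not in design.columns
        assert len(term_map["landform"]) == 4

    def test_interaction_columns_are_products(self, landform_table):
        design, term_map = build_design(landform_table,
                                        ["landform", "TCQ", "landform:TCQ"])
        col = "landform[karst]:TCQ"
        assert col in design.columns
        expected = design["landform[karst]"] * design["TCQ"]
        assert np.allclose(design[col], expected)

    def test_aliased_column_dropped_with_warning(self, landform_table):
        df = landform_table.copy()
        df["TCQ2"] = df["TCQ"] * 2  # exactly collinear
        rng = np.random.default_rng(7)
        y = rng.normal(size=len(df))
        fit = fit_glm(y, df, ["TCQ", "TCQ2"])
        assert fit.dropped_aliased == ["TCQ2"]

    def test_simulated_signal_fraction_recovered(self):
        rng = np.random.default_rng(8)
        des, ys = [], []
        for rep in range(20):
            x = rng.normal(size=500)
            signal = x * np.sqrt(0.6)
            noise = rng.normal(size=500) * np.sqrt(0.4)
            df = pd.DataFrame({"x": x})
            fit = fit_glm(signal + noise, df, ["x"])
            ys.append(fit.deviance_explained)
        assert 50 <= np.mean(ys) <= 70

    def test_nested_models_never_invert_ordering(self, landform_table):
        rng = np.random.default_rng(9)
        y = rng.normal(size=len(landform_table))
        small = fit_glm(y, landform_table, ["landform"])
        big = fit_glm(y, landform_table, ["landform", "TCQ", "PREC"])
        assert big.deviance_explained >= small.deviance_explained - 1e-10

    def test_standardized_coefficients_scale_free(self, landform_table):
        y = 3.0 * landform_table["TCQ"] + np.random.default_rng(10).normal(
            size=len(landform_table))
        fit = fit_glm(y, landform_table, ["TCQ"])
        sc = standardized_coefficients(fit, y, landform_table)
        scaled = landform_table.copy()
        scaled["TCQ"] = scaled["TCQ"] * 100
        fit2 = fit_glm(y, scaled, ["TCQ"])
        sc2 = standardized_coefficients(fit2, y, scaled)
        assert sc["TCQ"] == pytest.approx(sc2["TCQ"], abs=1e-10)


class TestStepAIC:
    def test_scope_equal_to_model_is_fixed_point(self, landform_table):
        rng = np.random.default_rng(11)
        y = rng.normal(size=len(landform_table)) + landform_table["TCQ"]
        # with adds exhausted and drops AIC-worse, the model is stable
        fit = step_aic(y, landform_table, ["TCQ"], scope=["TCQ"])
        best = fit_glm(y, landform_table, ["TCQ"])
        assert fit.aic <= best.aic + 1e-9

    def test_noise_predictor_usually_dropped(self):
        # AIC removes a single null predictor iff its chi2_1 deviance gain
        # falls below 2, i.e. with probability ~0.843; 50 draws should sit
        # well above the 3-sigma lower band (~34).
        dropped = 0
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            df = pd.DataFrame({"signal": rng.normal(size=500),
                               "noise": rng.normal(size=500)})
            y = df["signal"] + rng.normal(size=500)
            fit = step_aic(y, df, ["signal", "noise"])
            if "noise" not in fit.terms:
                dropped += 1
            assert "signal" in fit.terms  # standardized effect 1.0: kept
        assert dropped >= 35

    def test_marginality_preserved(self, landform_table):
        rng = np.random.default_rng(12)
        y = rng.normal(size=len(landform_table))
        fit = step_aic(y, landform_table,
                       ["landform", "TCQ", "landform:TCQ"])
        if "landform:TCQ" in fit.terms:
            assert {"landform", "TCQ"} <= set(fit.terms)

    def test_aic_never_increases(self, landform_table):
        rng = np.random.default_rng(13)
        y = rng.normal(size=len(landform_table))
        start = fit_glm(y, landform_table, ["landform", "TCQ", "PREC"])
        out = step_aic(y, landform_table, ["landform", "TCQ", "PREC"])
        assert out.aic <= start.aic + 1e-9


class TestLooImportance:
    def test_informative_predictor_has_largest_delta(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame({"good": rng.normal(size=500),
                           "null1": rng.normal(size=500),
                           "null2": rng.normal(size=500)})
        y = 2 * df["good"] + rng.normal(size=500)
        out = loo_importance(y, df, ["good", "null1", "null2"])
        out = out.set_index("term")["delta_deviance_explained"]
        assert out.idxmax() == "good"
        assert abs(out["null1"]) < 2.0 and abs(out["null2"]) < 2.0

    def test_dropping_a_main_removes_its_interactions(self, landform_table):
        rng = np.random.default_rng(15)
        y = rng.normal(size=len(landform_table))
        out = loo_importance(y, landform_table,
                             ["landform", "TCQ", "landform:TCQ"])
        assert set(out["term"]) == {"landform", "TCQ", "landform:TCQ"}


class TestWeightsAndMoran:
    def test_row_sums_one(self):
        w = knn_weights(random_coords(100, seed=16), k=8)
        assert np.allclose(w.matrix.sum(axis=1), 1.0)
        assert np.all(np.diag(w.matrix) == 0)

    def test_fully_connected_limit(self):
        w = knn_weights(random_coords(6, seed=17), k=5)
        off = w.matrix[~np.eye(6, dtype=bool)]
        assert np.allclose(off, 1 / 5)

    def test_collinear_points_tie_broken_by_site_order(self):
        coords = pd.DataFrame({"lon": [0.0, 1.0, 2.0], "lat": [0.0, 0.0, 0.0]})
        w = knn_weights(coords, k=1)
        assert w.matrix[1, 0] == 1.0  # middle site's tie goes to site 0
        assert np.allclose(w.matrix.sum(axis=1), 1.0)

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            knn_weights(random_coords(5, seed=0), k=5)

    def test_alternating_ring_gives_minus_one(self):
        W = np.zeros((4, 4))
        for i in range(4):
            W[i, (i - 1) % 4] = W[i, (i + 1) % 4] = 0.5
        w = SpatialWeights(ids=list(range(4)), matrix=W, k=2)
        res = morans_i([1, -1, 1, -1], w)
        assert res.I == pytest.approx(-1.0)
        assert res.expected == pytest.approx(-1 / 3)

    def test_iid_values_near_null_expectation(self):
        w = knn_weights(random_coords(200, seed=18), k=8)
        x = np.random.default_rng(19).normal(size=200)
        res = morans_i(x, w)
        assert abs(res.I - res.expected) <= 4 * np.sqrt(res.variance)

    def test_constant_vector_rejected(self):
        w = knn_weights(random_coords(10, seed=20), k=3)
        with pytest.raises(ValueError):
            morans_i(np.ones(10), w)


@pytest.fixture(scope="module")
def weights():
    return knn_weights(random_coords(200, seed=21), k=8)


class TestSpatialErrorModel:

    def test_lambda_zero_reduces_to_ols(self, weights):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(200, 2))
        y = X @ np.array([1.0, -0.5]) + rng.normal(size=200)
        pinned = SpatialErrorRegression(weights=weights,
                                        lambda_bounds=(-1e-12, 1e-12))
        pinned.fit(X, y)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert pinned.coef_ == pytest.approx(ols.params[1:], abs=1e-6)
        assert pinned.intercept_ == pytest.approx(ols.params[0], abs=1e-6)

    def test_free_lambda_near_zero_for_iid_errors(self, weights):
        lams = []
        for rep in range(20):
            rng = np.random.default_rng(300 + rep)
            X = rng.normal(size=(200, 2))
            y = X @ np.array([1.0, -0.5]) + rng.normal(size=200)
            lams.append(fit_sem_ml(y, X, weights).lam)
        assert abs(np.mean(lams)) < 0.1

    def test_profile_maximality_at_estimate(self, weights):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(200, 2))
        y = simulate_sem_response(X, [1.0, -0.5], weights, 0.5, seed=24)
        free = SpatialErrorRegression(weights=weights).fit(X, y)
        pinned = SpatialErrorRegression(weights=weights,
                                        lambda_bounds=(-1e-12, 1e-12)).fit(X, y)
        assert free.llf_ >= pinned.llf_ - 1e-9

    def test_lambda_recovery(self, weights):
        lams = []
        for rep in range(20):
            rng = np.random.default_rng(400 + rep)
            X = rng.normal(size=(200, 2))
            y = simulate_sem_response(X, [1.0, -0.5], weights, 0.6,
                                      seed=500 + rep)
            lams.append(fit_sem_ml(y, X, weights).lam)
        assert 0.45 <= np.mean(lams) <= 0.75

    def test_rank_deficient_design_rejected(self, weights):
        X = np.ones((200, 2))
        with pytest.raises(np.linalg.LinAlgError):
            SpatialErrorRegression(weights=weights).fit(X, np.ones(200))

    def test_sklearn_api(self, weights):
        est = SpatialErrorRegression(weights=weights)
        assert est.get_params()["fit_intercept"] is True
        rng = np.random.default_rng(25)
        X = rng.normal(size=(200, 1))
        y = 2 * X[:, 0] + rng.normal(size=200)
        est.fit(X, y)
        pred = est.predict(X)
        assert np.corrcoef(pred, y)[0, 1] ** 2 > 0.5
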