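"""Forest machinery: tree growth, OOB, importance, effects, proximity."""
import numpy as np
import pandas as pd
import pytest

from conftest import assert_same_tree, brute_force_cart
from lakesar.forest import (ProximityImputer, RegressionForest, grow_tree,
                            impute_missing)


class TestGrowTree:
    def test_perfectly_separable_step(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        f = grow_tree(X, y, mtry=1, min_leaf_size=1)
        root = 0
        assert f.tree_feature_[root] == 0
        assert 2.0 < f.tree_threshold_[root] <= 3.0
        preds = f.predict(X)
        np.testing.assert_allclose(preds, y, atol=1e-12)

    def test_constant_response_single_leaf(self):
        X = np.arange(10.0).reshape(-1, 1)
        f = grow_tree(X, np.full(10, 5.0), min_leaf_size=2)
        assert f.tree_feature_.shape[0] == 1
        assert f.tree_feature_[0] == -1
        np.testing.assert_allclose(f.predict(X), 5.0)

    def test_matches_brute_force_oracle_small(self):
        rng = np.random.default_rng(17)
        X = rng.uniform(0, 1, size=(60, 3))
        y = np.sin(4 * X[:, 0]) + rng.normal(0, 0.2, 60)
        f = grow_tree(X, y, mtry=3, min_leaf_size=5)
        ref = brute_force_cart(X, y, min_leaf=5)
        assert_same_tree(f, ref)


class TestForestFit:
    def test_single_tree_reduction(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, size=(100, 2))
        y = X[:, 0] + rng.normal(0, 0.1, 100)
        single = grow_tree(X, y, mtry=2, min_leaf_size=5)
        forest = RegressionForest(n_trees=1, mtry=2, bootstrap=False,
                                  random_state=0).fit(X, y)
        np.testing.assert_allclose(forest.predict(X), single.predict(X))

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, size=(80, 3))
        y = X[:, 1] + rng.normal(0, 0.2, 80)
        a = RegressionForest(n_trees=25, random_state=9).fit(X, y)
        b = RegressionForest(n_trees=25, random_state=9).fit(X, y)
        np.testing.assert_array_equal(a.tree_threshold_, b.tree_threshold_)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_oob_fraction_near_e_inverse(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, size=(100, 2))
        y = rng.normal(0, 1, 100)
        f = RegressionForest(n_trees=500, random_state=1).fit(X, y)
        mean_oob = f.oob_.sum(axis=1).mean()
        assert abs(mean_oob - 100 * (1 - 1 / 100) ** 100) < 2.0

    def test_missing_values_rejected_with_instruction(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]] * 12)
        with pytest.raises(ValueError, match="impute"):
            RegressionForest(n_trees=2).fit(X, np.zeros(24))

    def test_predictions_bounded_by_training_response(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, size=(200, 3))
        y = rng.normal(0, 1, 200)
        f = RegressionForest(n_trees=50, random_state=2).fit(X, y)
        grid = rng.uniform(-2, 3, size=(500, 3))  # beyond training range
        preds = f.predict(grid)
        assert preds.min() >= y.min() - 1e-12
        assert preds.max() <= y.max() + 1e-12

    def test_row_and_column_order_invariance(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.uniform(0, 1, size=(120, 4)),
                         columns=list("abcd"))
        y = X["a"].to_numpy() + rng.normal(0, 0.1, 120)
        f = RegressionForest(n_trees=30, random_state=3).fit(X, y)
        perm = rng.permutation(120)
        np.testing.assert_allclose(f.predict(X.iloc[perm]),
                                   f.predict(X)[perm])
        np.testing.assert_allclose(f.predict(X[["d", "b", "a", "c"]]),
                                   f.predict(X))


class TestOOBVariance:
    def test_pure_noise_explains_nothing(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, size=(300, 4))
        y = rng.normal(0, 1, 300)
        f = RegressionForest(n_trees=200, random_state=4).fit(X, y)
        assert f.oob_variance_explained_ <= 0.05

    def test_step_function_recovered(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, size=(500, 3))
        y = (X[:, 0] > 0.5).astype(float)
        f = RegressionForest(n_trees=200, random_state=5).fit(X, y)
        assert f.oob_variance_explained_ >= 0.9


@pytest.fixture(scope="module")
def step_forest():
    rng = np.random.default_rng(9)
    X = pd.DataFrame({
        "signal": rng.uniform(0, 1, 400),
        "noise": rng.normal(0, 1, 400),
        "constant": np.full(400, 3.7),
    })
    y = (X["signal"] > 0.5).astype(float).to_numpy()
    f = RegressionForest(n_trees=300, random_state=6).fit(X, y)
    return f, f.permutation_importance(n_perm=5, random_state=0)


class TestImportance:

    def test_informative_predictor_ranks_first(self, step_forest):
        _, imp = step_forest
        assert imp.iloc[0]["predictor"] == "signal"
        assert imp.iloc[0]["importance"] > 0

    def test_constant_column_importance_exactly_zero(self, step_forest):
        _, imp = step_forest
        row = imp[imp["predictor"] == "constant"].iloc[0]
        assert row["importance"] == 0.0

    def test_decoy_importance_near_zero(self, step_forest):
        _, imp = step_forest
        row = imp[imp["predictor"] == "noise"].iloc[0]
        assert abs(row["importance"]) < 0.25 * \
            imp.iloc[0]["importance"]

    def test_mse_metric_available(self, step_forest):
        f, _ = step_forest
        imp = f.permutation_importance(metric="mse", n_perm=2,
                                       random_state=1)
        assert (imp["metric"] == "mse").all()


class TestPartialDependence:
    def test_irrelevant_predictor_flat(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame({"x1": rng.uniform(0, 1, 600),
                          "x2": rng.uniform(0, 1, 600)})
        y = 2 * X["x1"].to_numpy() + rng.normal(0, 0.2, 600)
        f = RegressionForest(n_trees=300, random_state=7).fit(X, y)
        flat = f.partial_dependence("x2", grid_size=15)
        signal = f.partial_dependence("x1", grid_size=15)
        # flat within the noise band: an order of magnitude below the signal
        assert np.ptp(flat.effect) < 0.15 * np.ptp(signal.effect)
        assert np.ptp(flat.effect) < 0.3 * y.std()

    def test_linear_signal_slope_recovered(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"x1": rng.uniform(0, 1, 1000),
                          "x2": rng.uniform(0, 1, 1000)})
        y = 2 * X["x1"].to_numpy() + rng.normal(0, 0.5, 1000)
        f = RegressionForest(n_trees=300, random_state=8).fit(X, y)
        eff = f.partial_dependence("x1", grid_size=25)
        interior = (eff.grid > 0.1) & (eff.grid < 0.9)
        slope = np.polyfit(eff.grid[interior], eff.effect[interior], 1)[0]
        assert 1.5 <= slope <= 2.2  # edge attenuation expected
        # monotone increasing as a trend (grid-level wiggle is expected)
        g, v = eff.grid[interior], eff.effect[interior]
        rho = np.corrcoef(np.argsort(np.argsort(g)),
                          np.argsort(np.argsort(v)))[0, 1]
        assert rho > 0.9

    def test_grid_average_matches_mean_prediction(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame({"x1": rng.uniform(0, 1, 500),
                          "x2": rng.uniform(0, 1, 500)})
        y = np.sin(3 * X["x1"].to_numpy()) + rng.normal(0, 0.3, 500)
        f = RegressionForest(n_trees=200, random_state=9).fit(X, y)
        eff = f.partial_dependence("x1", grid_size=40)
        assert abs(eff.effect.mean() - f.predict(X).mean()) < 0.05 * y.std()


class TestInteractionSurface:
    def test_additive_signal_has_constant_row_offsets(self):
        # rows of an additive signal's surface differ by near-constant
        # offsets; a true interaction of comparable amplitude does not
        rng = np.random.default_rng(13)
        n = 2000
        x1, x2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        noise = rng.normal(0, 0.2, n)
        X = pd.DataFrame({"x1": x1, "x2": x2})

        def rms_interaction_residual(y):
            f = RegressionForest(n_trees=300, mtry=2,
                                 random_state=10).fit(X, y)
            s = f.interaction_surface(("x1", "x2"), grid_size=12).surface
            r = s - s.mean(axis=0) - s.mean(axis=1)[:, None] + s.mean()
            return np.sqrt((r ** 2).mean())

        y_add = np.sin(3 * x1) + 2 * x2 + noise
        y_int = 2 * np.sin(3 * x1) * x2 + noise
        r_add = rms_interaction_residual(y_add)
        r_int = rms_interaction_residual(y_int)
        assert r_add < 0.1 * y_add.std()
        assert r_add < r_int / 3

    def test_product_sign_quadrants(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame({"x1": rng.uniform(-1, 1, 1500),
                          "x2": rng.uniform(-1, 1, 1500)})
        y = (X["x1"] * X["x2"]).to_numpy() + rng.normal(0, 0.1, 1500)
        f = RegressionForest(n_trees=300, random_state=11).fit(X, y)
        g = f.interaction_surface(("x1", "x2"), grid_size=11)
        s = g.surface  # rows: x2, cols: x1
        assert s[-1, -1] > 0 and s[0, 0] > 0   # same-sign corners
        assert s[-1, 0] < 0 and s[0, -1] < 0   # opposite-sign corners


class TestProximity:
    def test_duplicated_rows_have_unit_proximity(self):
        rng = np.random.default_rng(15)
        X = rng.uniform(0, 1, size=(50, 2))
        X[1] = X[0]
        y = X[:, 0] + rng.normal(0, 0.05, 50)
        y[1] = y[0]
        f = RegressionForest(n_trees=100, min_leaf_size=5,
                             random_state=12).fit(X, y)
        P = f.proximity()
        assert P[0, 1] == 1.0

    def test_matrix_properties(self):
        rng = np.random.default_rng(16)
        X = rng.uniform(0, 1, size=(80, 3))
        y = X[:, 0] + rng.normal(0, 0.2, 80)
        P = RegressionForest(n_trees=100,
                             random_state=13).fit(X, y).proximity()
        np.testing.assert_allclose(P, P.T)
        np.testing.assert_allclose(np.diag(P), 1.0)
        assert P.min() >= 0 and P.max() <= 1

    def test_single_leaf_forest_all_ones(self):
        X = np.arange(30.0).reshape(-1, 1)
        f = RegressionForest(n_trees=20, random_state=14).fit(
            X, np.full(30, 2.0))
        np.testing.assert_allclose(f.proximity(), 1.0)

    def test_cluster_structure_reflected(self):
        rng = np.random.default_rng(17)
        X = np.vstack([rng.normal(0, 0.3, size=(60, 2)),
                       rng.normal(4, 0.3, size=(60, 2))])
        y = np.r_[np.zeros(60), np.ones(60)] + rng.normal(0, 0.1, 120)
        P = RegressionForest(n_trees=100,
                             random_state=15).fit(X, y).proximity()
        within = (P[:60, :60].mean() + P[60:, 60:].mean()) / 2
        between = P[:60, 60:].mean()
        assert within > between


class TestImputation:
    def test_no_missing_returns_unchanged(self):
        rng = np.random.default_rng(18)
        X = pd.DataFrame(rng.uniform(0, 1, size=(60, 3)),
                         columns=list("abc"))
        y = X["a"].to_numpy()
        out, imp = impute_missing(X, y, n_iter=2, seed=0, n_trees=30)
        pd.testing.assert_frame_equal(out, X)

    def test_iteration_zero_is_column_medians(self):
        rng = np.random.default_rng(19)
        X = pd.DataFrame(rng.normal(0, 1, size=(80, 3)),
                         columns=list("abc"))
        X.iloc[::11, 1] = np.nan
        y = rng.normal(0, 1, 80)
        _, imp = impute_missing(X, y, n_iter=1, seed=1, n_trees=30)
        filled = imp.iterations_[0]
        med = X["b"].median()
        assert np.all(filled[X["b"].isna().to_numpy(), 1] == med)

    def test_entirely_missing_column_errors(self):
        X = pd.DataFrame({"a": np.arange(30.0), "b": np.nan})
        with pytest.raises(ValueError, match="entirely missing"):
            ProximityImputer(n_iter=1).fit_transform(X, np.zeros(30))

    def test_over_twenty_percent_missing_rejected(self):
        rng = np.random.default_rng(20)
        X = pd.DataFrame({"a": np.arange(40.0),
                          "b": rng.normal(0, 1, 40)})
        X.iloc[:12, 1] = np.nan
        with pytest.raises(ValueError, match="20%"):
            ProximityImputer(n_iter=1).fit_transform(X, np.zeros(40))
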