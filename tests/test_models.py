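"""Base learners, grid search under shared CV folds, embedded importances."""
import numpy as np
import pandas as pd
import pytest

from qsrrkit.evaluation import cv_folds, rmse, train_test_from_folds
from qsrrkit.exceptions import ConfigurationError, UnsupportedMethodError, ValidationError
from qsrrkit.models import (
    ModelConfig,
    default_grid,
    embedded_importances,
    fit_predict,
    grid_search,
    make_estimator,
)


def oracle_grid_search(config, X, y, folds, fold_seed):
    """Independently coded exhaustive loop sharing the same fold assignment."""
    assignment = cv_folds(len(y), folds, fold_seed)
    vals = X.to_numpy(dtype=float)
    best = None
    for order, params in enumerate(config.grid_points()):
        errs = []
        for i in range(len(assignment)):
            tr, te = train_test_from_folds(assignment, i, len(y))
            est = make_estimator(config.algorithm, params, X.shape[1], config.seed)
            est.fit(vals[tr], y[tr])
            errs.append(rmse(y[te], est.predict(vals[te])))
        mean = float(np.mean(errs))
        if best is None or mean < best[0]:
            best = (mean, order, params)
    return best


class TestGridSearch:
    def test_singleton_grid_is_chosen(self, random_xy):
        X, y = random_xy
        mc = ModelConfig("LASSO", grid={"alpha": [0.05]}, seed=0)
        fm = grid_search(mc, X, y, folds=5)
        assert fm.chosen_hyperparameters == {"alpha": 0.05}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle_on_2x3_grid(self, seed):
        r = np.random.default_rng(seed)
        X = pd.DataFrame(r.standard_normal((40, 5)), columns=[f"x{i}" for i in range(5)])
        y = X["x0"].to_numpy() + r.normal(0, 0.5, 40)
        mc = ModelConfig(
            "SVR_RBF",
            grid={"C": [0.5, 2.0], "epsilon": [0.01, 0.1, 0.3]},
            seed=seed,
        )
        fm = grid_search(mc, X, y, folds=5, fold_seed=seed)
        best_rmse, _, best_params = oracle_grid_search(mc, X, y, 5, seed)
        assert fm.chosen_hyperparameters == best_params
        assert fm.cv_rmse == pytest.approx(best_rmse, abs=1e-12)

    def test_best_point_not_beaten_by_any_grid_point(self, random_xy):
        X, y = random_xy
        mc = ModelConfig("LASSO", grid={"alpha": [0.001, 0.01, 0.1, 1.0]}, seed=1)
        fm = grid_search(mc, X, y, folds=5, fold_seed=1)
        assignment = cv_folds(len(y), 5, 1)
        for alpha in mc.grid["alpha"]:
            errs = []
            for i in range(len(assignment)):
                tr, te = train_test_from_folds(assignment, i, len(y))
                est = make_estimator("LASSO", {"alpha": alpha}, X.shape[1], 1)
                est.fit(X.to_numpy()[tr], y[tr])
                errs.append(rmse(y[te], est.predict(X.to_numpy()[te])))
            assert fm.cv_rmse <= np.mean(errs) + 1e-12

    def test_lasso_penalty_above_shrinkage_bound_zeroes_coefficients(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 4)), columns=list("abcd"))
        X = X - X.mean()
        y = X["a"].to_numpy() + rng.normal(0, 0.1, 50)
        y = y - y.mean()
        bound = np.max(np.abs(X.to_numpy().T @ y)) / len(y)
        mc = ModelConfig("LASSO", grid={"alpha": [2 * bound]}, seed=0)
        fm = grid_search(mc, X, y, folds=5)
        assert np.allclose(fm.estimator.coef_, 0.0)

    def test_deterministic_under_fixed_seed(self, random_xy):
        X, y = random_xy
        mc = ModelConfig("RF", grid={"n_estimators": [30], "mtry": ["sqrt"]}, seed=3)
        a = grid_search(mc, X, y, folds=5, fold_seed=3)
        b = grid_search(mc, X, y, folds=5, fold_seed=3)
        assert a.cv_rmse == b.cv_rmse
        assert np.array_equal(
            a.estimator.predict(X.to_numpy()), b.estimator.predict(X.to_numpy())
        )

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig("PLS")


class TestFitPredict:
    def test_mlr_interpolates_noiseless_linear_data(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        y = X.to_numpy() @ np.array([1.0, -2.0, 0.5]) + 3.0
        mc = ModelConfig("MLR", seed=0)
        fm = grid_search(mc, X, y, folds=5)
        assert np.max(np.abs(fm.predict(X) - y)) < 1e-8

    def test_rf_on_constant_target_predicts_constant(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        y = np.full(20, 7.5)
        est = make_estimator("RF", {"n_estimators": 20}, 3, 0)
        est.fit(X.to_numpy(), y)
        assert np.allclose(est.predict(X.to_numpy()), 7.5)

    def test_svr_single_point_within_epsilon(self):
        X = np.array([[0.3]])
        y = np.array([2.0])
        est = make_estimator("SVR_RBF", {"C": 10.0, "epsilon": 0.1}, 1, 0)
        est.fit(X, y)
        assert abs(est.predict(X)[0] - 2.0) <= 0.1 + 1e-9

    def test_back_transform_returns_minutes(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 2)), columns=list("ab"))
        y = np.log(rng.uniform(2, 15, 30))
        fm = grid_search(ModelConfig("MLR", seed=0), X, y, folds=5)
        pred_t, pred_min = fit_predict(fm, X, transform="log")
        assert np.allclose(pred_min, np.exp(pred_t))
        same_t, same_min = fit_predict(fm, X, transform="none")
        assert np.array_equal(same_t, same_min)

    def test_missing_feature_listed_in_error(self, random_xy):
        X, y = random_xy
        fm = grid_search(ModelConfig("MLR", seed=0), X, y, folds=5)
        with pytest.raises(ValidationError, match="f3"):
            fm.predict(X.drop(columns=["f3"]))


class TestEmbeddedImportances:
    def test_lasso_returns_only_nonzero_coefficients(self, rng):
        X = pd.DataFrame(rng.standard_normal((100, 10)), columns=[f"x{i}" for i in range(10)])
        y = 3 * X["x0"].to_numpy() + 2 * X["x1"].to_numpy() - X["x2"].to_numpy()
        mc = ModelConfig("LASSO", grid={"alpha": [0.5]}, seed=0)
        fm = grid_search(mc, X, y, folds=5)
        names = embedded_importances(fm, top_k=20)
        nonzero = int(np.count_nonzero(fm.estimator.coef_))
        assert len(names) == nonzero <= 3

    def test_rf_ranks_the_true_driver_first(self):
        r = np.random.default_rng(5)
        X = pd.DataFrame(r.standard_normal((500, 6)), columns=[f"x{i}" for i in range(6)])
        y = X["x1"].to_numpy() + r.normal(0, 0.1, 500)
        mc = ModelConfig("RF", grid={"n_estimators": [100], "mtry": ["third"]}, seed=5)
        fm = grid_search(mc, X, y, folds=5, fold_seed=5)
        assert embedded_importances(fm, top_k=3)[0] == "x1"

    def test_importances_sorted_non_increasing(self, random_xy):
        X, y = random_xy
        mc = ModelConfig("GBR", grid={"n_estimators": [30], "max_depth": [2], "learning_rate": [0.1]}, seed=0)
        fm = grid_search(mc, X, y, folds=5)
        names = embedded_importances(fm, top_k=8)
        scores = [fm.importances[n] for n in names]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_mlr_and_svr_unsupported(self, random_xy):
        X, y = random_xy
        fm = grid_search(ModelConfig("MLR", seed=0), X, y, folds=5)
        with pytest.raises(UnsupportedMethodError):
            embedded_importances(fm)


def test_default_grids_cover_documented_ranges():
    assert len(default_grid("LASSO")["alpha"]) == 25
    svr = default_grid("SVR_RBF")
    assert set(svr) == {"C", "gamma_factor", "epsilon"}
    assert default_grid("MLR") == {}
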