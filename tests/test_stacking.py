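"""Two-level stacking: meta fit, prediction arithmetic, leakage semantics."""
import numpy as np
import pandas as pd
import pytest

from qsrrkit.evaluation import cv_folds, rmse, train_test_from_folds
from qsrrkit.exceptions import ConfigurationError, ValidationError
from qsrrkit.models import ModelConfig, grid_search
from qsrrkit.stacking import (
    LeakageWarning,
    StackingModel,
    stack_fit,
    stack_predict,
)


def _mlr_base(X, y, cols, seed=0):
    return grid_search(ModelConfig("MLR", seed=seed), X[cols], y, folds=5)


@pytest.fixture
def linear_problem(rng):
    X = pd.DataFrame(
        rng.standard_normal((40, 4)), columns=["a", "b", "c", "d"]
    )
    y = X["a"].to_numpy() * 2.0 + X["b"].to_numpy() - 0.5
    return X, y


class TestStackFit:
    def test_perfect_base_yields_identity_stack(self, linear_problem):
        X, y = linear_problem
        base = {"mlr": _mlr_base(X, y, ["a", "b"])}
        stack = stack_fit(base, X, y, folds=5, seed=0)
        pred = stack_predict(stack, base, X)
        assert np.max(np.abs(pred - y)) < 1e-6

    def test_meta_coefficients_match_normal_equations_oracle(self, linear_problem):
        X, y = linear_problem
        bases = {
            "m1": _mlr_base(X, y, ["a"]),
            "m2": _mlr_base(X, y, ["b", "c"]),
        }
        X_ext = X.iloc[:5]
        y_ext = y[:5]
        with pytest.warns(LeakageWarning):
            stack = stack_fit(
                bases, X, y, mode="external", external=(X_ext, y_ext),
                meta_solver="ols",
            )
        Z = np.column_stack([bases[k].predict(X_ext) for k in stack.base_keys])
        A = np.column_stack([np.ones(5), Z])
        coef, *_ = np.linalg.lstsq(A, y_ext, rcond=None)
        assert stack.intercept == pytest.approx(coef[0], abs=1e-8)
        assert np.allclose(stack.weights, coef[1:], atol=1e-8)

    def test_duplicate_bases_leave_predictions_invariant(self, linear_problem):
        X, y = linear_problem
        one = {"m1": _mlr_base(X, y, ["a", "b"])}
        two = {
            "m1": _mlr_base(X, y, ["a", "b"]),
            "m2": _mlr_base(X, y, ["a", "b"]),
        }
        s1 = stack_fit(one, X, y, folds=5, seed=1)
        s2 = stack_fit(two, X, y, folds=5, seed=1)
        p1 = stack_predict(s1, one, X)
        p2 = stack_predict(s2, two, X)
        assert np.allclose(p1, p2, atol=1e-6)

    def test_out_of_fold_matrix_matches_manual_loop(self, linear_problem):
        X, y = linear_problem
        bases = {"m1": _mlr_base(X, y, ["a"]), "m2": _mlr_base(X, y, ["b"])}
        stack, Z = stack_fit(
            bases, X, y, folds=5, seed=4, return_oof=True, n_repeats=1
        )
        assignment = cv_folds(len(y), 5, 4)
        manual = np.full((len(y), 2), np.nan)
        for i in range(5):
            tr, te = train_test_from_folds(assignment, i, len(y))
            for j, key in enumerate(stack.base_keys):
                fm = bases[key]
                refit = fm.refit(X[fm.feature_names].iloc[tr], y[tr])
                manual[te, j] = refit.predict(X[fm.feature_names].iloc[te])
        assert np.allclose(Z, manual, atol=1e-10)

    def test_external_mode_requires_external_data(self, linear_problem):
        X, y = linear_problem
        bases = {"m": _mlr_base(X, y, ["a"])}
        with pytest.raises(ConfigurationError, match="external"):
            stack_fit(bases, X, y, mode="external")

    def test_unknown_mode_rejected(self, linear_problem):
        X, y = linear_problem
        bases = {"m": _mlr_base(X, y, ["a"])}
        with pytest.raises(ConfigurationError, match="mode"):
            stack_fit(bases, X, y, mode="sideways")


class TestStackPredict:
    def test_affine_form_hand_example(self, linear_problem):
        X, y = linear_problem
        # constant-prediction bases: LASSO at a crushing penalty predicts the mean
        from qsrrkit.models import make_estimator, FittedModel

        def const_base(c):
            est = make_estimator("LASSO", {"alpha": 1e6}, 4, 0)
            est.fit(X.to_numpy(), np.full(len(X), c))
            return FittedModel(
                config=ModelConfig("LASSO", grid={"alpha": [1e6]}),
                chosen_hyperparameters={"alpha": 1e6},
                cv_rmse=0.0,
                cv_r2=0.0,
                feature_names=list(X.columns),
                estimator=est,
            )

        bases = {"b1": const_base(2.0), "b2": const_base(4.0)}
        stack = StackingModel(
            base_keys=["b1", "b2"], intercept=0.0, weights=np.array([0.5, 0.5])
        )
        pred = stack_predict(stack, bases, X)
        assert np.allclose(pred, 3.0, atol=1e-9)
        zero_stack = StackingModel(
            base_keys=["b1", "b2"], intercept=1.25, weights=np.array([0.0, 0.0])
        )
        assert np.allclose(stack_predict(zero_stack, bases, X), 1.25)

    def test_matches_composition_oracle_on_random_rows(self, linear_problem, rng):
        X, y = linear_problem
        bases = {"m1": _mlr_base(X, y, ["a"]), "m2": _mlr_base(X, y, ["b", "c"])}
        stack = stack_fit(bases, X, y, folds=5, seed=2)
        X_new = pd.DataFrame(rng.standard_normal((20, 4)), columns=X.columns)
        pred = stack_predict(stack, bases, X_new)
        manual = stack.intercept + sum(
            w * bases[k].predict(X_new)
            for k, w in zip(stack.base_keys, stack.weights)
        )
        assert np.allclose(pred, manual, atol=1e-12)

    def test_missing_base_model_rejected(self, linear_problem):
        X, y = linear_problem
        bases = {"m1": _mlr_base(X, y, ["a"])}
        stack = StackingModel(base_keys=["m1", "ghost"], intercept=0.0, weights=np.zeros(2))
        with pytest.raises(ValidationError, match="ghost"):
            stack_predict(stack, bases, X)


def test_external_mode_is_optimistically_biased(rng):
    """Training the meta-learner on the evaluation set understates its error."""
    gaps = []
    for r in range(10):
        rr = np.random.default_rng(100 + r)
        X = pd.DataFrame(rr.standard_normal((50, 4)), columns=list("abcd"))
        y = X["a"].to_numpy() + 0.5 * X["b"].to_numpy() + rr.normal(0, 0.6, 50)
        X_ext = pd.DataFrame(rr.standard_normal((12, 4)), columns=list("abcd"))
        y_ext = X_ext["a"].to_numpy() + 0.5 * X_ext["b"].to_numpy() + rr.normal(0, 0.6, 12)
        bases = {
            "m1": _mlr_base(X, y, ["a"], seed=r),
            "m2": _mlr_base(X, y, ["b", "c"], seed=r),
        }
        honest = stack_fit(bases, X, y, folds=5, seed=r)
        with pytest.warns(LeakageWarning):
            leaky = stack_fit(
                bases, X, y, mode="external", external=(X_ext, y_ext)
            )
        gaps.append(
            rmse(y_ext, stack_predict(honest, bases, X_ext))
            - rmse(y_ext, stack_predict(leaky, bases, X_ext))
        )
    # leaky external error is lower on average (it was fit on that very set)
    assert np.mean(gaps) > 0


def test_json_round_trip():
    s = StackingModel(
        base_keys=["a", "b"], intercept=0.5, weights=np.array([0.2, 0.8])
    )
    back = StackingModel.from_json(s.to_json())
    assert back.base_keys == s.base_keys
    assert back.intercept == s.intercept
    assert np.array_equal(back.weights, s.weights)
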