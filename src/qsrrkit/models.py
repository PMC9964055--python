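"""Base learners, default hyperparameter grids, and grid search under k-fold CV.

Five regression algorithms are supported — multiple linear regression (MLR),
LASSO, RBF-kernel support vector regression (SVR), random forest (RF) and
gradient boosting (GBR) — addressed in the model registry by the labels used
in the performance tables: ``MLR_CFS``, ``SVR_CFS``, ``MLR_RFE``,
``SVR_RFE``, ``Lasso``, ``RF``, ``GBM``. The suffix names the feature set a
model consumes (CFS- or RFE-selected); the embedded learners run on all
remaining features. MLR is offered only on selected feature sets, since with
more descriptors than compounds an unpenalized least-squares fit is
ill-posed.

Hyperparameters are tuned by exhaustive grid search: every grid point is
scored by k-fold cross-validated RMSE on a shared fold assignment and the
minimizer wins (ties go to the first point in deterministic grid order).
The SVR kernel width is parameterized as a multiple of the ``scale``
heuristic ``1 / (p · var(X))``.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.svm import SVR

from .evaluation import cv_folds, r2, rmse, train_test_from_folds
from .exceptions import ConfigurationError, UnsupportedMethodError, ValidationError

__all__ = [
    "ALGORITHMS",
    "MODEL_REGISTRY",
    "ModelConfig",
    "FittedModel",
    "default_grid",
    "make_estimator",
    "grid_search",
    "fit_predict",
    "embedded_importances",
]

ALGORITHMS = ("MLR", "LASSO", "SVR_RBF", "RF", "GBR")

#: Registry label -> (algorithm, feature source). The seven-model lineup of
#: the per-pH performance tables; the stacked ensemble is added on top.
MODEL_REGISTRY: dict[str, tuple[str, str]] = {
    "MLR_CFS": ("MLR", "cfs"),
    "SVR_CFS": ("SVR_RBF", "cfs"),
    "MLR_RFE": ("MLR", "rfe"),
    "SVR_RFE": ("SVR_RBF", "rfe"),
    "Lasso": ("LASSO", "all"),
    "RF": ("RF", "all"),
    "GBM": ("GBR", "all"),
}


def default_grid(algorithm: str) -> dict[str, list]:
    """Caret-style default hyperparameter grids (user-overridable)."""
    if algorithm == "MLR":
        return {}
    if algorithm == "LASSO":
        return {"alpha": list(np.logspace(-4, 1, 25))}
    if algorithm == "SVR_RBF":
        return {
            "C": [0.25, 0.5, 1.0, 2.0, 4.0, 8.0],
            "gamma_factor": [0.25, 0.5, 1.0, 2.0, 4.0],
            "epsilon": [0.01, 0.1, 0.2],
        }
    if algorithm == "RF":
        return {"n_estimators": [500], "mtry": ["third", "sqrt", "half"]}
    if algorithm == "GBR":
        return {
            "n_estimators": list(range(100, 1001, 150)),
            "max_depth": [1, 2, 3],
            "learning_rate": [0.01, 0.05, 0.1],
        }
    raise ConfigurationError(f"unknown algorithm {algorithm!r}")


_MTRY = {
    "third": lambda p: max(1, p // 3),
    "sqrt": lambda p: max(1, int(np.sqrt(p))),
    "half": lambda p: max(1, p // 2),
}


def make_estimator(algorithm: str, params: Mapping, n_features: int, seed: int):
    """Instantiate a scikit-learn estimator for one grid point."""
    params = dict(params)
    if algorithm == "MLR":
        return LinearRegression()
    if algorithm == "LASSO":
        return Lasso(alpha=float(params.get("alpha", 1.0)), max_iter=50000)
    if algorithm == "SVR_RBF":
        gamma = float(params.get("gamma_factor", 1.0)) / max(n_features, 1)
        return SVR(
            kernel="rbf",
            C=float(params.get("C", 1.0)),
            gamma=gamma,
            epsilon=float(params.get("epsilon", 0.1)),
        )
    if algorithm == "RF":
        mtry = params.get("mtry", "third")
        max_features = _MTRY[mtry](n_features) if isinstance(mtry, str) else int(mtry)
        return RandomForestRegressor(
            n_estimators=int(params.get("n_estimators", 500)),
            max_features=max_features,
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "GBR":
        return GradientBoostingRegressor(
            n_estimators=int(params.get("n_estimators", 100)),
            max_depth=int(params.get("max_depth", 3)),
            learning_rate=float(params.get("learning_rate", 0.1)),
            random_state=seed,
        )
    raise ConfigurationError(f"unknown algorithm {algorithm!r}")


@dataclass
class ModelConfig:
    """Which algorithm to fit, on which feature source, over which grid."""

    algorithm: str
    feature_source: str = "all"  # "cfs" | "rfe" | "all"
    grid: dict[str, list] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )
        if self.grid is None:
            self.grid = default_grid(self.algorithm)

    def grid_points(self) -> list[dict]:
        """Deterministic enumeration of the grid (insertion order of keys)."""
        if not self.grid:
            return [{}]
        keys = list(self.grid)
        if any(len(v) == 0 for v in self.grid.values()):
            raise ConfigurationError("empty candidate list in hyperparameter grid")
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.grid[k] for k in keys))
        ]


@dataclass
class FittedModel:
    """A tuned, refitted learner with its CV score and feature importances."""

    config: ModelConfig
    chosen_hyperparameters: dict
    cv_rmse: float
    cv_r2: float
    feature_names: list[str]
    estimator: object
    importances: dict[str, float] = field(default_factory=dict)

    def refit(self, X: pd.DataFrame, y) -> "FittedModel":
        """A fresh estimator with the same hyperparameters fitted on (X, y).

        ``X`` may carry a different feature subset than the original fit
        (e.g. features re-selected on a cross-validation fold); the refit
        estimator is sized to the columns it is given.
        """
        names = list(X.columns) if isinstance(X, pd.DataFrame) else self.feature_names
        est = make_estimator(
            self.config.algorithm,
            self.chosen_hyperparameters,
            len(names),
            self.config.seed,
        )
        est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
        return FittedModel(
            config=self.config,
            chosen_hyperparameters=self.chosen_hyperparameters,
            cv_rmse=self.cv_rmse,
            cv_r2=self.cv_r2,
            feature_names=names,
            estimator=est,
            importances=self.importances,
        )

    def predict(self, X_new: pd.DataFrame) -> np.ndarray:
        """Predictions on the model's (possibly transformed) target scale."""
        if isinstance(X_new, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in X_new.columns]
            if missing:
                raise ValidationError(f"missing features: {missing}")
            X_new = X_new[self.feature_names]
        arr = np.asarray(X_new, dtype=float)
        if arr.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"expected {len(self.feature_names)} features, got {arr.shape[1]}"
            )
        pred = np.asarray(self.estimator.predict(arr), dtype=float)
        if not np.isfinite(pred).all():
            raise ValidationError("non-finite predictions")
        return pred


def _extract_importances(algorithm: str, estimator, names: list[str]) -> dict[str, float]:
    if algorithm in ("LASSO", "MLR") and hasattr(estimator, "coef_"):
        vals = np.abs(np.ravel(estimator.coef_))
    elif hasattr(estimator, "feature_importances_"):
        vals = np.asarray(estimator.feature_importances_, dtype=float)
    else:
        return {}
    return {n: float(v) for n, v in zip(names, vals)}


def grid_search(
    config: ModelConfig,
    X: pd.DataFrame,
    y,
    folds: int = 10,
    fold_seed: int | None = None,
) -> FittedModel:
    """Exhaustive grid search minimizing k-fold cross-validated RMSE.

    Every grid point is scored on the same seeded fold assignment; the point
    with the lowest mean fold RMSE is refit on all of ``(X, y)``. Ties keep
    the earlier point in grid order. Folds whose training targets are
    constant are skipped with a warning.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < folds:
        raise ValidationError(f"n={n} < folds={folds}")
    names = list(X.columns)
    vals = X.to_numpy(dtype=float)
    seed = config.seed if fold_seed is None else fold_seed
    assignment = cv_folds(n, folds, seed)
    points = config.grid_points()

    best = None  # (mean_rmse, order, params, mean_r2)
    for order, params in enumerate(points):
        fold_rmse, fold_r2 = [], []
        for i in range(len(assignment)):
            tr, te = train_test_from_folds(assignment, i, n)
            if np.ptp(y[tr]) == 0:
                warnings.warn(
                    f"grid_search: fold {i} has constant training target; skipped",
                    stacklevel=2,
                )
                continue
            est = make_estimator(config.algorithm, params, p, config.seed)
            est.fit(vals[tr], y[tr])
            pred = est.predict(vals[te])
            fold_rmse.append(rmse(y[te], pred))
            if len(te) >= 2 and np.ptp(y[te]) > 0:
                fold_r2.append(r2(y[te], pred))
        if not fold_rmse:
            raise ValidationError("all CV folds degenerate")
        mean_rmse = float(np.mean(fold_rmse))
        mean_r2 = float(np.mean(fold_r2)) if fold_r2 else float("nan")
        if best is None or mean_rmse < best[0]:
            best = (mean_rmse, order, params, mean_r2)

    _, _, chosen, mean_r2 = best
    est = make_estimator(config.algorithm, chosen, p, config.seed)
    est.fit(vals, y)
    return FittedModel(
        config=config,
        chosen_hyperparameters=chosen,
        cv_rmse=best[0],
        cv_r2=mean_r2,
        feature_names=names,
        estimator=est,
        importances=_extract_importances(config.algorithm, est, names),
    )


def fit_predict(
    model: FittedModel, X_new: pd.DataFrame, transform: str = "none"
) -> tuple[np.ndarray, np.ndarray]:
    """Predict on the modeling scale and in back-transformed minutes.

    Returns ``(pred_transformed, pred_minutes)``; the two coincide when no
    target transform is in effect.
    """
    pred = model.predict(X_new)
    if transform == "log":
        return pred, np.exp(pred)
    if transform == "none":
        return pred, pred.copy()
    raise ConfigurationError(f"unknown transform {transform!r}")


def embedded_importances(model: FittedModel, top_k: int = 20) -> list[str]:
    """Top features by a learner's intrinsic (embedded) selection.

    LASSO ranks its nonzero |coefficients|; RF and GBR rank impurity-based
    importances. MLR and SVR have no embedded selection and raise.
    """
    alg = model.config.algorithm
    if alg not in ("LASSO", "RF", "GBR"):
        raise UnsupportedMethodError(
            f"embedded importances unavailable for {alg}; use LASSO, RF or GBR"
        )
    imp = model.importances
    if alg == "LASSO":
        items = [(n, v) for n, v in imp.items() if v > 0.0]
    else:
        items = list(imp.items())
    items.sort(key=lambda t: (-t[1], t[0]))
    return [n for n, _ in items[:top_k]]
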