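"""Performance metrics, cross-validation folds, nested evaluation and model ranking.

Retention models are compared by RMSE and R² under k-fold cross-validation and
on a held-out external test set; per-condition performance tables are then
aggregated into a mean rank per model across pH conditions.
"""
from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ValidationError

__all__ = [
    "rmse",
    "r2",
    "cv_folds",
    "nested_cv",
    "rank_models",
]


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root-mean-squared error sqrt(mean (y - yhat)^2)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValidationError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise ValidationError("rmse requires finite inputs")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 - SSE/SST; may be negative.

    Raises
    ------
    ValidationError
        If ``y`` is constant (total sum of squares is zero) or inputs are
        shorter than 2.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValidationError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise ValidationError("r2 requires at least 2 observations")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise ValidationError("r2 requires finite inputs")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValidationError("r2 undefined for constant observed values")
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


def cv_folds(n: int, folds: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Seeded random partition of ``range(n)`` into ``folds`` disjoint folds.

    Fold sizes differ by at most one; the same ``seed`` always yields the
    same assignment.
    """
    if n < folds:
        raise ValidationError(f"n={n} smaller than number of folds={folds}")
    if folds < 2:
        raise ValidationError(f"folds={folds} must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def train_test_from_folds(folds_: Sequence[np.ndarray], i: int, n: int):
    """Indices (train, test) for fold ``i`` of a fold assignment."""
    test = folds_[i]
    mask = np.ones(n, dtype=bool)
    mask[test] = False
    return np.flatnonzero(mask), test


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    fit_fn: Callable[[np.ndarray, np.ndarray, int, int], object],
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
) -> dict:
    """Nested cross-validation of a self-tuning learner.

    ``fit_fn(X_train, y_train, inner_folds, seed)`` must return a fitted
    object with a ``predict`` method; any hyperparameter search it performs
    sees only the outer-training data it is handed. The outer loop estimates
    generalization RMSE/R² as the mean of per-fold metrics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    assignment = cv_folds(len(y), outer_folds, seed)
    fold_rmse, fold_r2 = [], []
    for i in range(len(assignment)):
        tr, te = train_test_from_folds(assignment, i, len(y))
        model = fit_fn(X[tr], y[tr], inner_folds, seed + 1 + i)
        pred = np.asarray(model.predict(X[te]), dtype=float)
        fold_rmse.append(rmse(y[te], pred))
        if np.ptp(y[te]) > 0 and len(te) >= 2:
            fold_r2.append(r2(y[te], pred))
    return {
        "rmse_cv": float(np.mean(fold_rmse)),
        "r2_cv": float(np.mean(fold_r2)) if fold_r2 else float("nan"),
        "fold_rmse": fold_rmse,
    }


def rank_models(
    tables: Mapping[object, pd.DataFrame] | Sequence[pd.DataFrame],
    metric: str = "RMSE_test",
) -> pd.DataFrame:
    """Rank models within each performance table and average ranks across tables.

    Rank 1 is the lowest value of ``metric`` (errors: lower is better); ties
    receive the average of the ranks they span. Returns a DataFrame with one
    rank column per table plus a ``mean_rank`` column, sorted by mean rank.
    """
    if not isinstance(tables, Mapping):
        tables = {i: t for i, t in enumerate(tables)}
    keys = None
    ranks = {}
    for name, table in tables.items():
        if metric not in table.columns:
            raise ValidationError(f"metric {metric!r} missing from table {name!r}")
        if keys is None:
            keys = list(table.index)
        elif set(table.index) != set(keys):
            raise ValidationError("performance tables have mismatched model keys")
        col = table.loc[keys, metric].to_numpy(dtype=float)
        ranks[f"rank_{name}"] = rankdata(col, method="average")
    out = pd.DataFrame(ranks, index=pd.Index(keys, name="model"))
    out["mean_rank"] = out.mean(axis=1)
    return out.sort_values(["mean_rank", "model"], kind="stable")
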