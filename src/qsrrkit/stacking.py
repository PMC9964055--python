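"""Two-level stacked regression: base learners combined by a linear meta-model.

Level 1 holds the tuned base learners (each consuming its own feature
subset); level 2 is a multiple linear regression of the target on the base
learners' predictions, so the final prediction is
``intercept + sum_i w_i * base_i(x)``.

Two meta-training modes are provided. ``out_of_fold`` (default, leak-free)
regresses the training targets on cross-validated level-1 predictions: each
base learner is refit per fold with its chosen hyperparameters and predicts
its held-out fold. ``external`` instead trains the meta-model on level-1
predictions of the designated external test set; this reuses the evaluation
set for fitting and therefore yields optimistically biased external error —
a leakage warning is always emitted. It is retained only for fidelity
experiments with workflows that were defined that way.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .evaluation import cv_folds, train_test_from_folds
from .exceptions import ConfigurationError, ValidationError
from .models import FittedModel

__all__ = ["StackingModel", "stack_fit", "stack_predict", "LeakageWarning"]


class LeakageWarning(UserWarning):
    """The requested procedure lets evaluation data influence training."""


@dataclass
class StackingModel:
    """Meta-learner coefficients over an ordered lineup of base models."""

    base_keys: list[str]
    intercept: float
    weights: np.ndarray  # one per base model, in base_keys order
    mode: str = "out_of_fold"

    def __post_init__(self):
        if len(self.base_keys) == 0:
            raise ConfigurationError("base_keys must be nonempty")
        if len(set(self.base_keys)) != len(self.base_keys):
            raise ConfigurationError("base_keys must be unique")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.base_keys),):
            raise ConfigurationError("one meta weight required per base model")

    def to_json(self) -> str:
        return json.dumps(
            {
                "base_keys": self.base_keys,
                "intercept": self.intercept,
                "weights": self.weights.tolist(),
                "mode": self.mode,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "StackingModel":
        d = json.loads(text)
        return cls(
            base_keys=list(d["base_keys"]),
            intercept=float(d["intercept"]),
            weights=np.asarray(d["weights"], dtype=float),
            mode=d.get("mode", "out_of_fold"),
        )


def _level1_matrix(
    base_models: Mapping[str, FittedModel], keys: list[str], X: pd.DataFrame
) -> np.ndarray:
    cols = [base_models[k].predict(X) for k in keys]
    return np.column_stack(cols)


def _meta_fit(
    Z: np.ndarray, y: np.ndarray, solver: str = "nnls"
) -> tuple[float, np.ndarray]:
    """Linear meta fit with free intercept.

    ``solver="nnls"`` (default) constrains the base-model weights to be
    non-negative — the standard stabilization for stacked regressions,
    whose base predictions are strongly collinear. ``solver="ols"`` is the
    unconstrained least-squares fit; rank-deficient designs fall back to
    the minimum-norm solution with a warning.
    """
    if solver == "nnls":
        zbar = Z.mean(axis=0)
        ybar = float(y.mean())
        w, _ = nnls(Z - zbar, y - ybar)
        return ybar - float(zbar @ w), w
    if solver != "ols":
        raise ConfigurationError(f"meta solver must be 'nnls' or 'ols', got {solver!r}")
    A = np.column_stack([np.ones(len(Z)), Z])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(
            "collinear base predictions: meta coefficients are the "
            "minimum-norm solution and individually non-identifiable",
            stacklevel=3,
        )
    return float(coef[0]), coef[1:]


def stack_fit(
    base_models: Mapping[str, FittedModel],
    X: pd.DataFrame,
    y,
    mode: str = "out_of_fold",
    folds: int = 10,
    seed: int = 0,
    external: tuple[pd.DataFrame, np.ndarray] | None = None,
    return_oof: bool = False,
    meta_solver: str = "nnls",
    n_repeats: int = 1,
    select_features=None,
) -> StackingModel:
    """Fit the linear meta-learner over the given base models.

    ``X``/``y`` are the training compounds (full feature space; each base
    model selects its own columns). In ``external`` mode the meta-model is
    fit on level-1 predictions of ``external=(X_ext, y_ext)`` instead, with
    a :class:`LeakageWarning`.

    With ``return_oof=True`` returns ``(stack, Z)`` where ``Z`` is the
    level-1 prediction matrix the meta-learner was fit on (out-of-fold
    predictions of the training compounds in ``out_of_fold`` mode).

    Base models whose features were chosen by a data-driven selector must
    have the selection repeated inside each fold, or their out-of-fold
    predictions are optimistically biased and the meta-learner overweights
    them. ``select_features(X_fold, y_fold, seed) -> {source: [names]}``
    re-runs the selectors on each fold's training part; base models then
    consume the feature list for their ``config.feature_source`` (models
    with source ``"all"`` keep their original columns).
    """
    keys = sorted(base_models)
    if len(keys) < 2 and mode == "out_of_fold":
        pass  # a single base model is allowed; the meta fit is then trivial
    y = np.asarray(y, dtype=float)

    if mode == "out_of_fold":
        n = len(y)
        reps = []
        for rep in range(n_repeats):
            assignment = cv_folds(n, folds, seed + rep)
            Zr = np.full((n, len(keys)), np.nan)
            for i in range(len(assignment)):
                tr, te = train_test_from_folds(assignment, i, n)
                fold_feats = (
                    select_features(X.iloc[tr], y[tr], seed + 31 * rep + i)
                    if select_features is not None
                    else None
                )
                for j, key in enumerate(keys):
                    fm = base_models[key]
                    source = fm.config.feature_source
                    if fold_feats is not None and source in fold_feats:
                        sub = X[fold_feats[source]]
                    else:
                        sub = X[fm.feature_names]
                    refit = fm.refit(sub.iloc[tr], y[tr])
                    Zr[te, j] = refit.predict(sub.iloc[te])
            if np.isnan(Zr).any():
                raise ValidationError("incomplete out-of-fold prediction matrix")
            reps.append(Zr)
        # averaging over repeated fold assignments reduces the variance of
        # the level-1 matrix, and with it the meta-learner's selection noise
        Z = np.mean(reps, axis=0)
        intercept, weights = _meta_fit(Z, y, meta_solver)
    elif mode == "external":
        if external is None:
            raise ConfigurationError("external mode requires external=(X_ext, y_ext)")
        warnings.warn(
            "meta-learner trained on the external evaluation set: external "
            "error estimates for the stack will be optimistically biased",
            LeakageWarning,
            stacklevel=2,
        )
        X_ext, y_ext = external
        Z = _level1_matrix(base_models, keys, X_ext)
        intercept, weights = _meta_fit(Z, np.asarray(y_ext, dtype=float), meta_solver)
    else:
        raise ConfigurationError(
            f"mode must be 'out_of_fold' or 'external', got {mode!r}"
        )
    stack = StackingModel(base_keys=keys, intercept=intercept, weights=weights, mode=mode)
    return (stack, Z) if return_oof else stack


def stack_predict(
    stack: StackingModel,
    base_models: Mapping[str, FittedModel],
    X_new: pd.DataFrame,
) -> np.ndarray:
    """``intercept + sum_i w_i * base_i(X_new)`` on the modeling scale."""
    missing = [k for k in stack.base_keys if k not in base_models]
    if missing:
        raise ValidationError(f"base models missing from registry: {missing}")
    Z = _level1_matrix(base_models, stack.base_keys, X_new)
    return stack.intercept + Z @ stack.weights
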