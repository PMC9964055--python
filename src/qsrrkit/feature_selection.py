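"""Filter, wrapper and embedded feature selection for retention modeling.

Three selector families are provided:

* **CFS** (correlation-based feature selection): greedy forward search on
  Hall's merit ``M(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)``, which rewards
  subsets whose members correlate with retention but not with each other —
  the natural filter for strongly collinear descriptor blocks. A plain
  ``|cor(x, y)| >= tau`` threshold filter is available as an alternative.
* **RFE** (recursive feature elimination): a wrapper that recursively drops
  the lowest-ranked features down a grid of candidate subset sizes and picks
  the size with the lowest cross-validated RMSE (ties favor the smaller
  size). Ranking uses |coefficients| for linear learners and seeded
  permutation importance otherwise.
* **Embedded support identification**: the features a sparse penalized fit
  keeps. :func:`lasso_support` exposes the penalty-choice rule — CV-minimum,
  the 1-SE rule, BIC, or the adaptive LASSO (ridge-pilot weights + BIC),
  which is the selection-consistent choice and the package default for
  support recovery.

All tie-breaking is lexicographic by feature name so results are
reproducible under a fixed seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LassoLarsIC, LinearRegression, Ridge, Lasso

from .evaluation import cv_folds, rmse, train_test_from_folds
from .exceptions import ValidationError

__all__ = [
    "SelectionResult",
    "cfs_select",
    "correlation_threshold_select",
    "rfe_select",
    "lasso_support",
    "consensus_features",
]


@dataclass
class SelectionResult:
    """A selector's chosen feature subset with per-feature scores."""

    method: str  # "cfs" | "rfe" | "embedded"
    selected: list[str]
    scores: dict[str, float]
    settings: dict = field(default_factory=dict)

    def top(self, k: int) -> list[str]:
        """The ``k`` highest-scoring selected features (name-tiebroken)."""
        order = sorted(self.selected, key=lambda f: (-self.scores.get(f, 0.0), f))
        return order[:k]


def _check_Xy(X: pd.DataFrame, y) -> tuple[pd.DataFrame, np.ndarray]:
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValidationError("X and y lengths differ")
    return X, y


def cfs_merit(k: int, mean_rcf: float, mean_rff: float) -> float:
    """Hall's merit of a k-feature subset."""
    return k * mean_rcf / np.sqrt(k + k * (k - 1) * mean_rff)


def cfs_select(
    X: pd.DataFrame, y, max_features: int | None = None
) -> SelectionResult:
    """Correlation-based feature selection by greedy forward search.

    Starting empty, repeatedly adds the feature that most increases the
    merit; stops when no candidate strictly increases it (or at
    ``max_features``). Candidate ties break lexicographically by name.
    """
    X, y = _check_Xy(X, y)
    if X.shape[1] < 1:
        raise ValidationError("cfs_select requires at least one feature")
    if np.ptp(y) == 0:
        raise ValidationError("cfs_select: constant y, correlation undefined")
    names = list(X.columns)
    vals = X.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        rcf = np.abs(
            np.array(
                [
                    np.corrcoef(vals[:, j], y)[0, 1] if np.ptp(vals[:, j]) > 0 else 0.0
                    for j in range(len(names))
                ]
            )
        )
    rcf = np.nan_to_num(rcf)
    # pairwise |cor| among features, computed lazily per candidate evaluation
    corr_cache: dict[tuple[int, int], float] = {}

    def ff(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in corr_cache:
            a, b = vals[:, key[0]], vals[:, key[1]]
            c = np.corrcoef(a, b)[0, 1] if np.ptp(a) > 0 and np.ptp(b) > 0 else 0.0
            corr_cache[key] = abs(float(np.nan_to_num(c)))
        return corr_cache[key]

    selected: list[int] = []
    merits: dict[str, float] = {}
    current = 0.0
    limit = max_features if max_features is not None else len(names)
    order = sorted(range(len(names)), key=lambda j: names[j])
    while len(selected) < limit:
        best_j, best_merit = None, current
        for j in order:
            if j in selected:
                continue
            k = len(selected) + 1
            mean_rcf = (rcf[selected].sum() + rcf[j]) / k
            if k == 1:
                mean_rff = 0.0
            else:
                pair_sum = sum(ff(a, b) for ai, a in enumerate(selected) for b in selected[ai + 1 :])
                pair_sum += sum(ff(a, j) for a in selected)
                mean_rff = pair_sum / (k * (k - 1) / 2)
            m = cfs_merit(k, mean_rcf, mean_rff)
            if m > best_merit + 1e-12:
                best_j, best_merit = j, m
        if best_j is None:
            break
        selected.append(best_j)
        current = best_merit
        merits[names[best_j]] = float(best_merit)
    if not selected:  # degenerate: keep the single best-correlated feature
        j = int(np.argmax(rcf))
        selected = [j]
        merits[names[j]] = float(rcf[j])
    return SelectionResult(
        method="cfs",
        selected=[names[j] for j in selected],
        scores=merits,
        settings={"max_features": max_features},
    )


def correlation_threshold_select(
    X: pd.DataFrame, y, tau: float = 0.3
) -> SelectionResult:
    """Plain filter: keep features with ``|cor(x, y)| >= tau``."""
    X, y = _check_Xy(X, y)
    if np.ptp(y) == 0:
        raise ValidationError("constant y, correlation undefined")
    scores = {}
    for name in X.columns:
        col = X[name].to_numpy(dtype=float)
        c = np.corrcoef(col, y)[0, 1] if np.ptp(col) > 0 else 0.0
        scores[name] = abs(float(np.nan_to_num(c)))
    selected = sorted(
        [n for n, s in scores.items() if s >= tau],
        key=lambda n: (-scores[n], n),
    )
    return SelectionResult(
        method="cfs",
        selected=selected,
        scores={n: scores[n] for n in selected},
        settings={"tau": tau, "variant": "threshold"},
    )


def _rank_features(estimator, X: np.ndarray, y: np.ndarray, seed: int, names):
    """Feature order worst-first is NOT returned; returns importance scores."""
    est = clone(estimator)
    est.fit(X, y)
    if hasattr(est, "coef_"):
        imp = np.abs(np.ravel(est.coef_))
    elif hasattr(est, "feature_importances_"):
        imp = np.asarray(est.feature_importances_, dtype=float)
    else:
        res = permutation_importance(
            est, X, y, n_repeats=10, random_state=seed, scoring="neg_root_mean_squared_error"
        )
        imp = np.asarray(res.importances_mean, dtype=float)
    return imp


def _recursive_subsets(
    estimator, X: np.ndarray, y: np.ndarray, sizes: list[int], seed: int, names
) -> dict[int, np.ndarray]:
    """Feature index sets at each candidate size by recursive elimination."""
    current = np.arange(X.shape[1])
    out: dict[int, np.ndarray] = {}
    for size in sorted(sizes, reverse=True):
        if size < len(current):
            imp = _rank_features(estimator, X[:, current], y, seed, None)
            # keep the `size` most important; ties lexicographic by name
            order = sorted(
                range(len(current)), key=lambda i: (-imp[i], names[current[i]])
            )
            current = np.sort(current[np.array(order[:size], dtype=int)])
        out[size] = current.copy()
    return out


def rfe_select(
    X: pd.DataFrame,
    y,
    learner=None,
    subset_sizes: Sequence[int] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Recursive feature elimination with cross-validated size choice.

    For each fold, features are recursively dropped (on the training part
    only) to each candidate size and the held-out RMSE recorded; the size
    with the lowest mean CV RMSE wins, ties going to the smaller size. The
    final subset is obtained by re-running the elimination on all data at
    the winning size.
    """
    X, y = _check_Xy(X, y)
    p = X.shape[1]
    names = list(X.columns)
    if learner is None:
        learner = LinearRegression()
    if subset_sizes is None:
        subset_sizes = sorted({max(1, p // 8), max(1, p // 4), max(1, p // 2), p})
    sizes = sorted(set(int(s) for s in subset_sizes))
    if any(s < 1 or s > p for s in sizes):
        raise ValidationError(f"subset sizes {sizes} outside [1, {p}]")
    if p == 1:
        return SelectionResult(
            method="rfe",
            selected=names,
            scores={names[0]: 1.0},
            settings={"subset_sizes": sizes, "chosen_size": 1},
        )

    vals = X.to_numpy(dtype=float)
    assignment = cv_folds(len(y), folds, seed)
    cv_err = {s: [] for s in sizes}
    for i in range(len(assignment)):
        tr, te = train_test_from_folds(assignment, i, len(y))
        subsets = _recursive_subsets(learner, vals[tr], y[tr], sizes, seed + i, names)
        for s, idx in subsets.items():
            est = clone(learner)
            est.fit(vals[np.ix_(tr, idx)], y[tr])
            cv_err[s].append(rmse(y[te], est.predict(vals[np.ix_(te, idx)])))
    profile = {s: float(np.mean(cv_err[s])) for s in sizes}
    chosen = min(sizes, key=lambda s: (profile[s], s))

    subsets = _recursive_subsets(learner, vals, y, sizes, seed, names)
    idx = subsets[chosen]
    imp = _rank_features(learner, vals[:, idx], y, seed, None)
    selected = [names[j] for j in idx]
    return SelectionResult(
        method="rfe",
        selected=selected,
        scores={names[j]: float(v) for j, v in zip(idx, imp)},
        settings={
            "subset_sizes": sizes,
            "chosen_size": int(chosen),
            "cv_rmse_profile": profile,
            "folds": folds,
            "seed": seed,
        },
    )


def lasso_support(
    X: pd.DataFrame,
    y,
    rule: str = "adaptive",
    lambdas: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Support identification with an L1-penalized fit.

    ``rule`` chooses the penalty: ``"cv"`` (CV-minimum RMSE), ``"1se"``
    (largest penalty within one standard error of the CV minimum),
    ``"bic"`` (LARS path, BIC), or ``"adaptive"`` (default): a ridge pilot
    fit supplies weights ``1/|beta_pilot|`` and the reweighted LASSO penalty
    is chosen by BIC — the selection-consistent variant.
    """
    X, y = _check_Xy(X, y)
    names = list(X.columns)
    vals = X.to_numpy(dtype=float)
    if rule in ("cv", "1se"):
        if lambdas is None:
            lambdas = np.logspace(-4, 1, 25)
        assignment = cv_folds(len(y), folds, seed)
        stats = []
        for lam in lambdas:
            errs = []
            for i in range(len(assignment)):
                tr, te = train_test_from_folds(assignment, i, len(y))
                est = Lasso(alpha=float(lam), max_iter=50000).fit(vals[tr], y[tr])
                errs.append(rmse(y[te], est.predict(vals[te])))
            stats.append((float(np.mean(errs)), float(np.std(errs, ddof=1) / np.sqrt(len(errs)))))
        means = np.array([m for m, _ in stats])
        best = int(np.argmin(means))
        if rule == "1se":
            limit = means[best] + stats[best][1]
            ok = np.flatnonzero(means <= limit)
            best = int(ok[np.argmax(np.asarray(lambdas)[ok])])
        est = Lasso(alpha=float(lambdas[best]), max_iter=50000).fit(vals, y)
        coef = est.coef_
        settings = {"rule": rule, "lambda": float(lambdas[best])}
    elif rule == "bic":
        est = LassoLarsIC(criterion="bic").fit(vals, y)
        coef = est.coef_
        settings = {"rule": rule, "lambda": float(est.alpha_)}
    elif rule == "adaptive":
        pilot = Ridge(alpha=1.0).fit(vals, y).coef_
        w = 1.0 / np.maximum(np.abs(pilot), 1e-8)
        est = LassoLarsIC(criterion="bic").fit(vals / w, y)
        coef = est.coef_ / w
        settings = {"rule": rule, "lambda": float(est.alpha_)}
    else:
        raise ValidationError(f"unknown lasso_support rule {rule!r}")
    idx = np.flatnonzero(np.abs(coef) > 0)
    order = sorted(idx, key=lambda j: (-abs(coef[j]), names[j]))
    return SelectionResult(
        method="embedded",
        selected=[names[j] for j in order],
        scores={names[j]: float(abs(coef[j])) for j in order},
        settings=settings,
    )


def consensus_features(
    results: Sequence[SelectionResult], embedded_top_k: int = 20
) -> list[str]:
    """Features chosen by *every* selector (embedded lists truncated to top-k).

    Returns the sorted intersection; an empty intersection produces a warning
    and an empty list, not an error.
    """
    if len(results) < 2:
        raise ValidationError("consensus requires at least 2 selection results")
    sets = []
    for res in results:
        feats = res.top(embedded_top_k) if res.method == "embedded" else res.selected
        sets.append(set(feats))
    common = set.intersection(*sets)
    if not common:
        warnings.warn("consensus_features: empty intersection", stacklevel=2)
    return sorted(common)
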