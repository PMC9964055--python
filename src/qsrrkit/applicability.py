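"""k-nearest-neighbor applicability domain (fixed-k variant).

A query compound's AD statistic is the mean Euclidean distance to its k
nearest training compounds in the standardized descriptor space. The domain
threshold is a percentile (default 95th) of the training compounds' own
mean kNN distances, computed leave-self-out so that k = 1 does not collapse
to zero. A query is flagged ``Out`` iff its statistic strictly exceeds the
threshold; a distance exactly equal to the threshold is ``In``.

Percentiles use linear interpolation between order statistics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .exceptions import ConfigurationError, ValidationError

__all__ = ["ADConfig", "ad_distances", "ad_threshold", "ad_classify", "ad_report"]


@dataclass(frozen=True)
class ADConfig:
    """Neighbor count, threshold percentile and feature space of the AD."""

    k: int = 5
    percentile: float = 95.0
    feature_space: str = "all"  # "all" | "selected"

    def validate(self, n_train: int | None = None) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if n_train is not None and self.k >= n_train:
            raise ConfigurationError(f"k={self.k} must be < n_train={n_train}")
        if not (0.0 < self.percentile < 100.0):
            raise ConfigurationError("percentile must be in (0, 100)")
        if self.feature_space not in ("all", "selected"):
            raise ConfigurationError("feature_space must be 'all' or 'selected'")


def _as_array(X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D matrix")
    if not np.isfinite(arr).all():
        raise ValidationError("non-finite values in descriptor matrix")
    return arr


def ad_distances(train_X, query_X=None, k: int = 5) -> np.ndarray:
    """Mean Euclidean distance of each query row to its k nearest training rows.

    With ``query_X=None`` the training rows are scored against their own set
    with the self-distance excluded (leave-self-out).
    """
    train = _as_array(train_X)
    n_train = len(train)
    self_mode = query_X is None
    if isinstance(query_X, pd.DataFrame) and isinstance(train_X, pd.DataFrame):
        if list(query_X.columns) != list(train_X.columns):
            raise ValidationError("train and query feature names differ")
    query = train if self_mode else _as_array(query_X)
    if query.shape[1] != train.shape[1]:
        raise ValidationError("train and query feature counts differ")
    max_k = n_train - 1 if self_mode else n_train
    if k >= n_train:
        raise ValidationError(f"k={k} must be < n_train={n_train}")
    if k > max_k:
        raise ValidationError(f"k={k} exceeds available neighbors ({max_k})")
    D = cdist(query, train)
    if self_mode:
        np.fill_diagonal(D, np.inf)
    D.sort(axis=1)
    return D[:, :k].mean(axis=1)


def ad_threshold(train_X, k: int = 5, percentile: float = 95.0) -> float:
    """Percentile of the training set's own (leave-self-out) mean kNN distances."""
    if not (0.0 < percentile <= 100.0):
        raise ConfigurationError("percentile must be in (0, 100]")
    own = ad_distances(train_X, None, k)
    return float(np.percentile(own, percentile))  # linear interpolation


def ad_classify(distances, threshold: float) -> np.ndarray:
    """``"Out"`` iff distance strictly exceeds the threshold, else ``"In"``."""
    d = np.asarray(distances, dtype=float)
    if not (np.isfinite(d).all() and np.isfinite(threshold)):
        raise ValidationError("non-finite distances or threshold")
    return np.where(d > threshold, "Out", "In")


def ad_report(
    train_by_ph: dict[float, pd.DataFrame],
    query_by_ph: dict[float, pd.DataFrame],
    errors_by_ph: dict[float, pd.Series] | None = None,
    k: int = 5,
    percentile: float = 95.0,
    aggregate: str = "any",
) -> pd.DataFrame:
    """Per-compound AD table across pH conditions.

    One row per query compound with, per pH, the prediction error in minutes
    (if supplied), the mean kNN distance and the In/Out flag; a final
    ``Threshold`` row carries the per-pH thresholds, and an ``Applicability``
    column aggregates the per-pH flags (``aggregate="any"``: Out at any pH
    ⇒ Out; ``"all"``: Out only if out at every pH).
    """
    if aggregate not in ("any", "all"):
        raise ConfigurationError("aggregate must be 'any' or 'all'")
    if set(train_by_ph) != set(query_by_ph):
        raise ValidationError("train and query pH sets differ")
    phs = sorted(train_by_ph)
    index = query_by_ph[phs[0]].index
    out = pd.DataFrame(index=index.append(pd.Index(["Threshold"])))
    out.index.name = "compound"
    flags = []
    for ph in phs:
        train, query = train_by_ph[ph], query_by_ph[ph]
        if not query.index.equals(index):
            raise ValidationError("query compound sets differ across pH")
        dist = ad_distances(train, query, k)
        thr = ad_threshold(train, k, percentile)
        flag = ad_classify(dist, thr)
        flags.append(flag == "Out")
        if errors_by_ph is not None:
            out[f"Error_pH{ph:g}"] = list(errors_by_ph[ph].loc[index]) + [np.nan]
        out[f"Distance_pH{ph:g}"] = list(dist) + [thr]
        out[f"Flag_pH{ph:g}"] = list(flag) + [""]
    outmat = np.column_stack(flags)
    agg = outmat.any(axis=1) if aggregate == "any" else outmat.all(axis=1)
    out["Applicability"] = [("Out" if a else "In") for a in agg] + [""]
    return out
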