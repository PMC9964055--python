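"""Data cleaning, standardization and the modeling / external-test split.

Cleaning rules: compounds retained below 2 min at *every* pH are removed
(they elute near the dead time and carry no usable retention signal), and
descriptors with zero variance are dropped. Features are then standardized
to mean 0 / sd 1 with parameters learned on the training compounds only;
the external test set is transformed with the training parameters so it can
never influence them.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "rt_columns",
    "filter_low_retention",
    "remove_zero_variance",
    "standardize",
    "split",
    "SplitDataset",
]

logger = logging.getLogger(__name__)

_RT_RE = re.compile(r"^rt_pH(?P<ph>[0-9.]+)$")


def rt_columns(table: pd.DataFrame) -> dict[float, str]:
    """Map pH value -> retention column name (``rt_pH<value>`` convention)."""
    out = {}
    for col in table.columns:
        m = _RT_RE.match(col)
        if m:
            out[float(m.group("ph"))] = col
    if not out:
        raise ValidationError("no retention columns (rt_pH<value>) found")
    return dict(sorted(out.items()))


def filter_low_retention(
    table: pd.DataFrame, threshold: float = 2.0
) -> pd.DataFrame:
    """Drop compounds whose retention is below ``threshold`` at every pH.

    The rule is conjunctive over pH: a compound below the threshold at some
    conditions but not all of them is retained. Survivor order is preserved.
    """
    cols = rt_columns(table)
    for ph, col in cols.items():
        bad = table[col].isna()
        if bad.any():
            cid = table.loc[bad].iloc[0].get("id", table.index[bad][0])
            raise ValidationError(
                f"missing retention for compound {cid!r} at pH {ph:g}"
            )
    below_everywhere = (table[list(cols.values())] < threshold).all(axis=1)
    dropped = table.loc[below_everywhere]
    if len(dropped):
        logger.info(
            "filter_low_retention: removed %d compounds below %.3g min at all pH",
            len(dropped),
            threshold,
        )
    return table.loc[~below_everywhere].copy()


def remove_zero_variance(X: pd.DataFrame) -> pd.DataFrame:
    """Drop descriptor columns that are exactly constant."""
    if X.shape[1] == 0:
        raise ValidationError("descriptor matrix has no columns")
    values = X.to_numpy()
    constant = (values == values[0:1, :]).all(axis=0)
    dropped = [name for name, c in zip(X.columns, constant) if c]
    if len(dropped) == X.shape[1]:
        raise ValidationError("all descriptor columns have zero variance")
    if dropped:
        logger.info("remove_zero_variance: dropped %s", dropped)
    return X.loc[:, [c for c in X.columns if c not in set(dropped)]].copy()


def standardize(
    train_X: pd.DataFrame, test_X: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame]:
    """Center/scale to mean 0, sd 1 using training statistics only.

    Returns ``(train_std, test_std, scaler_params)`` where ``scaler_params``
    is a DataFrame with ``mean`` and ``sd`` rows. The test matrix (if given)
    is transformed with the TRAIN parameters. The sd uses the 1/n convention,
    so standardized training columns have unit population variance.
    """
    mean = train_X.mean(axis=0)
    sd = train_X.std(axis=0, ddof=0)
    zero = sd[sd == 0.0]
    if len(zero):
        raise ValidationError(
            f"zero standard deviation in columns {list(zero.index)}; "
            "run remove_zero_variance first"
        )
    params = pd.DataFrame({"mean": mean, "sd": sd}).T
    train_std = (train_X - mean) / sd
    test_std = None
    if test_X is not None:
        if list(test_X.columns) != list(train_X.columns):
            raise ValidationError("train/test feature names differ")
        test_std = (test_X - mean) / sd
    return train_std, test_std, params


@dataclass
class SplitDataset:
    """One pH condition's modeling/external-test split.

    ``train_X``/``test_X`` are descriptor DataFrames (standardized once
    :func:`standardize` has been applied), ``train_y``/``test_y`` retention
    values possibly on a transformed scale named by ``transform``.
    """

    ph: float
    train_X: pd.DataFrame
    train_y: pd.Series
    test_X: pd.DataFrame
    test_y: pd.Series
    transform: str = "none"
    scaler_params: pd.DataFrame | None = None

    def validate(self) -> None:
        overlap = set(self.train_X.index) & set(self.test_X.index)
        if overlap:
            raise ValidationError(f"train/test compounds overlap: {sorted(overlap)}")
        if list(self.train_X.columns) != list(self.test_X.columns):
            raise ValidationError("train/test feature names differ")


def _stratified_test_ids(
    table: pd.DataFrame, n_test: int, seed: int, n_strata: int = 4
) -> list:
    cols = list(rt_columns(table).values())
    mean_rt = table[cols].mean(axis=1)
    ranks = mean_rt.rank(method="first")
    strata = pd.qcut(ranks, q=n_strata, labels=False)
    rng = np.random.default_rng(seed)
    counts = np.bincount(strata, minlength=n_strata)
    exact = counts * n_test / len(table)
    alloc = np.floor(exact).astype(int)
    remainder = exact - alloc
    for idx in np.argsort(-remainder, kind="stable")[: n_test - alloc.sum()]:
        alloc[idx] += 1
    chosen = []
    for s in range(n_strata):
        members = table.index[strata == s].to_numpy()
        take = min(alloc[s], len(members))
        if take:
            chosen.extend(rng.choice(members, size=take, replace=False))
    return sorted(chosen)


def split(
    table: pd.DataFrame,
    matrices: Mapping[float, pd.DataFrame],
    n_test: int = 10,
    seed: int = 0,
    stratify: bool = False,
    force_test_ids: Sequence = (),
) -> dict[float, SplitDataset]:
    """Split compounds into modeling and external-test sets, shared across pH.

    The same ``n_test`` compounds form the external test set at every pH;
    membership is a seeded random draw, optionally stratified on retention
    quartiles (quartiles of the mean retention over pH, test counts within
    ±1 of proportional allocation). Ids in ``force_test_ids`` (those still
    present after filtering) are placed in the test set first; the remaining
    slots are drawn randomly.
    """
    n = len(table)
    if not (0 < n_test < n):
        raise ValidationError(f"n_test={n_test} must be in (0, {n})")
    cols = rt_columns(table)
    ids = table["id"].tolist() if "id" in table.columns else list(table.index)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate compound ids")
    indexed = table.set_index(pd.Index(ids, name="id"))
    forced = [i for i in ids if i in set(force_test_ids)]
    if len(forced) > n_test:
        raise ValidationError(
            f"{len(forced)} forced test compounds exceed n_test={n_test}"
        )
    remaining = n_test - len(forced)
    pool = [i for i in ids if i not in set(forced)]
    if stratify and remaining:
        drawn = _stratified_test_ids(indexed.loc[pool], remaining, seed)
    elif remaining:
        rng = np.random.default_rng(seed)
        drawn = list(rng.choice(np.asarray(pool, dtype=object), size=remaining, replace=False))
    else:
        drawn = []
    test_set = set(forced) | set(drawn)
    train_ids = [i for i in ids if i not in test_set]
    test_ids = [i for i in ids if i in test_set]

    out: dict[float, SplitDataset] = {}
    for ph, col in cols.items():
        if ph not in matrices:
            raise ValidationError(f"no descriptor matrix for pH {ph:g}")
        X = matrices[ph]
        missing = [i for i in ids if i not in X.index]
        if missing:
            raise ValidationError(
                f"descriptor matrix at pH {ph:g} missing compounds {missing[:5]}"
            )
        ds = SplitDataset(
            ph=ph,
            train_X=X.loc[train_ids].copy(),
            train_y=indexed.loc[train_ids, col].astype(float),
            test_X=X.loc[test_ids].copy(),
            test_y=indexed.loc[test_ids, col].astype(float),
        )
        ds.validate()
        out[ph] = ds
    return out
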