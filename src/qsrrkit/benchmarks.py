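"""Reusable synthetic benchmarks for the pipeline's statistical claims.

Each function runs a seeded simulation study and returns plain numbers, so
the same code backs both the test suite and the reproduction script:

* :func:`support_recovery` — can the wrapper (RFE) and embedded (adaptive
  LASSO) selectors recover the true sparse support of a linear signal?
* :func:`stacking_gain` — does the out-of-fold stacked ensemble match or
  beat the best single base model on external data?
* :func:`ad_rates` — does the kNN applicability domain flag far-out
  structural outliers while keeping the false-alarm rate on in-distribution
  queries near its nominal level?

Problem sizes are chosen so each study runs in minutes on one CPU; they are
stated in the package documentation.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .applicability import ad_classify, ad_distances, ad_threshold
from .evaluation import rmse
from .feature_selection import lasso_support, rfe_select
from .models import MODEL_REGISTRY, ModelConfig, grid_search
from .preprocess import filter_low_retention, remove_zero_variance, split, standardize
from .stacking import stack_fit, stack_predict
from .synthetic import SimulationConfig, generate

__all__ = ["sparse_linear_data", "support_recovery", "stacking_gain", "ad_rates"]


def sparse_linear_data(
    seed: int, n: int = 500, p: int = 100, n_true: int = 5, snr: float = 4.0
):
    """Independent-Gaussian design with a sparse linear signal at a given SNR.

    ``snr`` is var(signal)/var(noise). Returns ``(X, y, true_support)`` with
    X a DataFrame so selectors see feature names.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:n_true] = rng.uniform(0.5, 1.5, n_true) * rng.choice([-1.0, 1.0], n_true)
    f = X @ beta
    sigma = float(f.std()) / np.sqrt(snr)
    y = f + rng.normal(0.0, sigma, n)
    names = [f"x{i:03d}" for i in range(p)]
    return pd.DataFrame(X, columns=names), y, set(names[:n_true])


def _precision_recall(selected, true_support):
    sel = set(selected)
    if not sel:
        return 0.0, 0.0
    tp = len(sel & true_support)
    return tp / len(sel), tp / len(true_support)


def support_recovery(
    n_seeds: int = 20,
    seed: int = 0,
    n: int = 500,
    p: int = 100,
    n_true: int = 5,
    snr: float = 4.0,
) -> dict[str, float]:
    """Median support precision/recall of RFE and adaptive-LASSO selection.

    RFE searches the size grid (1, 2, 5, 10, 20, 50) with a linear-model
    ranking; embedded selection is the adaptive LASSO (ridge pilot + BIC).
    """
    recs = {"rfe": [], "lasso": []}
    for r in range(n_seeds):
        X, y, true = sparse_linear_data(seed + r, n=n, p=p, n_true=n_true, snr=snr)
        rfe = rfe_select(X, y, subset_sizes=[1, 2, 5, 10, 20, 50], folds=10, seed=seed + r)
        recs["rfe"].append(_precision_recall(rfe.selected, true))
        las = lasso_support(X, y, rule="adaptive", seed=seed + r)
        recs["lasso"].append(_precision_recall(las.selected, true))
    out = {}
    for name, vals in recs.items():
        out[f"{name}_precision"] = float(np.median([a for a, _ in vals]))
        out[f"{name}_recall"] = float(np.median([b for _, b in vals]))
    return out


_STACK_GRIDS = {
    "MLR_RFE": {},
    "SVR_RFE": {"C": [1.0, 4.0], "gamma_factor": [1.0], "epsilon": [0.1]},
    "Lasso": {"alpha": [float(a) for a in np.logspace(-3, 0, 7)]},
    "RF": {"n_estimators": [100], "mtry": ["third"]},
    "GBM": {"n_estimators": [200], "max_depth": [2], "learning_rate": [0.05]},
}


def stacking_gain(
    n_replicates: int = 20,
    seed: int = 0,
    folds: int = 10,
    n_train: int = 67,
    n_repeats: int = 4,
    oof_folds: int = 5,
) -> dict[str, float]:
    """External-RMSE ratio of the out-of-fold stack to its best base model.

    One replicate: generate the default nonlinear synthetic benchmark
    (without planted outliers, which belong to the applicability-domain
    benchmarks), train on a study-sized modeling set (``n_train``
    compounds) at one pH condition, tune the five base learners, stack
    out-of-fold, and compare generalization RMSE. Generalization error is
    measured on a large fresh external draw from the same generative model
    (every generated compound not used for training, ~165 compounds) so the
    comparison reflects the models rather than external-set sampling noise.
    Returns the fraction of replicates with ``stack <= 1.05 x best base``
    and the median ratio.
    """
    ratios = []
    for r in range(n_replicates):
        sim = SimulationConfig(seed=seed + r, n_outliers=0, n_compounds=300)
        ds = generate(sim)
        ph = sim.ph_levels[r % len(sim.ph_levels)]
        table = filter_low_retention(ds.compound_table)
        ids = table["id"].tolist()
        X = remove_zero_variance(ds.descriptor_matrices[ph].loc[ids])
        sp = split(
            table,
            {q: X for q in sim.ph_levels},
            n_test=len(ids) - n_train,
            seed=seed + r,
        )[ph]
        y_tr = np.log(sp.train_y.to_numpy())
        y_te = np.log(sp.test_y.to_numpy())
        tr, te, _ = standardize(sp.train_X, sp.test_X)
        rfe = rfe_select(
            tr, y_tr, subset_sizes=[5, 10, 20, 40], folds=folds, seed=seed + r
        )
        feats = {"rfe": rfe.selected, "all": list(tr.columns)}
        models = {}
        ext_rmse = {}
        for key, grid in _STACK_GRIDS.items():
            algorithm, source = MODEL_REGISTRY[key]
            mc = ModelConfig(algorithm=algorithm, feature_source=source, grid=grid, seed=seed + r)
            fm = grid_search(mc, tr[feats[source]], y_tr, folds=folds, fold_seed=seed + r)
            models[key] = fm
            ext_rmse[key] = rmse(y_te, fm.predict(te[feats[source]]))
        def fold_select(Xf, yf, sd):
            res = rfe_select(Xf, yf, subset_sizes=[5, 10, 20, 40], folds=5, seed=sd)
            return {"rfe": res.selected}

        stack = stack_fit(
            models,
            tr,
            y_tr,
            mode="out_of_fold",
            folds=oof_folds,
            seed=seed + r,
            n_repeats=n_repeats,
            select_features=fold_select,
        )
        stack_rmse = rmse(y_te, stack_predict(stack, models, te))
        ratios.append(stack_rmse / min(ext_rmse.values()))
    ratios = np.asarray(ratios)
    return {
        "win_rate": float(np.mean(ratios <= 1.05)),
        "median_ratio": float(np.median(ratios)),
        "ratios": ratios.tolist(),
    }


def ad_rates(
    n_replicates: int = 100,
    seed: int = 0,
    n_train: int = 200,
    p: int = 10,
    n_query: int = 2000,
    k: int = 5,
    percentile: float = 95.0,
    outlier_shift: float = 10.0,
) -> dict[str, float]:
    """Outlier detection rate and in-distribution false-alarm rate of the AD.

    Per replicate: standard-normal training cloud, one query shifted
    ``outlier_shift`` sd from the center plus in-distribution queries; both
    sets standardized with training parameters as in the pipeline. The
    false-alarm rate pools ``n_query`` in-distribution queries over the
    first 10 replicates (the nominal level is ``100 - percentile`` %).
    """
    out_flags = []
    false_rates = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        train = rng.standard_normal((n_train, p))
        mean, sd = train.mean(0), train.std(0)
        train_s = (train - mean) / sd
        thr = ad_threshold(train_s, k, percentile)
        outlier = rng.choice([-1.0, 1.0], p) * outlier_shift
        d_out = ad_distances(train_s, (outlier[None, :] - mean) / sd, k)
        out_flags.append(ad_classify(d_out, thr)[0] == "Out")
        if r < 10:
            queries = rng.standard_normal((n_query, p))
            d_in = ad_distances(train_s, (queries - mean) / sd, k)
            false_rates.append(float(np.mean(ad_classify(d_in, thr) == "Out")))
    return {
        "outlier_out_rate": float(np.mean(out_flags)),
        "in_dist_out_rate": float(np.mean(false_rates)),
    }
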