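"""End-to-end retention-modeling workflow as a model/results pair.

:class:`QSRRModel` is built from a compound table (retention times at each
pH) plus one descriptor matrix per pH; ``fit()`` runs the full workflow —
low-retention and zero-variance filtering, modeling/external split,
standardization, CFS and RFE feature selection, grid-searched base learners,
the stacked ensemble, kNN applicability-domain assessment and cross-pH rank
aggregation — and returns a :class:`QSRRResults` carrying the per-pH
performance tables, external predictions, AD report and consensus features,
with ``summary()`` and ``save()`` for reporting.

Retention is modeled on the log-minute scale by default (``transform:
log``); external errors are reported both on the modeling scale and in
back-transformed minutes.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .applicability import ADConfig, ad_report
from .evaluation import cv_folds, r2, rank_models, rmse, train_test_from_folds
from .exceptions import ConfigurationError, ValidationError
from .feature_selection import SelectionResult, cfs_select, consensus_features, rfe_select
from .models import (
    MODEL_REGISTRY,
    FittedModel,
    ModelConfig,
    embedded_importances,
    grid_search,
)
from .preprocess import (
    SplitDataset,
    filter_low_retention,
    remove_zero_variance,
    rt_columns,
    split,
    standardize,
)
from .stacking import StackingModel, stack_fit, stack_predict
from .synthetic import SimulationConfig, generate

__all__ = ["PipelineConfig", "QSRRModel", "QSRRResults", "run_all", "default_config"]

_CSV_FLOAT = "%.10g"


def _benchmark_grids() -> dict[str, dict]:
    """Compact per-model grids sized for the ~67-compound synthetic study."""
    return {
        "MLR_CFS": {},
        "MLR_RFE": {},
        "SVR_CFS": {"C": [1.0, 4.0, 16.0], "gamma_factor": [0.5, 1.0], "epsilon": [0.1]},
        "SVR_RFE": {"C": [1.0, 4.0, 16.0], "gamma_factor": [0.5, 1.0], "epsilon": [0.1]},
        "Lasso": {"alpha": [float(a) for a in np.logspace(-3, 0, 7)]},
        "RF": {"n_estimators": [200], "mtry": ["sqrt", "third"]},
        "GBM": {"n_estimators": [100, 300], "max_depth": [2], "learning_rate": [0.05]},
    }


@dataclass
class PipelineConfig:
    """Everything ``QSRRModel.fit`` needs besides the data."""

    transform: str = "log"  # "log" | "none"
    retention_threshold: float = 2.0  # minutes; conjunctive over pH
    n_test: int = 10
    stratify: bool = False
    folds: int = 10
    cfs_max_features: int | None = 20
    rfe_subset_sizes: tuple[int, ...] = (5, 10, 20, 40)
    model_keys: tuple[str, ...] = tuple(MODEL_REGISTRY)
    grids: dict[str, dict] = field(default_factory=_benchmark_grids)
    stacking_mode: str = "out_of_fold"
    stacking_bases: tuple[str, ...] = ("MLR_RFE", "Lasso", "SVR_RFE", "RF", "GBM")
    stacking_oof_folds: int = 5
    stacking_repeats: int = 2
    ad: ADConfig = field(default_factory=ADConfig)
    ad_aggregate: str = "any"
    embedded_top_k: int = 20
    cv_mode: str = "single"  # "single" | "nested"
    seed: int = 0
    simulation: SimulationConfig | None = None

    def validate(self) -> None:
        if self.transform not in ("log", "none"):
            raise ConfigurationError("transform must be 'log' or 'none'")
        unknown = [k for k in self.model_keys if k not in MODEL_REGISTRY]
        if unknown:
            raise ConfigurationError(f"unknown model keys: {unknown}")
        unknown = [k for k in self.stacking_bases if k not in self.model_keys]
        if unknown:
            raise ConfigurationError(f"stacking bases not among models: {unknown}")
        if self.cv_mode not in ("single", "nested"):
            raise ConfigurationError("cv_mode must be 'single' or 'nested'")
        self.ad.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        simple = {
            "transform",
            "retention_threshold",
            "folds",
            "cv_mode",
            "seed",
            "embedded_top_k",
            "ad_aggregate",
            "stacking_mode",
        }
        for key in simple & set(raw):
            kwargs[key] = raw[key]
        if "split" in raw:
            s = raw["split"]
            kwargs["n_test"] = int(s.get("n_test", 10))
            kwargs["stratify"] = bool(s.get("stratify", False))
            if "seed" in s:
                kwargs["seed"] = int(s["seed"])
        if "cfs" in raw:
            kwargs["cfs_max_features"] = raw["cfs"].get("max_features")
        if "rfe" in raw:
            kwargs["rfe_subset_sizes"] = tuple(raw["rfe"].get("subset_sizes", (5, 10, 20, 40)))
        if "models" in raw:
            kwargs["model_keys"] = tuple(raw["models"])
        if "grids" in raw:
            grids = _benchmark_grids()
            grids.update(raw["grids"])
            kwargs["grids"] = grids
        if "stacking" in raw:
            st = raw["stacking"]
            kwargs["stacking_mode"] = st.get("mode", "out_of_fold")
            if "bases" in st:
                kwargs["stacking_bases"] = tuple(st["bases"])
        if "ad" in raw:
            a = raw["ad"]
            kwargs["ad"] = ADConfig(
                k=int(a.get("k", 5)),
                percentile=float(a.get("percentile", 95.0)),
                feature_space=a.get("feature_space", "all"),
            )
            if "aggregate" in a:
                kwargs["ad_aggregate"] = a["aggregate"]
        if "simulation" in raw:
            kwargs["simulation"] = SimulationConfig(**raw["simulation"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def default_config(seed: int = 0) -> PipelineConfig:
    """The bundled synthetic-benchmark configuration."""
    cfg = PipelineConfig(seed=seed, simulation=SimulationConfig(seed=seed))
    cfg.validate()
    return cfg


def _apply_transform(y: pd.Series, transform: str) -> pd.Series:
    if transform == "log":
        if (y <= 0).any():
            raise ValidationError("log transform requires positive retention times")
        return np.log(y)
    return y.astype(float)


def _back_transform(pred: np.ndarray, transform: str) -> np.ndarray:
    return np.exp(pred) if transform == "log" else np.asarray(pred, dtype=float)


@dataclass
class PhFit:
    """Everything fitted for one pH condition."""

    ph: float
    split: SplitDataset
    selections: dict[str, SelectionResult]
    models: dict[str, FittedModel]
    stack: StackingModel
    performance: pd.DataFrame
    predictions: pd.DataFrame  # external-set observed/predicted per model
    consensus: list[str]


class QSRRResults:
    """Fitted-workflow results: tables, predictions, AD report, diagnostics."""

    def __init__(
        self,
        config: PipelineConfig,
        fits: dict[float, PhFit],
        ad_table: pd.DataFrame,
        rank_summary: pd.DataFrame,
    ):
        self.config = config
        self.fits = fits
        self.ad_table = ad_table
        self.rank_summary = rank_summary

    @property
    def ph_levels(self) -> list[float]:
        return sorted(self.fits)

    @property
    def performance_tables(self) -> dict[float, pd.DataFrame]:
        return {ph: fit.performance for ph, fit in self.fits.items()}

    @property
    def consensus(self) -> dict[float, list[str]]:
        return {ph: fit.consensus for ph, fit in self.fits.items()}

    def summary(self) -> str:
        lines = []
        lines.append("Retention-prediction workflow summary")
        lines.append("=" * 72)
        lines.append(
            f"transform: {self.config.transform} | folds: {self.config.folds} "
            f"| stacking: {self.config.stacking_mode} "
            f"| AD: k={self.config.ad.k}, p{self.config.ad.percentile:g}"
        )
        for ph in self.ph_levels:
            fit = self.fits[ph]
            lines.append("")
            lines.append(f"pH {ph:g} — performance ({self.config.transform} scale)")
            lines.append("-" * 72)
            lines.append(
                fit.performance.to_string(float_format=lambda v: f"{v:8.3f}")
            )
        lines.append("")
        lines.append("Mean rank across pH (external RMSE; 1 = best)")
        lines.append("-" * 72)
        lines.append(
            self.rank_summary["mean_rank"].to_string(float_format=lambda v: f"{v:6.2f}")
        )
        n_out = int((self.ad_table["Applicability"] == "Out").sum())
        lines.append("")
        lines.append(
            f"Applicability domain: {n_out} of "
            f"{len(self.ad_table) - 1} external compounds flagged Out"
        )
        return "\n".join(lines)

    def save(self, outdir: str | Path, plots: bool = True) -> None:
        """Write all result tables (and plots) under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for ph in self.ph_levels:
            fit = self.fits[ph]
            fit.performance.to_csv(
                outdir / f"performance_pH{ph:g}.csv", float_format=_CSV_FLOAT
            )
            fit.predictions.to_csv(
                outdir / f"predictions_pH{ph:g}.csv", float_format=_CSV_FLOAT
            )
            (outdir / f"stacking_pH{ph:g}.json").write_text(fit.stack.to_json())
        self.ad_table.to_csv(outdir / "ad_report.csv", float_format=_CSV_FLOAT)
        self.rank_summary.to_csv(outdir / "rank_summary.csv", float_format=_CSV_FLOAT)
        with open(outdir / "consensus_features.txt", "w") as fh:
            for ph in self.ph_levels:
                fh.write(f"pH {ph:g}: {', '.join(self.fits[ph].consensus)}\n")
        log = {
            "package_version": _pkg_version,
            "seed": self.config.seed,
            "transform": self.config.transform,
            "folds": self.config.folds,
            "stacking_mode": self.config.stacking_mode,
            "models": list(self.config.model_keys),
            "ph_levels": [float(p) for p in self.ph_levels],
            "chosen_hyperparameters": {
                f"{ph:g}": {
                    key: self.fits[ph].models[key].chosen_hyperparameters
                    for key in sorted(self.fits[ph].models)
                }
                for ph in self.ph_levels
            },
        }
        (outdir / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
        if plots:
            from . import plots as _plots

            _plots.save_all(self, outdir / "plots")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<QSRRResults: {len(self.fits)} pH conditions, "
            f"{len(self.config.model_keys)} models + stack>"
        )


class QSRRModel:
    """Retention-prediction model over one compound set at several pH values.

    Parameters
    ----------
    compound_table
        DataFrame with an ``id`` column and one ``rt_pH<value>`` retention
        column (minutes) per condition.
    descriptor_matrices
        Mapping pH -> compounds × descriptors DataFrame indexed by compound
        id. Matrices must cover every compound in the table.
    config
        Workflow settings; defaults to the bundled benchmark configuration.
    """

    def __init__(
        self,
        compound_table: pd.DataFrame,
        descriptor_matrices: Mapping[float, pd.DataFrame],
        config: PipelineConfig | None = None,
        force_test_ids: tuple = (),
    ):
        self.config = config or default_config()
        self.config.validate()
        self.compound_table = compound_table.reset_index(drop=True)
        self.descriptor_matrices = dict(descriptor_matrices)
        self.force_test_ids = tuple(force_test_ids)
        rt_columns(self.compound_table)  # raises early if malformed

    # ------------------------------------------------------------------
    @classmethod
    def from_csv(
        cls, data_dir: str | Path, config: PipelineConfig | None = None
    ) -> "QSRRModel":
        """Load ``compounds.csv`` + ``descriptors_pH<value>.csv`` from a directory."""
        data_dir = Path(data_dir)
        table = pd.read_csv(data_dir / "compounds.csv")
        matrices = {}
        for ph in rt_columns(table):
            path = data_dir / f"descriptors_pH{ph:g}.csv"
            if not path.exists():
                raise ValidationError(f"missing descriptor file {path.name}")
            matrices[ph] = pd.read_csv(path, index_col="id")
        return cls(table, matrices, config)

    @classmethod
    def from_synthetic(
        cls,
        sim_config: SimulationConfig | None = None,
        config: PipelineConfig | None = None,
    ) -> "QSRRModel":
        """Generate a synthetic benchmark dataset and wrap it.

        Planted structural outliers are placed in the external test set,
        mirroring a study design in which the out-of-domain compound is
        among the externally validated molecules.
        """
        config = config or default_config()
        sim = sim_config or config.simulation or SimulationConfig(seed=config.seed)
        ds = generate(sim)
        outlier_ids = tuple(ds.compound_table["id"].iloc[ds.oracle.outlier_idx])
        model = cls(
            ds.compound_table,
            ds.descriptor_matrices,
            config,
            force_test_ids=outlier_ids,
        )
        model.synthetic = ds
        return model

    # ------------------------------------------------------------------
    def fit(self) -> QSRRResults:
        cfg = self.config
        table = filter_low_retention(self.compound_table, cfg.retention_threshold)
        ids = table["id"].tolist()
        matrices = {
            ph: remove_zero_variance(self.descriptor_matrices[ph].loc[ids])
            for ph in rt_columns(table)
        }
        splits = split(
            table,
            matrices,
            n_test=cfg.n_test,
            seed=cfg.seed,
            stratify=cfg.stratify,
            force_test_ids=self.force_test_ids,
        )

        fits: dict[float, PhFit] = {}
        train_std_by_ph: dict[float, pd.DataFrame] = {}
        test_std_by_ph: dict[float, pd.DataFrame] = {}
        errors_by_ph: dict[float, pd.Series] = {}
        for i, (ph, ds) in enumerate(sorted(splits.items())):
            fit = self._fit_one_ph(ph, ds, seed=cfg.seed + 101 * (i + 1))
            fits[ph] = fit
            train_std_by_ph[ph] = fit.split.train_X
            test_std_by_ph[ph] = fit.split.test_X
            errors_by_ph[ph] = (
                (fit.predictions["observed_min"] - fit.predictions["Stack_min"])
                .abs()
                .rename("error_min")
            )

        ad_table = ad_report(
            train_std_by_ph,
            test_std_by_ph,
            errors_by_ph,
            k=cfg.ad.k,
            percentile=cfg.ad.percentile,
            aggregate=cfg.ad_aggregate,
        )
        ranks = rank_models(
            {f"pH{ph:g}": fits[ph].performance for ph in sorted(fits)},
            metric="RMSE_test",
        )
        return QSRRResults(cfg, fits, ad_table, ranks)

    # ------------------------------------------------------------------
    def _fit_one_ph(self, ph: float, ds: SplitDataset, seed: int) -> PhFit:
        cfg = self.config
        y_train = _apply_transform(ds.train_y, cfg.transform)
        y_test = _apply_transform(ds.test_y, cfg.transform)
        train_std, test_std, params = standardize(ds.train_X, ds.test_X)
        ds = SplitDataset(
            ph=ph,
            train_X=train_std,
            train_y=y_train,
            test_X=test_std,
            test_y=y_test,
            transform=cfg.transform,
            scaler_params=params,
        )

        selections = {
            "cfs": cfs_select(train_std, y_train, max_features=cfg.cfs_max_features),
            "rfe": rfe_select(
                train_std,
                y_train,
                subset_sizes=[
                    s for s in cfg.rfe_subset_sizes if s <= train_std.shape[1]
                ],
                folds=cfg.folds,
                seed=seed,
            ),
        }
        feature_sets = {
            "cfs": selections["cfs"].selected,
            "rfe": selections["rfe"].selected,
            "all": list(train_std.columns),
        }

        models: dict[str, FittedModel] = {}
        rows = []
        pred_table = pd.DataFrame(index=test_std.index)
        pred_table.index.name = "id"
        pred_table["observed"] = y_test.to_numpy()
        pred_table["observed_min"] = ds_test_min = _back_transform(
            y_test.to_numpy(), cfg.transform
        )
        for key in cfg.model_keys:
            algorithm, source = MODEL_REGISTRY[key]
            feats = feature_sets[source]
            mc = ModelConfig(
                algorithm=algorithm,
                feature_source=source,
                grid=cfg.grids.get(key),
                seed=seed,
            )
            fm = grid_search(mc, train_std[feats], y_train, folds=cfg.folds, fold_seed=seed)
            if cfg.cv_mode == "nested":
                nested = self._nested_scores(key, mc, feats, train_std, y_train, seed)
                fm.cv_rmse, fm.cv_r2 = nested
            models[key] = fm
            pred = fm.predict(test_std[feats])
            pred_table[key] = pred
            pred_table[f"{key}_min"] = _back_transform(pred, cfg.transform)
            rows.append(
                {
                    "model": key,
                    "RMSECV": fm.cv_rmse,
                    "R2CV": fm.cv_r2,
                    "RMSE_test": rmse(y_test.to_numpy(), pred),
                    "R2_test": r2(y_test.to_numpy(), pred),
                    "RMSE_test_min": rmse(ds_test_min, pred_table[f"{key}_min"].to_numpy()),
                }
            )

        bases = {k: models[k] for k in cfg.stacking_bases}
        base_sources = {MODEL_REGISTRY[k][1] for k in cfg.stacking_bases}

        def fold_select(Xf, yf, sd):
            # feature selection is part of each base pipeline: repeat it on
            # every fold's training part or OOF predictions leak optimism
            out = {}
            if "cfs" in base_sources:
                out["cfs"] = cfs_select(
                    Xf, yf, max_features=cfg.cfs_max_features
                ).selected
            if "rfe" in base_sources:
                out["rfe"] = rfe_select(
                    Xf,
                    yf,
                    subset_sizes=[s for s in cfg.rfe_subset_sizes if s <= Xf.shape[1]],
                    folds=min(5, cfg.folds),
                    seed=sd,
                ).selected
            return out

        if cfg.stacking_mode == "out_of_fold":
            stack, oof_Z = stack_fit(
                bases,
                train_std,
                y_train,
                mode="out_of_fold",
                folds=cfg.stacking_oof_folds,
                seed=seed,
                return_oof=True,
                n_repeats=cfg.stacking_repeats,
                select_features=fold_select if base_sources - {"all"} else None,
            )
            stack_cv_pred = stack.intercept + oof_Z @ stack.weights
        else:
            stack = stack_fit(
                bases,
                train_std,
                y_train,
                mode=cfg.stacking_mode,
                folds=cfg.folds,
                seed=seed,
                external=(test_std, y_test.to_numpy()),
            )
            stack_cv_pred = self._stack_cv_predictions(
                stack, models, train_std, y_train, seed
            )
        stack_pred = stack_predict(stack, models, test_std)
        pred_table["Stack"] = stack_pred
        pred_table["Stack_min"] = _back_transform(stack_pred, cfg.transform)
        rows.append(
            {
                "model": "Stack",
                "RMSECV": rmse(y_train.to_numpy(), stack_cv_pred),
                "R2CV": r2(y_train.to_numpy(), stack_cv_pred),
                "RMSE_test": rmse(y_test.to_numpy(), stack_pred),
                "R2_test": r2(y_test.to_numpy(), stack_pred),
                "RMSE_test_min": rmse(ds_test_min, pred_table["Stack_min"].to_numpy()),
            }
        )
        performance = pd.DataFrame(rows).set_index("model")

        embedded = [
            SelectionResult(
                method="embedded",
                selected=embedded_importances(models[k], cfg.embedded_top_k),
                scores=models[k].importances,
            )
            for k in ("Lasso", "RF", "GBM")
            if k in models
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty intersection is fine here
            consensus = consensus_features(
                [selections["cfs"], selections["rfe"], *embedded],
                embedded_top_k=cfg.embedded_top_k,
            )

        return PhFit(
            ph=ph,
            split=ds,
            selections=selections,
            models=models,
            stack=stack,
            performance=performance,
            predictions=pred_table,
            consensus=consensus,
        )

    # ------------------------------------------------------------------
    def _stack_cv_predictions(self, stack, models, train_std, y_train, seed):
        """Out-of-fold level-1 predictions pushed through the meta-learner."""
        y = y_train.to_numpy()
        n = len(y)
        assignment = cv_folds(n, self.config.folds, seed)
        Z = np.full((n, len(stack.base_keys)), np.nan)
        for i in range(len(assignment)):
            tr, te = train_test_from_folds(assignment, i, n)
            for j, key in enumerate(stack.base_keys):
                fm = models[key]
                sub = train_std[fm.feature_names]
                Z[te, j] = fm.refit(sub.iloc[tr], y[tr]).predict(sub.iloc[te])
        return stack.intercept + Z @ stack.weights

    def _nested_scores(self, key, mc: ModelConfig, feats, train_std, y_train, seed):
        """Outer-CV generalization estimate; inner CV drives the grid search."""
        y = y_train.to_numpy()
        n = len(y)
        outer = cv_folds(n, self.config.folds, seed + 7)
        fold_rmse, fold_r2 = [], []
        for i in range(len(outer)):
            tr, te = train_test_from_folds(outer, i, n)
            inner_folds = min(self.config.folds, len(tr))
            fm = grid_search(
                mc, train_std[feats].iloc[tr], y[tr], folds=inner_folds, fold_seed=seed + 13 + i
            )
            pred = fm.predict(train_std[feats].iloc[te])
            fold_rmse.append(rmse(y[te], pred))
            if len(te) >= 2 and np.ptp(y[te]) > 0:
                fold_r2.append(r2(y[te], pred))
        return float(np.mean(fold_rmse)), (
            float(np.mean(fold_r2)) if fold_r2 else float("nan")
        )


def run_all(
    config: PipelineConfig | str | Path | None = None,
    outdir: str | Path = "results",
    data_dir: str | Path | None = None,
    plots: bool = True,
) -> QSRRResults:
    """Run the complete workflow and write all outputs under ``outdir``.

    With ``data_dir`` the compound table and descriptor matrices are loaded
    from CSV; otherwise a synthetic benchmark dataset is generated from the
    configuration's simulation block. Outputs: per-pH performance and
    prediction CSVs, the AD report, the cross-pH rank summary, consensus
    features, stacking coefficients, a run log, and plots.
    """
    if config is None:
        config = default_config()
    elif isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    config.validate()
    if data_dir is not None:
        model = QSRRModel.from_csv(data_dir, config)
    else:
        model = QSRRModel.from_synthetic(config.simulation, config)
    results = model.fit()
    results.save(outdir, plots=plots)
    return results
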