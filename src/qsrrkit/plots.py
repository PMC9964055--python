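"""Diagnostic plots: observed vs predicted, residuals, and model ranks.

Every figure is backed by a CSV the results object already writes, so tests
assert on numbers rather than pixels.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["observed_vs_predicted", "residuals_by_ph", "rank_bar", "save_all"]


def observed_vs_predicted(results, model_key: str = "Stack", ax=None):
    """Scatter of external predictions vs observed retention (minutes),
    one panel per pH, with the identity line."""
    phs = results.ph_levels
    fig, axes = plt.subplots(1, len(phs), figsize=(3.2 * len(phs), 3.2), squeeze=False)
    for ax_, ph in zip(axes[0], phs):
        tab = results.fits[ph].predictions
        obs, pred = tab["observed_min"], tab[f"{model_key}_min"]
        ax_.scatter(obs, pred, s=18)
        lim = [0, max(obs.max(), pred.max()) * 1.05]
        ax_.plot(lim, lim, "k--", lw=0.8)
        ax_.set_title(f"pH {ph:g}")
        ax_.set_xlabel("observed (min)")
    axes[0][0].set_ylabel(f"{model_key} predicted (min)")
    fig.tight_layout()
    return fig


def residuals_by_ph(results, model_key: str = "Stack"):
    """Residuals (predicted − observed, minutes) of the external set per pH."""
    phs = results.ph_levels
    fig, axes = plt.subplots(1, len(phs), figsize=(3.2 * len(phs), 3.0), squeeze=False)
    for ax_, ph in zip(axes[0], phs):
        tab = results.fits[ph].predictions
        resid = tab[f"{model_key}_min"] - tab["observed_min"]
        ax_.stem(range(len(resid)), resid)
        ax_.axhline(0, color="k", lw=0.8)
        ax_.set_title(f"pH {ph:g}")
        ax_.set_xlabel("compound")
    axes[0][0].set_ylabel("residual (min)")
    fig.tight_layout()
    return fig


def rank_bar(results):
    """Mean rank of each model across pH (1 = lowest external RMSE)."""
    ranks = results.rank_summary["mean_rank"]
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.bar(ranks.index, ranks.to_numpy())
    ax.set_ylabel("mean rank (lower is better)")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    return fig


def save_all(results, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, fig in (
        ("observed_vs_predicted.png", observed_vs_predicted(results)),
        ("residuals.png", residuals_by_ph(results)),
        ("rank_bar.png", rank_bar(results)),
    ):
        fig.savefig(outdir / name, dpi=120)
        plt.close(fig)
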