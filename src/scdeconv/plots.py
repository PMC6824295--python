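"""Diagnostic plots: prediction scatter with fit, Bland-Altman, binned errors."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluation import bland_altman, correlation_report
from .mixtures import ProportionSet

__all__ = ["plot_scatter_fit", "plot_bland_altman", "plot_error_bins"]


def plot_scatter_fit(pred: ProportionSet, truth: ProportionSet,
                     fit: str = "linear", path: str | None = None):
    """Predicted vs expected proportions per cell type with the fitted curve."""
    report = correlation_report(pred, truth, fit=fit)
    k = len(pred.cell_types)
    ncols = min(k, 4)
    nrows = int(np.ceil(k / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 3 * nrows),
                             squeeze=False)
    for j, t in enumerate(pred.cell_types):
        ax = axes[j // ncols][j % ncols]
        x, y = pred.weights[:, j], truth.weights[:, j]
        ax.plot(x, y, ".", ms=2, alpha=0.5)
        ax.plot([0, 100], [0, 100], "--", color="grey", lw=1)
        coef = report[t].get("fit_coefficients")
        if coef is not None:
            xs = np.linspace(x.min(), x.max(), 50)
            ys = sum(c * xs**i for i, c in enumerate(coef))
            ax.plot(xs, ys, "-", color="C1", lw=1.5)
        ax.set_title(f"{t} (r={report[t]['pearson_r']:.2f})", fontsize=9)
        ax.set_xlabel("predicted %")
        ax.set_ylabel("expected %")
    for j in range(k, nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_bland_altman(pred: ProportionSet, truth: ProportionSet,
                      path: str | None = None):
    """Difference vs mean of predicted and expected with 1.96-SD limits."""
    ba = bland_altman(pred, truth)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ba["points"]["mean"].ravel(), ba["points"]["diff"].ravel(),
            ".", ms=2, alpha=0.4)
    ax.axhline(ba["mean_diff"], color="k", ls="--", lw=1)
    for lim in ba["limits"]:
        ax.axhline(lim, color="red", ls="--", lw=1)
    ax.set_xlabel("(predicted + expected) / 2")
    ax.set_ylabel("predicted - expected")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_error_bins(bins: pd.DataFrame, path: str | None = None):
    """Mean absolute proportional error per expected-proportion bin and type."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for t, grp in bins.groupby("cell_type"):
        grp = grp.sort_values("bin_lo")
        ax.plot(grp["bin_lo"], grp["mean_prop_error"], "o-", ms=3, label=t)
    ax.set_xlabel("expected proportion bin (lower edge)")
    ax.set_ylabel("mean absolute proportional error")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
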