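"""Performance metrics for predicted vs. expected cell-type proportions.

Covers per-type Pearson correlation with a linear or quadratic least-squares
fit, Bland-Altman agreement (mean difference with 1.96-SD limits), absolute
proportional error binned by expected proportion, per-sample maximum
absolute / proportional errors, and quantile-based stratification of samples
by a ratio of cell-type proportions (e.g. cytotoxic T cells over
monocytes/macrophages for survival grouping).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .mixtures import ProportionSet

__all__ = [
    "correlation_report",
    "bland_altman",
    "proportional_error_bins",
    "ratio_stratify",
]

logger = logging.getLogger(__name__)

#: floor (percentage points) for the denominator of the proportional error
PROP_ERROR_EPS = 0.1


def _check_aligned(pred: ProportionSet, truth: ProportionSet):
    if pred.cell_types != truth.cell_types:
        raise ValueError("cell-type columns differ between pred and truth")
    if pred.n_samples != truth.n_samples:
        raise ValueError("sample counts differ between pred and truth")


def _fit(x: np.ndarray, y: np.ndarray, fit: str) -> np.ndarray:
    """Least-squares coefficients of y ~ x (linear) or y ~ x + x^2 (quadratic),
    returned lowest order first (intercept, slope[, quad])."""
    deg = {"linear": 1, "quadratic": 2}[fit]
    return np.polyfit(x, y, deg)[::-1]


def correlation_report(
    pred: ProportionSet, truth: ProportionSet, fit: str = "linear"
) -> dict[str, dict]:
    """Per-type and pooled Pearson correlation plus a fit of truth ~ pred.

    Returns a dict keyed by cell type (plus ``"pooled"``) with ``pearson_r``,
    ``p_value``, ``fit`` and ``fit_coefficients`` (lowest order first). Types
    with zero predictor variance get ``pearson_r = nan``.
    """
    _check_aligned(pred, truth)
    if pred.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation")
    if fit not in ("linear", "quadratic"):
        raise ValueError(f"unknown fit {fit!r}")
    out = {}
    for j, t in enumerate(pred.cell_types):
        x, y = pred.weights[:, j], truth.weights[:, j]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[t] = {"pearson_r": float("nan"), "p_value": float("nan"),
                      "fit": fit, "fit_coefficients": None,
                      "note": "zero variance"}
            continue
        r, p = scipy.stats.pearsonr(x, y)
        out[t] = {"pearson_r": float(r), "p_value": float(p), "fit": fit,
                  "fit_coefficients": _fit(x, y, fit)}
    x, y = pred.weights.ravel(), truth.weights.ravel()
    r, p = scipy.stats.pearsonr(x, y)
    out["pooled"] = {"pearson_r": float(r), "p_value": float(p), "fit": fit,
                     "fit_coefficients": _fit(x, y, fit)}
    return out


def bland_altman(pred: ProportionSet, truth: ProportionSet) -> dict:
    """Bland-Altman agreement of predicted vs. expected proportions.

    diff = pred - truth and mean = (pred + truth)/2 per point; limits of
    agreement are mean_diff +/- 1.96 * sd(diff). Returns overall statistics,
    per-type mean/sd differences, and the per-point arrays for plotting.
    """
    _check_aligned(pred, truth)
    if pred.n_samples * len(pred.cell_types) < 2:
        raise ValueError("need at least 2 points")
    diff = pred.weights - truth.weights
    mean = (pred.weights + truth.weights) / 2.0
    d = diff.ravel()
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    lo, hi = mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff
    outside = float(((d < lo) | (d > hi)).mean()) if sd_diff > 0 else 0.0
    per_type = {
        t: {"mean_diff": float(diff[:, j].mean()),
            "sd_diff": float(diff[:, j].std(ddof=1)) if diff.shape[0] > 1
            else 0.0}
        for j, t in enumerate(pred.cell_types)
    }
    return {
        "mean_diff": mean_diff,
        "sd_diff": sd_diff,
        "limits": (float(lo), float(hi)),
        "fraction_outside": outside,
        "per_type": per_type,
        "points": {"diff": diff, "mean": mean},
    }


def proportional_error_bins(
    pred: ProportionSet,
    truth: ProportionSet,
    bin_edges: np.ndarray | None = None,
    eps: float = PROP_ERROR_EPS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Absolute and proportional errors binned by expected proportion.

    Absolute error is |p_hat - p| (percentage points); proportional error is
    |p_hat - p| / max(p, eps). Returns (per-(type, bin) table, per-sample
    table with ``max_abs_error`` and ``max_prop_error`` over types).
    """
    _check_aligned(pred, truth)
    if bin_edges is None:
        bin_edges = np.arange(0.0, 101.0, 10.0)
    bin_edges = np.asarray(bin_edges, float)
    abs_err = np.abs(pred.weights - truth.weights)
    prop_err = abs_err / np.maximum(truth.weights, eps)
    # right-inclusive last bin so p = 100 lands in the top bin
    bin_idx = np.clip(np.digitize(truth.weights, bin_edges[1:-1]), 0,
                      len(bin_edges) - 2)
    rows = []
    for j, t in enumerate(pred.cell_types):
        for b in range(len(bin_edges) - 1):
            sel = bin_idx[:, j] == b
            if not sel.any():
                continue
            rows.append({
                "cell_type": t,
                "bin": f"[{bin_edges[b]:g},{bin_edges[b + 1]:g})",
                "bin_lo": bin_edges[b],
                "n": int(sel.sum()),
                "mean_abs_error": float(abs_err[sel, j].mean()),
                "mean_prop_error": float(prop_err[sel, j].mean()),
            })
    table = pd.DataFrame(rows)
    per_sample = pd.DataFrame({
        "sample_id": pred.sample_ids,
        "max_abs_error": abs_err.max(axis=1),
        "max_prop_error": prop_err.max(axis=1),
    })
    return table, per_sample


def ratio_stratify(
    props: ProportionSet,
    numerator: list[str],
    denominator: list[str],
    quantile: float = 0.9,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Label samples 'high' when a proportion ratio exceeds an empirical quantile.

    ratio = sum(numerator types) / max(sum(denominator types), eps); samples
    strictly above the ``quantile`` (default 90th percentile, linear
    interpolation) are 'high', ties and the rest are 'rest'. Typical use:
    CD8 / monocyte-macrophage ratio for survival stratification.
    """
    if not numerator or not denominator:
        raise ValueError("numerator and denominator type lists must be non-empty")
    for t in list(numerator) + list(denominator):
        if t not in props.cell_types:
            raise ValueError(
                f"unknown cell type {t!r}; known: {props.cell_types}"
            )
    num_idx = [props.cell_types.index(t) for t in numerator]
    den_idx = [props.cell_types.index(t) for t in denominator]
    num = props.weights[:, num_idx].sum(axis=1)
    den = props.weights[:, den_idx].sum(axis=1)
    if np.all(den < eps):
        logger.warning("all denominator proportions ~0; ratios use eps floor")
    ratio = num / np.maximum(den, eps)
    q = float(np.quantile(ratio, quantile))
    group = np.where(ratio > q, "high", "rest")
    df = pd.DataFrame({"sample_id": props.sample_ids, "ratio": ratio,
                       "group": group})
    df.attrs["quantile"] = quantile
    df.attrs["threshold"] = q
    df.attrs["n_high"] = int((group == "high").sum())
    df.attrs["n_rest"] = int((group == "rest").sum())
    return df
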