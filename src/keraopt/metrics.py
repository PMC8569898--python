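"""Model-fit metrics and comparison utilities.

R-squared, RMSE, MAD and SSE per prediction subset; predicted-vs-actual
regression; residual diagnostics for normal-probability plots; Pearson
correlation; fold change.  These are the statistics used to compare the
response-surface and neural-network models of amino-acid release.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Metrics",
    "compute_metrics",
    "predicted_vs_actual",
    "residual_diagnostics",
    "correlation",
    "fold_change",
    "compare_models",
]


@dataclass(frozen=True)
class Metrics:
    """Goodness statistics for one prediction set.

    ``r2`` is 1 - SSE/SS_total where SS_total uses the *subset's own*
    observed variance, so a validation subset can legitimately score higher
    than the training subset.  ``r2`` is None when the observed values have
    zero variance (undefined).
    """

    n: int
    r2: float | None
    rmse: float
    mad: float
    sse: float


def compute_metrics(observed, predicted, mask=None) -> Metrics:
    """R2/RMSE/MAD/SSE of ``predicted`` against ``observed``.

    ``mask`` optionally restricts to a subset (boolean array or index array).
    """
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: {o.shape} observed vs {p.shape} predicted")
    if mask is not None:
        o, p = o[mask], p[mask]
    n = len(o)
    if n < 1:
        raise ValueError("empty prediction set")
    err = o - p
    sse = float(err @ err)
    rmse = float(np.sqrt(sse / n))
    mad = float(np.mean(np.abs(err)))
    sstot = float(np.sum((o - o.mean()) ** 2))
    if n < 2 or sstot == 0.0:
        r2 = None
    else:
        r2 = 1.0 - sse / sstot
    return Metrics(n=n, r2=r2, rmse=rmse, mad=mad, sse=sse)


def predicted_vs_actual(observed, predicted):
    """Simple linear regression of predicted on observed.

    Returns ``(slope, intercept, r2)``; perfect prediction gives (1, 0, 1).
    """
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if len(o) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(p, p[0]):
        # constant predictions: zero slope, undefined correlation -> r2 = 0
        return 0.0, float(p[0]), 0.0
    res = stats.linregress(o, p)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def residual_diagnostics(observed, predicted) -> pd.DataFrame:
    """Plot-ready residual diagnostics.

    Residuals are sorted and assigned normal plotting positions
    (i - 0.375)/(n + 0.25), mapped through the standard normal quantile
    function; the frame also pairs each fitted value with its residual for a
    residual-vs-fit panel.
    """
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    n = len(o)
    if n < 3:
        raise ValueError("need at least 3 points")
    resid = o - p
    order = np.argsort(resid, kind="stable")
    ranks = np.arange(1, n + 1)
    positions = (ranks - 0.375) / (n + 0.25)
    frame = pd.DataFrame(
        {
            "fitted": p[order],
            "residual": resid[order],
            "plotting_position": positions,
            "normal_quantile": stats.norm.ppf(positions),
        }
    )
    return frame


def correlation(x, y):
    """Pearson product-moment correlation with a two-sided t p-value."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fold_change(optimized: float, baseline: float) -> float:
    """Ratio of an optimized response to its baseline (baseline > 0)."""
    if not baseline > 0:
        raise ValueError(f"baseline must be > 0, got {baseline}")
    return float(optimized) / float(baseline)


def compare_models(observed, predictions: dict, subset=None) -> dict:
    """Training/validation/overall metrics per model plus a winner.

    Parameters
    ----------
    observed : array-like
        Measured responses for all runs.
    predictions : dict of label -> array-like
        Full-length predicted responses per model.
    subset : array-like of {"training","validation"}, optional
        Per-run split; when given, per-subset blocks are reported.

    Returns a dict with per-model metric blocks, a predicted-vs-actual
    regression per model, and ``winner`` (highest overall R2, RMSE as
    tiebreak).
    """
    observed = np.asarray(observed, dtype=float).ravel()
    report: dict = {"models": {}, "winner": None}
    best_key = None
    for label, pred in predictions.items():
        pred = np.asarray(pred, dtype=float).ravel()
        block = {"overall": compute_metrics(observed, pred)}
        if subset is not None:
            sub = np.asarray(subset, dtype=object).ravel()
            for name in ("training", "validation"):
                m = sub == name
                if m.any():
                    block[name] = compute_metrics(observed, pred, mask=m)
        slope, intercept, r2 = predicted_vs_actual(observed, pred)
        block["pred_vs_actual"] = {"slope": slope, "intercept": intercept, "r2": r2}
        report["models"][label] = block
        key = (block["overall"].r2 if block["overall"].r2 is not None else -np.inf,
               -block["overall"].rmse)
        if best_key is None or key > best_key:
            best_key, report["winner"] = key, label
    return report
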