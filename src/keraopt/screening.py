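"""Two-level screening analysis (Plackett-Burman style).

The main effect of a factor in a balanced two-level design is

    effect_i = 2 (sum M+ - sum M-) / N  =  mean(high) - mean(low),

i.e. twice the OLS slope on the +/-1 coded column.  The first-order model is
fit by least squares; each factor's sum of squares, percent contribution,
t statistic and p-value are reported together with the model-level goodness
statistics (s, R2, adjusted R2, predicted R2 via leave-one-out PRESS) and
the critical |t| used as the significance reference line in Pareto charts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._ols import fit_ols
from .design import DesignMatrix, ResponseTable

__all__ = ["ScreeningResult", "main_effect", "analyze_screening", "pareto_ranking"]


@dataclass
class ScreeningResult:
    """Per-factor effect table plus model-level goodness statistics.

    ``table`` is indexed by factor name with columns ``effect``,
    ``coefficient`` (= effect/2), ``ss``, ``contribution_pct``, ``t`` and
    ``p``.  R-squared statistics are on the percent scale.
    """

    table: pd.DataFrame
    intercept: float
    s: float
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    error_df: int
    alpha_level: float
    significance_threshold_t: float
    fitted: np.ndarray
    residuals: np.ndarray


def _check_two_level(design: DesignMatrix) -> None:
    coded = design.coded
    if not np.all(np.isclose(np.abs(coded), 1.0)):
        raise ValueError("screening analysis requires a two-level (+/-1 coded) design")
    bal = coded.sum(axis=0)
    if not np.allclose(bal, 0.0):
        bad = [design.factor_names[j] for j in np.nonzero(~np.isclose(bal, 0))[0]]
        raise ValueError(f"unbalanced columns (unequal +1/-1 counts): {bad}")


def main_effect(design: DesignMatrix, responses: ResponseTable, factor: str) -> float:
    """Main effect of ``factor``: mean response at +1 minus mean at -1."""
    _check_two_level(design)
    y = responses.response
    if len(y) != design.n_runs:
        raise ValueError("response table does not cover every run")
    col = design.column(factor)
    return float(y[col > 0].mean() - y[col < 0].mean())


def analyze_screening(
    design: DesignMatrix, responses: ResponseTable, alpha_level: float = 0.05
) -> ScreeningResult:
    """First-order fit of a balanced two-level screening design.

    Percent contribution of a factor is its sum of squares over the *total*
    (corrected) sum of squares, so contributions over all factors add up to
    the model R2.  Predicted R2 uses the closed-form leave-one-out PRESS.
    """
    _check_two_level(design)
    y = responses.response
    n, k = design.n_runs, design.n_factors
    if len(y) != n:
        raise ValueError("response table does not cover every run")
    error_df = n - k - 1
    if error_df <= 0:
        raise ValueError(
            f"saturated design: {n} runs cannot estimate {k} effects plus an "
            "intercept with residual df; drop factors or add replicate runs"
        )
    X = np.column_stack([np.ones(n), design.coded])
    fit = fit_ols(X, y)
    coefs = fit.coef[1:]
    effects = 2.0 * coefs
    ss_factor = n * coefs**2
    sstot = float(np.sum((y - y.mean()) ** 2))
    s2 = fit.sse / error_df
    se = fit.coef_se()[1:]
    t = coefs / se
    p = 2.0 * stats.t.sf(np.abs(t), error_df)

    table = pd.DataFrame(
        {
            "effect": effects,
            "coefficient": coefs,
            "ss": ss_factor,
            "contribution_pct": ss_factor / sstot * 100.0,
            "t": t,
            "p": p,
        },
        index=pd.Index(design.factor_names, name="factor"),
    )
    press = fit.press
    return ScreeningResult(
        table=table,
        intercept=float(fit.coef[0]),
        s=float(np.sqrt(s2)),
        r2=(1.0 - fit.sse / sstot) * 100.0,
        adj_r2=(1.0 - (fit.sse / error_df) / (sstot / (n - 1))) * 100.0,
        pred_r2=(1.0 - press / sstot) * 100.0,
        press=press,
        error_df=error_df,
        alpha_level=alpha_level,
        significance_threshold_t=float(stats.t.ppf(1.0 - alpha_level / 2.0, error_df)),
        fitted=fit.fitted,
        residuals=fit.residuals,
    )


def pareto_ranking(result: ScreeningResult) -> pd.DataFrame:
    """Factors ordered by |standardized effect| (|t|), largest first.

    The returned frame has columns ``abs_t`` and ``significant`` (|t| at or
    above the two-sided critical value).  Ties keep the input factor order
    (stable sort).
    """
    abs_t = result.table["t"].abs()
    order = np.argsort(-abs_t.to_numpy(), kind="stable")
    ranked = pd.DataFrame(
        {
            "abs_t": abs_t.to_numpy()[order],
            "significant": abs_t.to_numpy()[order] >= result.significance_threshold_t,
        },
        index=result.table.index[order],
    )
    return ranked
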