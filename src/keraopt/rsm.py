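"""Second-order response-surface modeling on central composite designs.

Fits the full quadratic

    Y = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j

to coded factor levels by least squares, and provides the supporting
statistics used in response-surface practice:

* an ANOVA with adjusted (partial, Type-III style) sums of squares per term,
  grouped linear/square/interaction rows, and a lack-of-fit / pure-error
  split from replicated runs;
* goodness statistics (s, R2, adjusted R2, predicted R2 from leave-one-out
  PRESS);
* exact algebraic conversion of the coded polynomial to actual units;
* contour grids for factor pairs at held values of the remaining factors;
* constrained maximization of the fitted surface (stationary point when the
  surface is concave and the point interior, deterministic multistart
  search otherwise).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._ols import fit_ols
from .design import DesignMatrix, Factor, ResponseTable

__all__ = [
    "QuadraticModel",
    "GoodnessStats",
    "OptimumResult",
    "quadratic_model_matrix",
    "fit_quadratic",
    "anova_quadratic",
    "goodness_quadratic",
    "uncode_model",
    "contour_grid",
    "optimize_response",
]


def quadratic_model_matrix(coded: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Model matrix [1, x_i, x_i^2, x_i*x_j (i<j)] and term labels.

    Term labels use 0-based column indices and are relabelled with factor
    names by the fitting routines.
    """
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    n, k = coded.shape
    cols = [np.ones(n)]
    labels = ["const"]
    for i in range(k):
        cols.append(coded[:, i])
        labels.append(f"lin{i}")
    for i in range(k):
        cols.append(coded[:, i] ** 2)
        labels.append(f"sq{i}")
    for i, j in itertools.combinations(range(k), 2):
        cols.append(coded[:, i] * coded[:, j])
        labels.append(f"int{i}.{j}")
    return np.column_stack(cols), labels


@dataclass
class QuadraticModel:
    """A fitted (or constructed) second-order polynomial in coded units.

    ``linear``/``square`` map factor name -> coefficient; ``interaction``
    maps an ordered factor-name pair (tuple, design order) -> coefficient.
    ``coding`` carries the Factor objects needed to move between coded and
    actual units.
    """

    factor_names: list[str]
    beta0: float
    linear: dict[str, float]
    square: dict[str, float]
    interaction: dict[tuple[str, str], float]
    coding: list[Factor] | None = None
    fitted_runs: int = 0

    def __post_init__(self) -> None:
        names = self.factor_names
        missing = [n for n in names if n not in self.linear or n not in self.square]
        if missing:
            raise ValueError(f"missing linear/square coefficients for {missing}")
        for pair in itertools.combinations(names, 2):
            self.interaction.setdefault(tuple(pair), 0.0)

    @property
    def k(self) -> int:
        return len(self.factor_names)

    def gradient_terms(self) -> tuple[np.ndarray, np.ndarray]:
        """(g, B) with prediction = beta0 + g.x + x'Bx in coded units."""
        names = self.factor_names
        g = np.array([self.linear[n] for n in names])
        B = np.diag([self.square[n] for n in names]).astype(float)
        for (a, b), coef in self.interaction.items():
            i, j = names.index(a), names.index(b)
            B[i, j] += coef / 2.0
            B[j, i] += coef / 2.0
        return g, B

    def predict_coded(self, coded) -> np.ndarray:
        """Evaluate the polynomial at coded points (n, k) or a single point."""
        x = np.atleast_2d(np.asarray(coded, dtype=float))
        if x.shape[1] != self.k:
            raise ValueError(f"expected {self.k} coded columns, got {x.shape[1]}")
        g, B = self.gradient_terms()
        out = self.beta0 + x @ g + np.einsum("ni,ij,nj->n", x, B, x)
        return out if np.asarray(coded).ndim > 1 else float(out[0])

    def predict_actual(self, actual) -> np.ndarray:
        """Evaluate at actual-unit points using the attached coding."""
        if self.coding is None:
            raise ValueError("model carries no coding scheme")
        a = np.atleast_2d(np.asarray(actual, dtype=float))
        coded = np.column_stack([f.code(a[:, j]) for j, f in enumerate(self.coding)])
        out = self.predict_coded(coded)
        return out if np.asarray(actual).ndim > 1 else float(np.atleast_1d(out)[0])

    def predict(self, design: DesignMatrix) -> np.ndarray:
        if design.factor_names != self.factor_names:
            raise ValueError(
                f"design factors {design.factor_names} do not match model factors "
                f"{self.factor_names}"
            )
        return self.predict_coded(design.coded)


@dataclass(frozen=True)
class GoodnessStats:
    """s, R2 family (percent scale) and PRESS for a quadratic fit."""

    s: float
    r2: float
    adj_r2: float
    pred_r2: float
    press: float


@dataclass(frozen=True)
class OptimumResult:
    """Location and value of the constrained optimum of a fitted surface."""

    coded: np.ndarray
    actual: np.ndarray | None
    predicted_response: float
    on_boundary: bool
    region: str
    radius: float


def _relabel(model_labels: list[str], names: list[str]) -> list[str]:
    out = []
    for lab in model_labels:
        if lab == "const":
            out.append("const")
        elif lab.startswith("lin"):
            out.append(names[int(lab[3:])])
        elif lab.startswith("sq"):
            out.append(f"{names[int(lab[2:])]}^2")
        else:
            i, j = lab[3:].split(".")
            out.append(f"{names[int(i)]}*{names[int(j)]}")
    return out


def fit_quadratic(design: DesignMatrix, responses: ResponseTable) -> QuadraticModel:
    """OLS fit of the full second-order model on coded columns."""
    y = responses.response
    if len(y) != design.n_runs:
        raise ValueError("response table does not cover every run")
    X, labels = quadratic_model_matrix(design.coded)
    if design.n_runs <= X.shape[1]:
        raise ValueError(
            f"{design.n_runs} runs cannot support {X.shape[1]} quadratic terms"
        )
    fit = fit_ols(X, y)
    names = design.factor_names
    k = len(names)
    coef = fit.coef
    linear = {names[i]: float(coef[1 + i]) for i in range(k)}
    square = {names[i]: float(coef[1 + k + i]) for i in range(k)}
    inter = {}
    for idx, (i, j) in enumerate(itertools.combinations(range(k), 2)):
        inter[(names[i], names[j])] = float(coef[1 + 2 * k + idx])
    return QuadraticModel(
        factor_names=list(names),
        beta0=float(coef[0]),
        linear=linear,
        square=square,
        interaction=inter,
        coding=list(design.factors),
        fitted_runs=design.n_runs,
    )


def _term_groups(k: int) -> dict[str, list[int]]:
    """Model-matrix column indices (excluding the constant) per term group."""
    n_int = k * (k - 1) // 2
    return {
        "linear": list(range(1, 1 + k)),
        "square": list(range(1 + k, 1 + 2 * k)),
        "interaction": list(range(1 + 2 * k, 1 + 2 * k + n_int)),
    }


def anova_quadratic(
    model: QuadraticModel, design: DesignMatrix, responses: ResponseTable
) -> pd.DataFrame:
    """ANOVA of the quadratic fit with adjusted (partial) sums of squares.

    Each term row (and each group row: linear, square, interaction) reports
    the increase in residual SS when that term (group) is dropped from the
    full model and the fit redone — the Type-III convention, under which the
    three group rows need not equal the sum of their member rows when terms
    are correlated (squares in a CCD are).  Lack of fit and pure error split
    the residual using replicate groups (runs with identical coded settings);
    F for lack of fit uses the pure-error mean square as denominator.
    """
    y = responses.response
    X, labels = quadratic_model_matrix(design.coded)
    full = fit_ols(X, y)
    n, p = X.shape
    names = design.factor_names
    term_labels = _relabel(labels, names)
    sstot = float(np.sum((y - y.mean()) ** 2))
    sse = full.sse
    df_err = n - p
    ms_err = sse / df_err
    rows = []

    def frow(source, df, ss, against_ms, against_df):
        ms = ss / df
        f = ms / against_ms
        pval = float(stats.f.sf(f, df, against_df))
        return {"source": source, "df": df, "ss": ss, "ms": ms, "f": f, "p": pval}

    ss_model = sstot - sse
    df_model = p - 1
    rows.append(frow("model", df_model, ss_model, ms_err, df_err))

    def drop_ss(cols_to_drop: list[int]) -> float:
        keep = [c for c in range(p) if c not in cols_to_drop]
        return fit_ols(X[:, keep], y).sse - sse

    groups = _term_groups(len(names))
    for gname in ("linear", "square", "interaction"):
        idx = groups[gname]
        if not idx:
            continue
        rows.append(frow(gname, len(idx), drop_ss(idx), ms_err, df_err))
        for c in idx:
            rows.append(frow(term_labels[c], 1, drop_ss([c]), ms_err, df_err))

    rows.append({"source": "error", "df": df_err, "ss": sse, "ms": ms_err,
                 "f": np.nan, "p": np.nan})

    rep_groups = [g for g in design.replicate_groups() if len(g) >= 2]
    if rep_groups:
        ss_pe = float(sum(np.sum((y[g] - y[g].mean()) ** 2) for g in rep_groups))
        df_pe = int(sum(len(g) - 1 for g in rep_groups))
        df_lof = df_err - df_pe
        ss_lof = sse - ss_pe
        if df_lof >= 1 and df_pe >= 1:
            ms_pe = ss_pe / df_pe
            rows.append(frow("lack_of_fit", df_lof, ss_lof, ms_pe, df_pe))
            rows.append({"source": "pure_error", "df": df_pe, "ss": ss_pe,
                         "ms": ms_pe, "f": np.nan, "p": np.nan})
        else:
            warnings.warn("model saturates replicate structure; lack-of-fit rows omitted")
    else:
        warnings.warn("no replicated runs; pure-error split unavailable, lack-of-fit rows omitted")

    rows.append({"source": "total", "df": n - 1, "ss": sstot, "ms": np.nan,
                 "f": np.nan, "p": np.nan})
    return pd.DataFrame(rows).set_index("source")


def goodness_quadratic(
    model: QuadraticModel, design: DesignMatrix, responses: ResponseTable
) -> GoodnessStats:
    """s = sqrt(MS_error), R2 family on the percent scale, and PRESS."""
    y = responses.response
    X, _ = quadratic_model_matrix(design.coded)
    fit = fit_ols(X, y)
    n, p = X.shape
    sstot = float(np.sum((y - y.mean()) ** 2))
    press = fit.press
    return GoodnessStats(
        s=float(np.sqrt(fit.sse / (n - p))),
        r2=(1.0 - fit.sse / sstot) * 100.0,
        adj_r2=(1.0 - (fit.sse / (n - p)) / (sstot / (n - 1))) * 100.0,
        pred_r2=(1.0 - press / sstot) * 100.0,
        press=press,
    )


def uncode_model(model: QuadraticModel) -> dict:
    """Exact expansion of the coded polynomial into actual-unit coefficients.

    Substituting x_i = (X_i - c_i)/s_i and collecting powers of X gives a
    polynomial whose predictions agree with the coded form everywhere.
    Returns ``{"intercept", "linear", "square", "interaction"}`` keyed like
    the coded model but on the actual scale.
    """
    if model.coding is None:
        raise ValueError("model carries no coding scheme")
    names = model.factor_names
    c = np.array([f.center for f in model.coding])
    s = np.array([f.step for f in model.coding])
    g, B = model.gradient_terms()

    intercept = model.beta0 - float(g @ (c / s)) + float((c / s) @ B @ (c / s))
    linear = {}
    for i, name in enumerate(names):
        val = g[i] / s[i]
        val -= 2.0 * float(B[i] @ (c / s)) / s[i]
        linear[name] = val
    square = {name: model.square[name] / s[i] ** 2 for i, name in enumerate(names)}
    inter = {}
    for (a, b), coef in model.interaction.items():
        i, j = names.index(a), names.index(b)
        inter[(a, b)] = coef / (s[i] * s[j])
    return {"intercept": intercept, "linear": linear, "square": square, "interaction": inter}


def contour_grid(
    model: QuadraticModel,
    factor_x: str,
    factor_y: str,
    hold: dict[str, float],
    grid_n: int = 50,
    coded_range: float = 1.682,
) -> pd.DataFrame:
    """Predictions over a grid in two factors, holding the others fixed.

    ``hold`` gives actual-unit values for every factor that is not on an
    axis.  The grid spans ``+/- coded_range`` in coded units of the two axis
    factors.  Returns a long-format frame with the two actual-unit axis
    columns and the prediction.
    """
    names = model.factor_names
    for f in (factor_x, factor_y):
        if f not in names:
            raise KeyError(f"unknown factor {f!r}")
    others = [n for n in names if n not in (factor_x, factor_y)]
    missing = [n for n in others if n not in hold]
    if missing:
        raise ValueError(f"hold values missing for {missing}")
    if model.coding is None:
        raise ValueError("model carries no coding scheme")
    coding = {f.name: f for f in model.coding}
    if grid_n < 1:
        raise ValueError("grid_n must be >= 1")
    grid = np.zeros(1) if grid_n == 1 else np.linspace(-coded_range, coded_range, grid_n)
    xs, ys = np.meshgrid(grid, grid, indexing="ij")
    pts = np.zeros((grid_n * grid_n, len(names)))
    pts[:, names.index(factor_x)] = xs.ravel()
    pts[:, names.index(factor_y)] = ys.ravel()
    for n in others:
        pts[:, names.index(n)] = coding[n].code(hold[n])
    z = model.predict_coded(pts)
    return pd.DataFrame(
        {
            factor_x: coding[factor_x].decode(xs.ravel()),
            factor_y: coding[factor_y].decode(ys.ravel()),
            "prediction": z,
        }
    )


def optimize_response(
    model: QuadraticModel, region: str = "cuboid", radius: float = 1.682
) -> OptimumResult:
    """Maximize the fitted quadratic over a coded cuboid or sphere.

    When the quadratic part is negative definite and the analytic stationary
    point lies inside the region, it is returned directly.  Otherwise a
    deterministic multistart search (2^k region corners + center) runs a
    bounded simplex search (cuboid) or SLSQP with a radius constraint
    (sphere); no randomness is involved, so results are reproducible.
    """
    if region not in ("cuboid", "sphere"):
        raise ValueError(f"region must be 'cuboid' or 'sphere', got {region!r}")
    if not radius > 0:
        raise ValueError("region radius must be > 0")
    g, B = model.gradient_terms()
    k = model.k

    def value(x: np.ndarray) -> float:
        return float(model.beta0 + g @ x + x @ B @ x)

    eig = np.linalg.eigvalsh(B)
    best_x = None
    if np.all(eig < -1e-12):
        xs = np.linalg.solve(-2.0 * B, g)
        inside = (
            np.all(np.abs(xs) <= radius + 1e-9)
            if region == "cuboid"
            else float(np.linalg.norm(xs)) <= radius + 1e-9
        )
        if inside:
            best_x = xs

    if best_x is None:
        corner_scale = radius if region == "cuboid" else radius / np.sqrt(k)
        starts = [np.zeros(k)] + [
            corner_scale * np.array(signs, dtype=float)
            for signs in itertools.product((-1.0, 1.0), repeat=k)
        ]
        neg = lambda x: -value(np.asarray(x))
        best_val = -np.inf
        for x0 in starts:
            if region == "cuboid":
                res = optimize.minimize(
                    neg, x0, method="Nelder-Mead",
                    bounds=[(-radius, radius)] * k,
                    options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000},
                )
            else:
                res = optimize.minimize(
                    neg, x0, method="SLSQP",
                    constraints=[{"type": "ineq",
                                  "fun": lambda x: radius**2 - float(x @ x)}],
                    options={"ftol": 1e-12, "maxiter": 500},
                )
            if -res.fun > best_val:
                best_val, best_x = -res.fun, np.asarray(res.x)
        if region == "sphere":
            nrm = float(np.linalg.norm(best_x))
            if nrm > radius:
                best_x = best_x * (radius / nrm)

    on_boundary = (
        bool(np.any(np.abs(np.abs(best_x) - radius) < 1e-6))
        if region == "cuboid"
        else bool(abs(np.linalg.norm(best_x) - radius) < 1e-6)
    )
    actual = None
    if model.coding is not None:
        actual = np.array([f.decode(best_x[i]) for i, f in enumerate(model.coding)])
    return OptimumResult(
        coded=best_x,
        actual=actual,
        predicted_response=value(best_x),
        on_boundary=on_boundary,
        region=region,
        radius=radius,
    )
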