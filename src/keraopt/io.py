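"""Reading and writing the delimited design/response tables and reports.

Canonical table format: comma-separated, header row, UTF-8, "." decimal.
A factor table carries ``name,units,center,step`` (or ``low,high`` from
which center and step are derived); a design table carries coded columns
``x_<name>`` (or actual columns ``<name>``) plus optional ``response``,
``sd`` and ``subset`` columns.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignMatrix, Factor, ResponseTable
from .metrics import Metrics

__all__ = [
    "read_factor_table",
    "read_tables",
    "write_design",
    "screening_report",
    "format_screening",
    "anova_report",
    "format_anova",
    "comparison_report",
    "format_comparison",
]


def read_factor_table(path) -> list[Factor]:
    """Parse a factor table; accepts center/step or low/high level columns."""
    frame = pd.read_csv(path)
    cols = set(frame.columns)
    if "name" not in cols:
        raise ValueError(f"{path}: factor table needs a 'name' column, found {sorted(cols)}")
    factors = []
    for i, row in frame.iterrows():
        units = str(row["units"]) if "units" in cols and pd.notna(row.get("units")) else ""
        try:
            if {"center", "step"} <= cols:
                factors.append(Factor(str(row["name"]), units, float(row["center"]), float(row["step"])))
            elif {"low", "high"} <= cols:
                factors.append(Factor.from_levels(str(row["name"]), float(row["low"]), float(row["high"]), units))
            else:
                raise ValueError("need center/step or low/high columns")
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, row {i + 2}: {exc}") from None
    return factors


def _numeric(frame: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(frame[col], errors="coerce")
    bad = vals.index[vals.isna() & frame[col].notna()]
    if len(bad):
        raise ValueError(
            f"{path}: non-numeric value in column {col!r} at row(s) "
            f"{[int(b) + 2 for b in bad]}"  # +2: header + 1-based
        )
    if vals.isna().any():
        raise ValueError(f"{path}: missing value in column {col!r}")
    return vals.to_numpy(float)


def read_tables(factor_path, design_path, design_kind: str = "custom"):
    """Parse factor + design/response files into package objects.

    Returns ``(DesignMatrix, ResponseTable | None)``; the response table is
    present when the design file carries a ``response`` column.  Coded
    columns ``x_<name>`` are preferred; actual-unit columns ``<name>`` are
    coded through the factor table when no coded columns exist.
    """
    factors = read_factor_table(factor_path)
    frame = pd.read_csv(design_path)
    names = [f.name for f in factors]
    coded_cols = [f"x_{n}" for n in names]
    if all(c in frame.columns for c in coded_cols):
        coded = np.column_stack([_numeric(frame, c, design_path) for c in coded_cols])
    elif all(n in frame.columns for n in names):
        actual = np.column_stack([_numeric(frame, n, design_path) for n in names])
        coded = np.column_stack([f.code(actual[:, j]) for j, f in enumerate(factors)])
    else:
        missing = [n for n in names if n not in frame.columns and f"x_{n}" not in frame.columns]
        raise ValueError(f"{design_path}: design file missing factor column(s) {missing}")

    kwargs = {}
    if "point_type" in frame.columns:
        kwargs["point_type"] = frame["point_type"].to_numpy(object)
    if "replicate_id" in frame.columns:
        kwargs["replicate_id"] = _numeric(frame, "replicate_id", design_path).astype(int)
    design = DesignMatrix(factors=factors, coded=coded, design_kind=design_kind, **kwargs)

    responses = None
    if "response" in frame.columns:
        run_id = None
        if "run" in frame.columns:
            run_id = _numeric(frame, "run", design_path).astype(int)
            if len(set(run_id.tolist())) != len(run_id):
                raise ValueError(f"{design_path}: duplicate run ids")
        responses = ResponseTable(
            response=_numeric(frame, "response", design_path),
            sd=_numeric(frame, "sd", design_path) if "sd" in frame.columns else None,
            subset=frame["subset"].to_numpy(object) if "subset" in frame.columns else None,
            run_id=run_id,
        )
    return design, responses


def write_design(design: DesignMatrix, path) -> None:
    """Write a design as delimited text (coded + actual columns + metadata)."""
    design.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# report builders: every number below is read off objects computed by the
# analysis modules; nothing is recomputed here.

def _metrics_dict(m: Metrics) -> dict:
    return dataclasses.asdict(m)


def screening_report(result) -> dict:
    """JSON-able screening report (per-factor stats + goodness block)."""
    return {
        "factors": {
            name: {k: float(v) for k, v in row.items()}
            for name, row in result.table.iterrows()
        },
        "goodness": {
            "s": result.s,
            "r2": result.r2,
            "adj_r2": result.adj_r2,
            "pred_r2": result.pred_r2,
            "press": result.press,
            "error_df": result.error_df,
        },
        "significance_threshold_t": result.significance_threshold_t,
        "alpha_level": result.alpha_level,
    }


def format_screening(result) -> str:
    lines = ["Screening analysis (first-order model, coded +/-1 units)", ""]
    lines.append(result.table.to_string(float_format=lambda v: f"{v:.4g}"))
    lines += [
        "",
        f"s = {result.s:.2f}   R2 = {result.r2:.2f}%   adj-R2 = {result.adj_r2:.2f}%   "
        f"pred-R2 = {result.pred_r2:.2f}%",
        f"error df = {result.error_df}   two-sided |t| threshold "
        f"(alpha={result.alpha_level}) = {result.significance_threshold_t:.2f}",
    ]
    return "\n".join(lines)


def anova_report(model, anova: pd.DataFrame, goodness, optimum=None) -> dict:
    """JSON-able quadratic-fit report: coefficients, ANOVA, goodness, optimum."""
    doc = {
        "coefficients": {
            "intercept": model.beta0,
            "linear": dict(model.linear),
            "square": dict(model.square),
            "interaction": {"*".join(k): v for k, v in model.interaction.items()},
        },
        "anova": {
            str(src): {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
            for src, row in anova.iterrows()
        },
        "goodness": dataclasses.asdict(goodness),
    }
    if optimum is not None:
        doc["optimum"] = {
            "coded": [float(v) for v in optimum.coded],
            "actual": None if optimum.actual is None else [float(v) for v in optimum.actual],
            "predicted_response": optimum.predicted_response,
            "on_boundary": optimum.on_boundary,
            "region": optimum.region,
            "radius": optimum.radius,
        }
    return doc


def format_anova(anova: pd.DataFrame, goodness) -> str:
    lines = ["ANOVA (adjusted SS; F for lack of fit uses the pure-error MS)", ""]
    lines.append(anova.to_string(float_format=lambda v: f"{v:,.2f}"))
    lines += [
        "",
        f"s = {goodness.s:.2f}   R2 = {goodness.r2:.2f}%   adj-R2 = {goodness.adj_r2:.2f}%   "
        f"pred-R2 = {goodness.pred_r2:.2f}%   PRESS = {goodness.press:,.2f}",
    ]
    return "\n".join(lines)


def comparison_report(report: dict) -> dict:
    """JSON-able version of :func:`keraopt.metrics.compare_models` output."""
    out = {"winner": report["winner"], "models": {}}
    for label, block in report["models"].items():
        out["models"][label] = {
            key: (_metrics_dict(val) if isinstance(val, Metrics) else val)
            for key, val in block.items()
        }
    return out


def format_comparison(report: dict) -> str:
    lines = []
    for section in ("training", "validation", "overall"):
        present = [
            (label, block[section])
            for label, block in report["models"].items()
            if section in block
        ]
        if not present:
            continue
        lines.append(f"{section.capitalize()} statistics")
        lines.append(f"{'model':<10}{'R2':>10}{'RMSE':>10}{'MAD':>10}{'SSE':>14}{'n':>5}")
        for label, m in present:
            r2 = "n/a" if m.r2 is None else f"{m.r2:.4f}"
            lines.append(
                f"{label:<10}{r2:>10}{m.rmse:>10.3f}{m.mad:>10.3f}{m.sse:>14,.2f}{m.n:>5}"
            )
        lines.append("")
    lines.append(f"Winner (overall R2, RMSE tiebreak): {report['winner']}")
    return "\n".join(lines)


def write_json(doc: dict, path) -> None:
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")
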