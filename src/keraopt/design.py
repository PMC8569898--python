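"""Experimental designs for screening and response-surface work.

Two designs are supported: the 12-run two-level Plackett-Burman screening
design (up to 11 factors) and the central composite design (CCD), rotatable
by default.  Factor levels are handled in *coded units*:

    x_i = (X_i - X_0) / dX_i

where ``X_0`` is the center of the factor's range and ``dX_i`` the step, so
that factorial points sit at +/-1, the center at 0, and CCD axial (star)
points at +/-alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignMatrix",
    "ResponseTable",
    "code_levels",
    "decode_levels",
    "generate_plackett_burman",
    "generate_ccd",
    "rotatable_alpha",
]

# Cyclic generator row of the standard 12-run Plackett-Burman design; the
# twelfth run is all -1.
_PB12_GENERATOR = (1, 1, -1, 1, 1, 1, -1, -1, -1, 1, -1)


@dataclass(frozen=True)
class Factor:
    """A controllable variable with a coded <-> actual unit mapping.

    Parameters
    ----------
    name : str
        Identifier used in design tables and model terms.
    units : str
        Physical units of the actual scale (e.g. ``"mg/g CFK"``, ``"day"``).
    center : float
        Actual value mapping to coded 0 (the center point).
    step : float
        Actual-scale change corresponding to one coded unit; must be > 0.
    """

    name: str
    units: str = ""
    center: float = 0.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.center):
            raise ValueError(f"factor {self.name!r}: center must be finite")
        if not (np.isfinite(self.step) and self.step > 0):
            raise ValueError(f"factor {self.name!r}: step must be finite and > 0")

    @classmethod
    def from_levels(cls, name: str, low: float, high: float, units: str = "") -> "Factor":
        """Build a factor from its low/high (coded -1/+1) actual levels."""
        if not (high > low):
            raise ValueError(f"factor {name!r}: need high > low, got {low}..{high}")
        return cls(name, units, center=(high + low) / 2.0, step=(high - low) / 2.0)

    def code(self, actual):
        """Map actual values to coded units, (X - center)/step."""
        actual = np.asarray(actual, dtype=float)
        if not np.all(np.isfinite(actual)):
            raise ValueError(f"factor {self.name!r}: non-finite actual value")
        out = (actual - self.center) / self.step
        return float(out) if out.ndim == 0 else out

    def decode(self, coded):
        """Map coded values back to actual units, center + step*x."""
        coded = np.asarray(coded, dtype=float)
        if not np.all(np.isfinite(coded)):
            raise ValueError(f"factor {self.name!r}: non-finite coded value")
        out = self.center + self.step * coded
        return float(out) if out.ndim == 0 else out


def code_levels(factor: Factor, actual):
    """Coded level of ``actual`` for ``factor`` (module-level convenience)."""
    return factor.code(actual)


def decode_levels(factor: Factor, coded):
    """Actual level of coded value ``coded`` for ``factor``."""
    return factor.decode(coded)


@dataclass
class DesignMatrix:
    """A run matrix in coded units plus its factor coding scheme.

    Attributes
    ----------
    factors : list of Factor
        Column order of ``coded``.
    coded : (n_runs, n_factors) ndarray
        Coded factor settings, one row per run.
    point_type : ndarray of str
        One of ``factorial``/``axial``/``center`` per run.
    replicate_id : ndarray of int
        Replicate block each run belongs to (1-based).
    design_kind : str
        ``"plackett_burman"`` or ``"ccd"``.
    """

    factors: list[Factor]
    coded: np.ndarray
    point_type: np.ndarray = field(default=None)
    replicate_id: np.ndarray = field(default=None)
    design_kind: str = "custom"

    def __post_init__(self) -> None:
        self.coded = np.atleast_2d(np.asarray(self.coded, dtype=float))
        n = self.n_runs
        if self.coded.shape[1] != len(self.factors):
            raise ValueError(
                f"coded matrix has {self.coded.shape[1]} columns for "
                f"{len(self.factors)} factors"
            )
        if self.point_type is None:
            self.point_type = np.array([_classify_point(r) for r in self.coded])
        else:
            self.point_type = np.asarray(self.point_type, dtype=object)
        if self.replicate_id is None:
            self.replicate_id = np.ones(n, dtype=int)
        else:
            self.replicate_id = np.asarray(self.replicate_id, dtype=int)
        if len(self.point_type) != n or len(self.replicate_id) != n:
            raise ValueError("point_type / replicate_id length mismatch with runs")

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def actual(self) -> np.ndarray:
        """Run matrix in actual units."""
        return np.column_stack([f.decode(self.coded[:, j]) for j, f in enumerate(self.factors)])

    def column(self, name: str) -> np.ndarray:
        """Coded column for factor ``name``."""
        try:
            j = self.factor_names.index(name)
        except ValueError:
            raise KeyError(f"no factor named {name!r}; have {self.factor_names}") from None
        return self.coded[:, j]

    def replicate_groups(self) -> list[np.ndarray]:
        """Indices of runs sharing identical coded settings (for pure error)."""
        keys: dict[tuple, list[int]] = {}
        for i, row in enumerate(np.round(self.coded, 10)):
            keys.setdefault(tuple(row), []).append(i)
        return [np.asarray(v) for v in keys.values()]

    def to_frame(self, include_actual: bool = True) -> pd.DataFrame:
        """Tabular view: run id, coded (x_*) and actual columns, metadata."""
        out = pd.DataFrame({"run": np.arange(1, self.n_runs + 1)})
        for j, f in enumerate(self.factors):
            out[f"x_{f.name}"] = self.coded[:, j]
        if include_actual:
            act = self.actual()
            for j, f in enumerate(self.factors):
                out[f.name] = act[:, j]
        out["point_type"] = self.point_type
        out["replicate_id"] = self.replicate_id
        return out


@dataclass
class ResponseTable:
    """Measured response per run, with optional replicate SDs and subset flags.

    ``subset`` entries, when present, are ``"training"`` / ``"validation"``
    and partition the runs (used for holdback-style model assessment).
    """

    response: np.ndarray
    sd: np.ndarray | None = None
    subset: np.ndarray | None = None
    run_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float).ravel()
        n = len(self.response)
        if not np.all(np.isfinite(self.response)):
            raise ValueError("responses must be finite")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float).ravel()
            if len(self.sd) != n or np.any(self.sd < 0):
                raise ValueError("sd must align with responses and be >= 0")
        if self.subset is not None:
            self.subset = np.asarray(self.subset, dtype=object).ravel()
            bad = set(self.subset) - {"training", "validation"}
            if len(self.subset) != n or bad:
                raise ValueError(f"subset labels must partition runs into training/validation; got {bad}")
        if self.run_id is None:
            self.run_id = np.arange(1, n + 1)
        else:
            self.run_id = np.asarray(self.run_id, dtype=int).ravel()
            if len(self.run_id) != n:
                raise ValueError("run_id length mismatch")
            if len(set(self.run_id.tolist())) != n:
                raise ValueError("duplicate run ids")

    def __len__(self) -> int:
        return len(self.response)

    def mask(self, subset: str) -> np.ndarray:
        """Boolean mask of runs labelled ``subset`` (training/validation)."""
        if self.subset is None:
            raise ValueError("this response table carries no subset labels")
        return self.subset == subset


def _classify_point(row: np.ndarray, atol: float = 1e-9) -> str:
    if np.all(np.abs(row) < atol):
        return "center"
    if np.all(np.abs(np.abs(row) - 1.0) < atol):
        return "factorial"
    nz = np.abs(row) > atol
    if nz.sum() == 1:
        return "axial"
    return "factorial"


def generate_plackett_burman(n_factors: int, factors: list[Factor] | None = None) -> DesignMatrix:
    """12-run Plackett-Burman screening design for up to 11 factors.

    Constructed from the standard cyclic generator row; every column carries
    six +1 and six -1 and all column pairs are orthogonal.  The first
    ``n_factors`` columns are assigned to factors; remaining columns are
    implicit dummy contrasts (not returned).
    """
    if not (1 <= n_factors <= 11):
        raise ValueError(
            f"n_factors={n_factors}: the 12-run Plackett-Burman design "
            "accommodates 1..11 factors"
        )
    gen = np.array(_PB12_GENERATOR, dtype=float)
    rows = [np.roll(gen, i) for i in range(11)]
    rows.append(-np.ones(11))
    full = np.array(rows)
    coded = full[:, :n_factors]
    if factors is None:
        factors = [Factor(f"F{j + 1}") for j in range(n_factors)]
    elif len(factors) != n_factors:
        raise ValueError("len(factors) must equal n_factors")
    return DesignMatrix(
        factors=list(factors),
        coded=coded,
        point_type=np.array(["factorial"] * 12, dtype=object),
        replicate_id=np.ones(12, dtype=int),
        design_kind="plackett_burman",
    )


def rotatable_alpha(k: int) -> float:
    """Axial distance (2^k)^(1/4) giving a rotatable CCD for k factors."""
    return float((2.0 ** k) ** 0.25)


def generate_ccd(
    factors: list[Factor],
    alpha: float | None = None,
    n_center: int = 6,
    n_replicates: int = 1,
) -> DesignMatrix:
    """Central composite design: 2^k factorial + 2k axial + center runs.

    ``alpha`` defaults to the rotatable value (2^k)^(1/4).  The whole block
    (factorial, then axial, then center) is repeated ``n_replicates`` times;
    run order within a block is metadata only, since all fits here are
    order-invariant.
    """
    k = len(factors)
    if k < 2:
        raise ValueError("a CCD needs at least 2 factors")
    if alpha is None:
        alpha = rotatable_alpha(k)
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    if n_center < 1 or n_replicates < 1:
        raise ValueError("n_center and n_replicates must be >= 1")

    fact = np.array(list(itertools.product([-1.0, 1.0], repeat=k)))
    axial = np.zeros((2 * k, k))
    for j in range(k):
        axial[2 * j, j] = -alpha
        axial[2 * j + 1, j] = alpha
    center = np.zeros((n_center, k))
    block = np.vstack([fact, axial, center])
    ptype = (["factorial"] * len(fact)) + (["axial"] * len(axial)) + (["center"] * n_center)

    coded = np.vstack([block] * n_replicates)
    point_type = np.array(ptype * n_replicates, dtype=object)
    replicate_id = np.repeat(np.arange(1, n_replicates + 1), len(block))
    return DesignMatrix(
        factors=list(factors),
        coded=coded,
        point_type=point_type,
        replicate_id=replicate_id,
        design_kind="ccd",
    )
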