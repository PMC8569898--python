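"""Synthetic response generators matching the modeling assumptions.

Screening data are generated from chosen main effects plus homoscedastic
Gaussian noise; central-composite data from a known second-order surface
plus Gaussian noise.  The default noise scale for surface simulations,
sd = 42.6, is the square root of the pure-error mean square estimated from
the replicated study design (MS about 1815), i.e. the replication noise the
real experiment exhibited.  Both generators are seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import FIXTURES, load_fixture
from .design import DesignMatrix, ResponseTable
from .rsm import QuadraticModel

__all__ = [
    "PAPER_NOISE_SD",
    "SurfaceTruth",
    "simulate_ccd_response",
    "simulate_pb_response",
    "load_fixture",
    "FIXTURES",
]

# sqrt of the pure-error mean square of the replicated CCD (45,371 / 25)
PAPER_NOISE_SD = float(np.sqrt(45_371.0 / 25.0))


@dataclass
class SurfaceTruth:
    """A known second-order surface in coded units plus a noise level."""

    model: QuadraticModel
    noise_sd: float = PAPER_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_ccd_response(truth: SurfaceTruth, design: DesignMatrix) -> ResponseTable:
    """Quadratic surface evaluated on the design plus N(0, noise_sd) error."""
    if design.factor_names != truth.model.factor_names:
        raise ValueError(
            f"design factors {design.factor_names} do not match surface factors "
            f"{truth.model.factor_names}"
        )
    mean = truth.model.predict_coded(design.coded)
    rng = np.random.default_rng(truth.seed)
    y = mean + rng.normal(0.0, truth.noise_sd, size=design.n_runs)
    return ResponseTable(response=y)


def simulate_pb_response(
    effects: dict[str, float],
    baseline: float,
    noise_sd: float,
    seed: int,
    design: DesignMatrix,
) -> ResponseTable:
    """Two-level screening response: baseline + coded x (effect/2) + noise.

    Factors absent from ``effects`` contribute nothing (true effect zero).
    """
    unknown = set(effects) - set(design.factor_names)
    if unknown:
        raise ValueError(f"effects given for factors not in the design: {sorted(unknown)}")
    if not np.all(np.isclose(np.abs(design.coded), 1.0)):
        raise ValueError("simulate_pb_response requires a two-level design")
    mean = np.full(design.n_runs, float(baseline))
    for name, eff in effects.items():
        mean += design.column(name) * (eff / 2.0)
    rng = np.random.default_rng(seed)
    y = mean + rng.normal(0.0, noise_sd, size=design.n_runs)
    return ResponseTable(response=y)
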