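"""Shared least-squares plumbing: fit, leverages, PRESS.

Small and deliberately boring; every user-facing statistic is assembled in
`screening` / `rsm` from these pieces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class OLSFit:
    coef: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    hat_diag: np.ndarray
    sse: float
    cov_unscaled: np.ndarray  # (X'X)^{-1}
    df_resid: int

    @property
    def press(self) -> float:
        """Leave-one-out prediction error SS via the hat-matrix identity."""
        return float(np.sum((self.residuals / (1.0 - self.hat_diag)) ** 2))

    def coef_se(self, sigma2: float | None = None) -> np.ndarray:
        s2 = self.sse / self.df_resid if sigma2 is None else sigma2
        return np.sqrt(s2 * np.diag(self.cov_unscaled))


def fit_ols(X: np.ndarray, y: np.ndarray) -> OLSFit:
    """Ordinary least squares with an explicit rank check.

    Raises ``ValueError`` naming the offending columns when the model matrix
    is rank-deficient (collinear terms), since a silent pseudo-inverse fit
    would make the per-term ANOVA meaningless.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"{n} rows in model matrix but {len(y)} responses")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # locate a minimal set of dependent columns for the error message
        _, r = np.linalg.qr(X)
        dep = [j for j in range(p) if abs(r[min(j, r.shape[0] - 1), j]) < 1e-10 * max(1.0, abs(r).max())]
        raise ValueError(f"model matrix is rank deficient (rank {rank} < {p}); suspect columns {dep}")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    xtx_inv = np.linalg.inv(X.T @ X)
    hat = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    return OLSFit(
        coef=coef,
        fitted=fitted,
        residuals=resid,
        hat_diag=hat,
        sse=float(resid @ resid),
        cov_unscaled=xtx_inv,
        df_resid=n - p,
    )
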