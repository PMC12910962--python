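"""Pointwise and global R-squared for multilevel functional models.

At each grid point t the coefficient of determination is computed across all
observed (subject, meal) pairs,

    R2(t) = 1 - sum_ij (Y_ij(t) - Yhat_ij(t))^2 / sum_ij (Y_ij(t) - Ybar(t))^2,

with Ybar(t) the grand mean over the pairs observed at t.  The global value
is the time average of the pointwise curve, approximated by trapezoidal
quadrature and divided by the window span, so a constant pointwise curve
aggregates to its own value.  Values can be negative (a fit worse than the
pointwise grand mean); they are reported as-is.  Grid points where the
denominator vanishes are flagged NaN and excluded from the aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .containers import MultilevelFunctionalData
from .grid import FunctionalGrid

if TYPE_CHECKING:  # pragma: no cover
    from .fosr import FoSRFit
    from .mfpca import MFPCAFit

__all__ = ["R2Curve", "GlobalR2", "pointwise_r2", "global_r2", "fosr_r2", "mfpca_r2"]


@dataclass
class R2Curve:
    grid: FunctionalGrid
    values: np.ndarray  # NaN where undefined
    variant: str = "custom"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid),):
            raise ValueError("R2 curve must have one value per grid point")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.any(finite > 1 + 1e-10):
            raise ValueError("pointwise R2 cannot exceed 1")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class GlobalR2:
    value: float
    variant: str = "custom"
    quadrature: str = "trapezoid"

    def __post_init__(self) -> None:
        if self.value > 1 + 1e-10:
            raise ValueError("global R2 cannot exceed 1")


def pointwise_r2(
    observed: MultilevelFunctionalData | np.ndarray,
    fitted: np.ndarray,
    grid: FunctionalGrid | None = None,
    variant: str = "custom",
) -> R2Curve:
    """Pointwise coefficient of determination across curves.

    Missing observations (and entries missing in the fitted surface) are
    excluded pairwise from both sums; a grid point needs at least two
    observed values with nonzero spread, otherwise it is flagged NaN.
    """
    if isinstance(observed, MultilevelFunctionalData):
        grid = observed.grid
        Y = observed.curves
    else:
        if grid is None:
            raise ValueError("grid is required when passing a bare array")
        Y = np.asarray(observed, dtype=float)
    F = np.asarray(fitted, dtype=float)
    if F.shape != Y.shape:
        raise ValueError("observed and fitted shapes differ")
    mask = np.isfinite(Y) & np.isfinite(F)
    counts = mask.sum(axis=0)
    Y0 = np.where(mask, Y, 0.0)
    F0 = np.where(mask, F, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ybar = Y0.sum(axis=0) / counts
        ss_res = np.where(mask, (Y0 - F0) ** 2, 0.0).sum(axis=0)
        ss_tot = np.where(mask, (Y0 - ybar) ** 2, 0.0).sum(axis=0)
        values = 1.0 - ss_res / ss_tot
    values = np.where((counts >= 2) & (ss_tot > 0), values, np.nan)
    return R2Curve(grid=grid, values=values, variant=variant)


def global_r2(curve: R2Curve) -> GlobalR2:
    """Time-averaged R2 by trapezoidal quadrature over the valid subgrid."""
    valid = curve.valid
    if valid.sum() < 2:
        raise ValueError("global R2 needs at least two valid grid points")
    t = curve.grid.times[valid]
    v = curve.values[valid]
    value = float(np.trapezoid(v, t) / (t[-1] - t[0]))
    return GlobalR2(value=value, variant=curve.variant)


def fosr_r2(
    fit: "FoSRFit", data: MultilevelFunctionalData, design
) -> tuple[tuple[R2Curve, GlobalR2], tuple[R2Curve, GlobalR2]]:
    """Marginal (fixed effects only) and conditional (plus alpha_i) R2."""
    from .fosr import predict

    marg = predict(fit, design, mode="marginal")
    cond = predict(fit, design, subject_ids=data.subject_ids, mode="conditional")
    m_curve = pointwise_r2(data, marg, variant="fosr_marginal")
    c_curve = pointwise_r2(data, cond, variant="fosr_conditional")
    return (m_curve, global_r2(m_curve)), (c_curve, global_r2(c_curve))


def mfpca_r2(
    fit: "MFPCAFit", data: MultilevelFunctionalData
) -> tuple[tuple[R2Curve, GlobalR2], tuple[R2Curve, GlobalR2]]:
    """Participant-level and full-model reconstruction R2."""
    from .mfpca import reconstruct

    part = reconstruct(fit, level="participant_only")
    full = reconstruct(fit, level="full")
    p_curve = pointwise_r2(data, part, variant="mfpca_participant")
    f_curve = pointwise_r2(data, full, variant="mfpca_full")
    return (p_curve, global_r2(p_curve)), (f_curve, global_r2(f_curve))
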