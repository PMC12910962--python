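"""Sampling grids for postprandial windows and quadrature on them.

Postprandial CGM curves are observed on a regular grid of minutes since the
meal, nominally every 5 minutes over a 6-hour (0-360 min) window.  All inner
products, norms and integrals in this package use trapezoidal quadrature on
the grid, so eigenfunctions returned by the decompositions are orthonormal in
the L2([0, 360]) sense, not merely as coordinate vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FunctionalGrid", "make_default_grid"]

DEFAULT_WINDOW_MINUTES = 360.0
DEFAULT_STEP_MINUTES = 5.0


@dataclass(frozen=True)
class FunctionalGrid:
    """Strictly increasing sampling times (minutes since meal).

    Parameters
    ----------
    times
        Sampling times in minutes; must be finite, unique and sorted
        ascending, starting at 0.
    step
        Nominal sampling interval in minutes (5 for the CGM devices this
        package models).  Used for alignment tolerances; the grid itself may
        be irregular.
    """

    times: np.ndarray
    step: float = DEFAULT_STEP_MINUTES

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("grid needs at least two time points")
        if not np.all(np.isfinite(times)):
            raise ValueError("grid times must be finite")
        if np.any(np.diff(times) <= 0):
            raise ValueError("grid times must be strictly increasing")
        if times[0] != 0:
            raise ValueError("postprandial grid must start at 0 minutes")
        if self.step <= 0:
            raise ValueError("step must be positive")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> float:
        """Length of the window in minutes (360 for the default grid)."""
        return float(self.times[-1] - self.times[0])

    @property
    def quad_weights(self) -> np.ndarray:
        """Trapezoidal quadrature weights w with sum(w) == span."""
        return trapezoid_weights(self.times)

    def inner(self, f: np.ndarray, g: np.ndarray) -> float:
        """L2 inner product <f, g> = integral of f*g over the window."""
        w = self.quad_weights
        return float(np.sum(w * np.asarray(f) * np.asarray(g)))

    def norm(self, f: np.ndarray) -> float:
        return float(np.sqrt(max(self.inner(f, f), 0.0)))


def trapezoid_weights(times: np.ndarray) -> np.ndarray:
    """Trapezoid-rule weights for an arbitrary sorted grid."""
    times = np.asarray(times, dtype=float)
    d = np.diff(times)
    w = np.zeros_like(times)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w


def make_default_grid() -> FunctionalGrid:
    """The standard 5-minute grid over the 6-hour postprandial window.

    Returns the 73-point grid 0, 5, ..., 360 minutes.
    """
    times = np.arange(0.0, DEFAULT_WINDOW_MINUTES + DEFAULT_STEP_MINUTES / 2,
                      DEFAULT_STEP_MINUTES)
    return FunctionalGrid(times=times, step=DEFAULT_STEP_MINUTES)
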