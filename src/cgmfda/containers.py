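"""In-memory containers for hierarchically observed curves.

The central object is :class:`MultilevelFunctionalData`: a stack of
postprandial glucose curves Y_ij(t) on a common grid, one row per
(subject, meal) pair, with NaN marking grid points where no CGM sample was
available.  Missing entries are first-class citizens — no estimator in this
package imputes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import FunctionalGrid

__all__ = ["MultilevelFunctionalData"]


@dataclass
class MultilevelFunctionalData:
    """Curves Y_ij(t) on a shared grid with subject / meal indexing.

    Parameters
    ----------
    grid
        Common sampling grid.
    curves
        Array of shape (n_rows, len(grid)); NaN = missing.
    subject_ids
        One id per row (any hashable, typically str or int).
    meal_index
        Within-subject meal number, 1..J_i, one per row.
    """

    grid: FunctionalGrid
    curves: np.ndarray
    subject_ids: np.ndarray
    meal_index: np.ndarray

    def __post_init__(self) -> None:
        self.curves = np.asarray(self.curves, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        self.meal_index = np.asarray(self.meal_index, dtype=int)
        n, m = self.curves.shape if self.curves.ndim == 2 else (0, 0)
        if self.curves.ndim != 2 or m != len(self.grid):
            raise ValueError(
                f"curves must be 2-D with {len(self.grid)} columns to match the grid"
            )
        if self.subject_ids.shape != (n,) or self.meal_index.shape != (n,):
            raise ValueError("subject_ids and meal_index must have one entry per row")
        if np.any(self.meal_index < 1):
            raise ValueError("meal_index is 1-based")

    # -- basic structure -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.curves.shape[0]

    @property
    def subjects(self) -> np.ndarray:
        """Unique subject ids in order of first appearance."""
        _, idx = np.unique(self.subject_ids, return_index=True)
        return self.subject_ids[np.sort(idx)]

    @property
    def n_subjects(self) -> int:
        return self.subjects.size

    def meals_per_subject(self) -> pd.Series:
        return pd.Series(self.meal_index).groupby(self.subject_ids).size()

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing entries."""
        return np.isfinite(self.curves)

    def observed_fraction(self) -> np.ndarray:
        """Per-row fraction of observed grid points."""
        return self.observed.mean(axis=1)

    def require_min_observed(self, min_fraction: float) -> "MultilevelFunctionalData":
        """Return the subset of rows meeting a minimum observed fraction."""
        keep = self.observed_fraction() >= min_fraction
        return self.take(np.flatnonzero(keep))

    def take(self, rows: np.ndarray) -> "MultilevelFunctionalData":
        return MultilevelFunctionalData(
            grid=self.grid,
            curves=self.curves[rows],
            subject_ids=self.subject_ids[rows],
            meal_index=self.meal_index[rows],
        )

    # -- long-format interchange ----------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        """Long CSV dialect: subject_id, meal_index, time_min, glucose."""
        n, m = self.curves.shape
        frame = pd.DataFrame(
            {
                "subject_id": np.repeat(self.subject_ids, m),
                "meal_index": np.repeat(self.meal_index, m),
                "time_min": np.tile(self.grid.times, n),
                "glucose": self.curves.ravel(),
            }
        )
        return frame[np.isfinite(frame["glucose"].to_numpy())].reset_index(drop=True)

    @classmethod
    def from_long_frame(
        cls, frame: pd.DataFrame, grid: FunctionalGrid
    ) -> "MultilevelFunctionalData":
        required = {"subject_id", "meal_index", "time_min", "glucose"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"long frame is missing columns: {sorted(missing)}")
        time_pos = {t: k for k, t in enumerate(grid.times)}
        keys = frame[["subject_id", "meal_index"]].drop_duplicates().to_numpy()
        curves = np.full((len(keys), len(grid)), np.nan)
        row_of = {(s, int(j)): r for r, (s, j) in enumerate(keys)}
        for s, j, t, y in frame[
            ["subject_id", "meal_index", "time_min", "glucose"]
        ].itertuples(index=False):
            k = time_pos.get(float(t))
            if k is None:
                raise ValueError(f"time {t} not on the target grid")
            curves[row_of[(s, int(j))], k] = y
        return cls(
            grid=grid,
            curves=curves,
            subject_ids=keys[:, 0],
            meal_index=keys[:, 1].astype(int),
        )
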