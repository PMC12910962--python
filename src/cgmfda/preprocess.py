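"""Raw CGM streams + meal diaries -> aligned postprandial curves.

Extraction takes the 6 hours of CGM samples after each reported meal time
and aligns them to the common grid by nearest-sample matching within half
the nominal sampling step; grid points with no sample nearby stay missing
(no interpolation, no imputation).  The pre-meal glucose covariate is the
sample nearest to 5 minutes before the meal.

Quality control mirrors conservative CGM practice: windows that start during
the first 24 hours of sensor wear (when accuracy is markedly lower) are
dropped, and windows containing a contiguous signal-loss run of more than
two hours are dropped.  Both thresholds are configurable; the gap rule is
strictly greater-than, so a gap of exactly the threshold is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import MultilevelFunctionalData
from .grid import FunctionalGrid

__all__ = [
    "CgmStream",
    "MealRecord",
    "ExtractedWindows",
    "Exclusion",
    "extract_postprandial_windows",
    "apply_quality_filters",
]

INITIAL_GLUCOSE_OFFSET_MIN = 5.0  # pre-meal reading taken 5 min before the meal


@dataclass
class CgmStream:
    """One subject's CGM trace: strictly increasing timestamps (timezone-
    naive local clock time) and finite positive glucose in mg/dL."""

    subject_id: str
    timestamps: np.ndarray  # datetime64[ns]
    glucose: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[ns]")
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.timestamps.shape != self.glucose.shape:
            raise ValueError("timestamps and glucose must align")
        if self.timestamps.size and np.any(np.diff(self.timestamps).astype(np.int64) <= 0):
            raise ValueError("timestamps must be strictly increasing (no duplicates)")
        if np.any(~np.isfinite(self.glucose)) or np.any(self.glucose <= 0):
            raise ValueError("glucose values must be finite and positive")


@dataclass
class MealRecord:
    """One diary entry: when the meal was eaten and its nutrient content."""

    subject_id: str
    timestamp: pd.Timestamp
    label: str
    carbohydrates: float = 0.0
    fats: float = 0.0
    proteins: float = 0.0
    fiber: float = 0.0

    def __post_init__(self) -> None:
        self.timestamp = pd.Timestamp(self.timestamp)
        for name in ("carbohydrates", "fats", "proteins", "fiber"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} grams must be nonnegative")


@dataclass
class ExtractedWindows:
    """Aligned curves plus the per-row context needed by filters and FoSR."""

    data: MultilevelFunctionalData
    initial_glucose: np.ndarray  # per row; NaN when no pre-meal sample
    meal_times: np.ndarray  # datetime64[ns] per row
    meals: list[MealRecord] = field(default_factory=list)  # per row

    @property
    def n_rows(self) -> int:
        return self.data.n_rows


@dataclass(frozen=True)
class Exclusion:
    subject_id: str
    meal_time: pd.Timestamp
    rule: str
    detail: str


def _nearest_samples(
    stream: CgmStream, targets: np.ndarray, tol_minutes: float
) -> np.ndarray:
    """Value of the stream sample nearest each target time, NaN beyond tol."""
    out = np.full(targets.size, np.nan)
    if stream.timestamps.size == 0:
        return out
    st = stream.timestamps.astype("datetime64[ns]").astype(np.int64)
    tg = targets.astype("datetime64[ns]").astype(np.int64)
    pos = np.searchsorted(st, tg)
    tol = int(tol_minutes * 60 * 1e9)
    for i, (t, p) in enumerate(zip(tg, pos)):
        best, best_d = -1, tol + 1
        for cand in (p - 1, p):
            if 0 <= cand < st.size:
                d = abs(int(st[cand]) - int(t))
                if d < best_d:
                    best, best_d = cand, d
        if best >= 0 and best_d <= tol:
            out[i] = stream.glucose[best]
    return out


def extract_postprandial_windows(
    stream: CgmStream,
    meals: Sequence[MealRecord],
    grid: FunctionalGrid,
    label_filter: str | None = "dinner",
) -> ExtractedWindows:
    """Aligned 6-hour windows for each of one subject's matching meals.

    Meals not matching ``label_filter`` (case-insensitive; ``None`` keeps
    all) are skipped.  Windows are returned in chronological meal order with
    meal_index 1..J.  Empty inputs yield an empty result, not an error.
    """
    for meal in meals:
        if meal.subject_id != stream.subject_id:
            raise ValueError(
                f"meal for subject {meal.subject_id!r} does not belong to "
                f"stream subject {stream.subject_id!r}"
            )
    selected = [
        m
        for m in meals
        if label_filter is None or m.label.lower() == label_filter.lower()
    ]
    selected.sort(key=lambda m: m.timestamp)
    tol = grid.step / 2.0
    curves, init, times = [], [], []
    for meal in selected:
        t0 = np.datetime64(meal.timestamp, "ns")
        targets = t0 + (grid.times * 60e9).astype("timedelta64[ns]")
        curves.append(_nearest_samples(stream, targets, tol))
        pre = t0 - np.timedelta64(int(INITIAL_GLUCOSE_OFFSET_MIN * 60e9), "ns")
        init.append(_nearest_samples(stream, np.array([pre]), tol)[0])
        times.append(t0)
    n = len(selected)
    data = MultilevelFunctionalData(
        grid=grid,
        curves=np.vstack(curves) if n else np.empty((0, len(grid))),
        subject_ids=np.array([stream.subject_id] * n),
        meal_index=np.arange(1, n + 1),
    )
    return ExtractedWindows(
        data=data,
        initial_glucose=np.array(init),
        meal_times=np.array(times, dtype="datetime64[ns]"),
        meals=selected,
    )


def concat_windows(parts: Sequence[ExtractedWindows]) -> ExtractedWindows:
    """Stack per-subject extractions into one dataset."""
    parts = [p for p in parts if p.n_rows > 0]
    if not parts:
        raise ValueError("no windows to concatenate")
    grid = parts[0].data.grid
    data = MultilevelFunctionalData(
        grid=grid,
        curves=np.vstack([p.data.curves for p in parts]),
        subject_ids=np.concatenate([p.data.subject_ids for p in parts]),
        meal_index=np.concatenate([p.data.meal_index for p in parts]),
    )
    return ExtractedWindows(
        data=data,
        initial_glucose=np.concatenate([p.initial_glucose for p in parts]),
        meal_times=np.concatenate([p.meal_times for p in parts]),
        meals=[m for p in parts for m in p.meals],
    )


def _longest_gap_minutes(row_observed: np.ndarray, times: np.ndarray) -> float:
    """Longest contiguous signal-loss span in one window, in minutes.

    For an interior run of missing grid points the span runs between the
    nearest observed neighbours; for a run touching a window edge it runs
    from the edge to the first/last observed point.
    """
    if row_observed.all():
        return 0.0
    if not row_observed.any():
        return float(times[-1] - times[0])
    obs_idx = np.flatnonzero(row_observed)
    longest = max(float(times[obs_idx[0]] - times[0]),
                  float(times[-1] - times[obs_idx[-1]]))
    gaps = np.diff(times[obs_idx])
    interior = gaps[gaps > 0]
    if interior.size:
        longest = max(longest, float(interior.max()))
    return longest


def apply_quality_filters(
    windows: ExtractedWindows,
    wear_start: Mapping[str, pd.Timestamp] | None = None,
    max_gap_minutes: float = 120.0,
    discard_first_hours: float = 24.0,
) -> tuple[ExtractedWindows, list[Exclusion]]:
    """Drop low-quality windows; return the survivors and an exclusion log.

    Rules, in order: (1) windows whose meal time falls within
    ``discard_first_hours`` of the subject's sensor wear start are removed;
    (2) windows with a contiguous missing run strictly longer than
    ``max_gap_minutes`` are removed.  Meal indices are renumbered 1..J_i
    within subject afterwards.
    """
    if max_gap_minutes < 0 or discard_first_hours < 0:
        raise ValueError("thresholds must be nonnegative")
    if discard_first_hours > 0 and wear_start is None:
        raise ValueError("wear_start is required when discard_first_hours > 0")
    obs = windows.data.observed
    times = windows.data.grid.times
    keep = np.ones(windows.n_rows, dtype=bool)
    log: list[Exclusion] = []
    for r in range(windows.n_rows):
        sid = str(windows.data.subject_ids[r])
        mt = pd.Timestamp(windows.meal_times[r])
        if discard_first_hours > 0 and wear_start is not None and sid in wear_start:
            elapsed_h = (mt - pd.Timestamp(wear_start[sid])).total_seconds() / 3600.0
            if elapsed_h < discard_first_hours:
                keep[r] = False
                log.append(Exclusion(
                    sid, mt, "first_wear_hours",
                    f"meal {elapsed_h:.1f} h after wear start "
                    f"(< {discard_first_hours} h)",
                ))
                continue
        gap = _longest_gap_minutes(obs[r], times)
        if gap > max_gap_minutes:
            keep[r] = False
            log.append(Exclusion(
                sid, mt, "max_gap",
                f"longest signal loss {gap:.0f} min (> {max_gap_minutes:.0f} min)",
            ))
    rows = np.flatnonzero(keep)
    new_meal_index = _renumber(windows.data.subject_ids[rows])
    data = MultilevelFunctionalData(
        grid=windows.data.grid,
        curves=windows.data.curves[rows],
        subject_ids=windows.data.subject_ids[rows],
        meal_index=new_meal_index,
    )
    filtered = ExtractedWindows(
        data=data,
        initial_glucose=windows.initial_glucose[rows],
        meal_times=windows.meal_times[rows],
        meals=[windows.meals[r] for r in rows] if windows.meals else [],
    )
    return filtered, log


def _renumber(subject_ids: np.ndarray) -> np.ndarray:
    out = np.empty(subject_ids.size, dtype=int)
    counters: dict = {}
    for i, s in enumerate(subject_ids):
        counters[s] = counters.get(s, 0) + 1
        out[i] = counters[s]
    return out
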