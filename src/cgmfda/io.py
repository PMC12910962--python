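"""Delimited-text readers/writers for every on-disk artifact.

CSV is the interchange format for curves, covariates, scores and coefficient
tables; YAML for configs, truth files and fit metadata.  Every table written
here carries a leading metadata block of ``# key: value`` comment lines
(config hash, seed, writer version) sufficient to reproduce it; the readers
skip those lines transparently.  Timestamps are ISO-8601, glucose is mg/dL.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import MultilevelFunctionalData
from .grid import FunctionalGrid
from .preprocess import CgmStream, Exclusion, MealRecord
from .simulate import SimulatedDataset

__all__ = [
    "write_table",
    "read_table",
    "read_cgm_long",
    "write_cgm_long",
    "read_meals",
    "write_meals",
    "read_covariates",
    "write_curves_long",
    "read_curves_long",
    "write_dataset",
    "write_exclusion_log",
    "dataset_to_raw_streams",
    "config_hash",
]

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1"


# ---------------------------------------------------------------------------
# metadata-carrying tables
# ---------------------------------------------------------------------------

def config_hash(payload: Mapping) -> str:
    """Stable short hash of a config-like mapping."""
    canon = yaml.safe_dump(_plain(payload), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _plain(obj):
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (pd.Index, pd.Series)):
        return _plain(obj.to_numpy())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_table(
    frame: pd.DataFrame, path: str | Path, meta: Mapping | None = None,
    index: bool = False,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# format_version: {FORMAT_VERSION}"]
    for key, val in (meta or {}).items():
        lines.append(f"# {key}: {val}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        frame.to_csv(fh, index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_table_meta(path: str | Path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
    return meta


# ---------------------------------------------------------------------------
# raw CGM / diary dialects
# ---------------------------------------------------------------------------

class _StreamList(list):
    """List of CgmStream with the count of skipped malformed rows attached."""

    n_skipped: int = 0


def read_cgm_long(path: str | Path) -> _StreamList:
    """CGM long CSV (subject_id, timestamp, glucose) -> per-subject streams.

    Streams are grouped by subject and sorted by timestamp.  Rows with an
    unparseable timestamp or a non-finite/nonpositive glucose value are
    skipped; the count is logged and exposed as ``result.n_skipped``.
    """
    frame = read_table(path)
    for col in ("subject_id", "timestamp", "glucose"):
        if col not in frame.columns:
            raise ValueError(f"CGM file {path} is missing required column {col!r}")
    ts = pd.to_datetime(frame["timestamp"], errors="coerce")
    glu = pd.to_numeric(frame["glucose"], errors="coerce")
    ok = ts.notna() & np.isfinite(glu) & (glu > 0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("skipped %d malformed CGM rows in %s", n_skipped, path)
    frame = frame.loc[ok].assign(timestamp=ts[ok], glucose=glu[ok])
    streams = _StreamList()
    streams.n_skipped = n_skipped
    for sid, sub in frame.groupby("subject_id", sort=True):
        sub = sub.sort_values("timestamp").drop_duplicates("timestamp")
        streams.append(
            CgmStream(
                subject_id=str(sid),
                timestamps=sub["timestamp"].to_numpy(dtype="datetime64[ns]"),
                glucose=sub["glucose"].to_numpy(dtype=float),
            )
        )
    return streams


def write_cgm_long(
    streams: Sequence[CgmStream], path: str | Path, meta: Mapping | None = None
) -> None:
    frames = [
        pd.DataFrame(
            {
                "subject_id": s.subject_id,
                "timestamp": pd.Series(s.timestamps).dt.strftime("%Y-%m-%dT%H:%M:%S"),
                "glucose": s.glucose,
            }
        )
        for s in streams
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["subject_id", "timestamp", "glucose"])
    )
    write_table(out, path, meta)


def read_meals(path: str | Path) -> list[MealRecord]:
    """Meal CSV (subject_id, timestamp, label, carb_g, fat_g, protein_g,
    fiber_g) -> records."""
    frame = read_table(path)
    required = ["subject_id", "timestamp", "label"]
    for col in required:
        if col not in frame.columns:
            raise ValueError(f"meal file {path} is missing required column {col!r}")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            MealRecord(
                subject_id=str(row.subject_id),
                timestamp=pd.Timestamp(row.timestamp),
                label=str(row.label),
                carbohydrates=float(getattr(row, "carb_g", 0.0)),
                fats=float(getattr(row, "fat_g", 0.0)),
                proteins=float(getattr(row, "protein_g", 0.0)),
                fiber=float(getattr(row, "fiber_g", 0.0)),
            )
        )
    return out


def write_meals(
    meals: Sequence[MealRecord], path: str | Path, meta: Mapping | None = None
) -> None:
    out = pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in meals],
            "timestamp": [m.timestamp.strftime("%Y-%m-%dT%H:%M:%S") for m in meals],
            "label": [m.label for m in meals],
            "carb_g": [m.carbohydrates for m in meals],
            "fat_g": [m.fats for m in meals],
            "protein_g": [m.proteins for m in meals],
            "fiber_g": [m.fiber for m in meals],
        }
    )
    write_table(out, path, meta)


def read_covariates(path: str | Path) -> pd.DataFrame:
    frame = read_table(path)
    if "subject_id" not in frame.columns:
        raise ValueError(f"covariate file {path} is missing column 'subject_id'")
    frame["subject_id"] = frame["subject_id"].astype(str)
    return frame


# ---------------------------------------------------------------------------
# curve matrices (long dialect shared with the synthetic generator)
# ---------------------------------------------------------------------------

def write_curves_long(
    data: MultilevelFunctionalData, path: str | Path, meta: Mapping | None = None
) -> None:
    write_table(data.to_long_frame(), path, meta)


def read_curves_long(
    path: str | Path, grid: FunctionalGrid | None = None
) -> MultilevelFunctionalData:
    frame = read_table(path)
    frame["subject_id"] = frame["subject_id"].astype(str)
    if grid is None:
        times = np.sort(frame["time_min"].unique().astype(float))
        step = float(np.median(np.diff(times))) if times.size > 1 else 5.0
        grid = FunctionalGrid(times=times, step=step)
    return MultilevelFunctionalData.from_long_frame(frame, grid)


# ---------------------------------------------------------------------------
# simulated datasets
# ---------------------------------------------------------------------------

def write_dataset(
    dataset: SimulatedDataset, out_dir: str | Path, meta: Mapping | None = None
) -> dict[str, Path]:
    """Write curves/covariates/outcomes CSVs plus a YAML truth file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"curves": out_dir / "curves.csv"}
    write_curves_long(dataset.data, paths["curves"], meta)
    if dataset.covariates is not None:
        paths["covariates"] = out_dir / "covariates.csv"
        write_table(dataset.covariates, paths["covariates"], meta)
    if dataset.outcomes is not None:
        paths["outcomes"] = out_dir / "outcomes.csv"
        write_table(
            dataset.outcomes.rename_axis("subject_id").reset_index(),
            paths["outcomes"], meta,
        )
    paths["truth"] = out_dir / "truth.yaml"
    _write_truth(dataset, paths["truth"], meta)
    return paths


def _write_truth(
    dataset: SimulatedDataset, path: Path, meta: Mapping | None
) -> None:
    cfg = dataset.truth.config
    payload = {
        "meta": _plain(dict(meta or {})),
        "config": {
            "n_subjects": cfg.n_subjects,
            "seed": cfg.seed,
            "noise_sd": cfg.noise_sd,
            "grid_times": cfg.grid.times,
            "mean_function": cfg.mean_function,
            "level1_eigenvalues": cfg.level1_eigenvalues,
            "level1_eigenfunctions": cfg.level1_eigenfunctions,
            "level2_eigenvalues": cfg.level2_eigenvalues,
            "level2_eigenfunctions": cfg.level2_eigenfunctions,
            "coefficient_functions": dict(cfg.coefficient_functions or {}),
        },
        "scores_level1": {
            "subject_id": dataset.truth.scores_level1.index,
            "values": dataset.truth.scores_level1.to_numpy(),
        },
        "scores_level2": dataset.truth.scores_level2.to_dict(orient="list"),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(payload), fh, sort_keys=True)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_exclusion_log(log: Sequence[Exclusion], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "subject_id": [e.subject_id for e in log],
            "meal_time": [pd.Timestamp(e.meal_time).isoformat() for e in log],
            "rule": [e.rule for e in log],
            "detail": [e.detail for e in log],
        }
    )
    write_table(frame, path)


# ---------------------------------------------------------------------------
# synthetic data in raw-stream form
# ---------------------------------------------------------------------------

def dataset_to_raw_streams(
    data: MultilevelFunctionalData,
    covariates: pd.DataFrame | None = None,
    start: str | pd.Timestamp = "2015-03-02 20:00",
    wear_lead_hours: float = 30.0,
) -> tuple[list[CgmStream], list[MealRecord], dict[str, pd.Timestamp]]:
    """Render gridded curves as raw CGM streams + dinner diary records.

    Each subject's meal j is placed at ``start`` plus j-1 days, with samples
    exactly on the grid offsets, so re-extraction reproduces the curves
    without interpolation distortion.  Wear start is set ``wear_lead_hours``
    before the first meal so default quality filters keep every window.
    """
    start = pd.Timestamp(start)
    streams: list[CgmStream] = []
    meal_records: list[MealRecord] = []
    wear: dict[str, pd.Timestamp] = {}
    offsets = (data.grid.times * 60e9).astype("timedelta64[ns]")
    for subj in data.subjects:
        rows = np.flatnonzero(data.subject_ids == subj)
        ts_parts, gl_parts = [], []
        for r in rows:
            j = int(data.meal_index[r])
            t0 = np.datetime64(start + pd.Timedelta(days=j - 1), "ns")
            obs = data.observed[r]
            ts_parts.append(t0 + offsets[obs])
            gl_parts.append(data.curves[r, obs])
            nutr = {}
            if covariates is not None:
                match = covariates[
                    (covariates["subject_id"] == subj)
                    & (covariates["meal_index"] == j)
                ]
                if len(match):
                    row = match.iloc[0]
                    nutr = {
                        "carbohydrates": float(row.get("carbohydrates", 0.0)),
                        "fats": float(row.get("fats", 0.0)),
                        "proteins": float(row.get("proteins", 0.0)),
                        "fiber": float(row.get("fiber", 0.0)),
                    }
            meal_records.append(
                MealRecord(
                    subject_id=str(subj),
                    timestamp=pd.Timestamp(t0),
                    label="dinner",
                    **nutr,
                )
            )
        ts = np.concatenate(ts_parts)
        gl = np.concatenate(gl_parts)
        order = np.argsort(ts)
        streams.append(
            CgmStream(subject_id=str(subj), timestamps=ts[order], glucose=gl[order])
        )
        wear[str(subj)] = start - pd.Timedelta(hours=wear_lead_hours)
    return streams, meal_records, wear
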