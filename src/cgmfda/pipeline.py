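"""Pipeline orchestration: simulate -> preprocess -> mfpca -> fosr -> r2 -> latent.

Each stage reads its inputs from, and writes its outputs to, a shared
artifact directory, so stages can be run individually (via the CLI) or
end-to-end with :func:`run_pipeline`.  All numeric outputs are reproducible:
every file's metadata block records the config hash and seed, and rerunning
with the same config and inputs produces byte-identical tables.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fosr as fosr_mod
from . import io as io_mod
from . import latent as latent_mod
from . import mfpca as mfpca_mod
from . import preprocess as pre_mod
from . import r2 as r2_mod
from . import simulate as sim_mod
from .containers import MultilevelFunctionalData
from .grid import FunctionalGrid

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "mfpca", "fosr", "r2", "latent")


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    out_dir: str = "cgmfda_run"
    stages: tuple[str, ...] = ("simulate", "mfpca", "fosr", "r2", "latent")
    seed: int = 0
    # synthetic-data stage
    n_subjects: int = 377
    meals_min: int = 3
    meals_max: int = 6
    noise_sd: float = 3.0
    # preprocess stage (used when raw input paths are given)
    cgm_path: str | None = None
    meals_path: str | None = None
    wear_start_path: str | None = None
    meal_label: str = "dinner"
    max_gap_minutes: float = 120.0
    discard_first_hours: float = 24.0
    min_observed_fraction: float = 0.5
    # model hyperparameters
    K: int = 3
    H: int = 3
    day_effects: bool = False
    smooth: bool = False
    band_mode: str = "pointwise"
    boot_reps: int = 200
    min_obs_points: int = 5
    n_scores: int = 2

    def __post_init__(self) -> None:
        for name in ("max_gap_minutes", "discard_first_hours",
                     "min_observed_fraction", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def meta(self) -> dict:
        payload = asdict(self)
        payload.pop("out_dir")  # the hash reflects the computation, not where
        return {"config_hash": io_mod.config_hash(payload), "seed": self.seed,
                "pipeline_version": io_mod.FORMAT_VERSION}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages in canonical order.

    Returns the artifact directory.  Any stage error raises
    :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runners = {
        "simulate": stage_simulate,
        "preprocess": stage_preprocess,
        "mfpca": stage_mfpca,
        "fosr": stage_fosr,
        "r2": stage_r2,
        "latent": stage_latent,
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            runners[stage](config)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        logger.info("stage %s finished in %.2f s (seed=%d)",
                    stage, time.perf_counter() - t0, config.seed)
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _dataset_dir(config: PipelineConfig) -> Path:
    return Path(config.out_dir) / "dataset"


def stage_simulate(config: PipelineConfig) -> None:
    sim_config = sim_mod.default_fosr_config(
        n_subjects=config.n_subjects,
        meals_per_subject=(config.meals_min, config.meals_max),
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    dataset = sim_mod.simulate_fosr_dataset(sim_config)
    io_mod.write_dataset(dataset, _dataset_dir(config), config.meta())


def stage_preprocess(config: PipelineConfig) -> None:
    if config.cgm_path is None or config.meals_path is None:
        raise ValueError("preprocess stage needs cgm_path and meals_path")
    streams = io_mod.read_cgm_long(config.cgm_path)
    meals = io_mod.read_meals(config.meals_path)
    wear = {}
    if config.wear_start_path is not None:
        wtab = io_mod.read_table(config.wear_start_path)
        wear = {
            str(r.subject_id): pd.Timestamp(r.wear_start)
            for r in wtab.itertuples(index=False)
        }
    grid = make_grid()
    parts = []
    for stream in streams:
        own = [m for m in meals if m.subject_id == stream.subject_id]
        win = pre_mod.extract_postprandial_windows(
            stream, own, grid, label_filter=config.meal_label
        )
        if win.n_rows:
            parts.append(win)
    windows = pre_mod.concat_windows(parts)
    filtered, log = pre_mod.apply_quality_filters(
        windows,
        wear_start=wear or None,
        max_gap_minutes=config.max_gap_minutes,
        discard_first_hours=config.discard_first_hours if wear else 0.0,
    )
    data = filtered.data.require_min_observed(config.min_observed_fraction)
    out = _dataset_dir(config)
    io_mod.write_curves_long(data, out / "curves.csv", config.meta())
    io_mod.write_exclusion_log(log, out / "exclusions.csv")


def make_grid() -> FunctionalGrid:
    from .grid import make_default_grid

    return make_default_grid()


def _load_curves(config: PipelineConfig) -> MultilevelFunctionalData:
    return io_mod.read_curves_long(_dataset_dir(config) / "curves.csv")


def _load_design(config: PipelineConfig, data: MultilevelFunctionalData):
    cov = io_mod.read_table(_dataset_dir(config) / "covariates.csv")
    cov["subject_id"] = cov["subject_id"].astype(str)
    key = pd.DataFrame(
        {"subject_id": data.subject_ids.astype(str), "meal_index": data.meal_index}
    )
    cov = key.merge(cov, on=["subject_id", "meal_index"], how="left", validate="1:1")
    design = fosr_mod.make_design(cov)
    return cov, design


def stage_mfpca(config: PipelineConfig) -> None:
    data = _load_curves(config)
    fit = mfpca_mod.fit_mfpca(
        data, K=config.K, H=config.H, day_effects=config.day_effects,
        min_obs=config.min_obs_points,
    )
    out = Path(config.out_dir) / "mfpca"
    meta = config.meta()
    t = fit.grid.times
    io_mod.write_table(pd.DataFrame({"time_min": t, "mu": fit.mu}),
                       out / "mean.csv", meta)
    io_mod.write_table(
        fit.nu.T.rename_axis("time_min").reset_index().rename(
            columns=lambda c: f"nu_{c}" if c != "time_min" else c
        ),
        out / "day_effects.csv", meta,
    )
    for name, lvl in (("level1", fit.level1), ("level2", fit.level2)):
        fns = pd.DataFrame(
            lvl.eigenfunctions.T, columns=[f"ef{i + 1}" for i in
                                           range(lvl.n_components)]
        )
        fns.insert(0, "time_min", t)
        io_mod.write_table(fns, out / f"eigenfunctions_{name}.csv", meta)
    io_mod.write_table(
        pd.DataFrame(
            {
                "level": ["subject"] * fit.level1.n_components
                + ["meal"] * fit.level2.n_components,
                "component": list(range(1, fit.level1.n_components + 1))
                + list(range(1, fit.level2.n_components + 1)),
                "eigenvalue": np.concatenate(
                    [fit.level1.eigenvalues, fit.level2.eigenvalues]
                ),
            }
        ),
        out / "eigenvalues.csv", meta,
    )
    io_mod.write_table(
        fit.level1.scores.rename_axis("subject_id").reset_index(),
        out / "scores_level1.csv", meta,
    )
    io_mod.write_table(fit.level2.scores, out / "scores_level2.csv", meta)
    with open(out / "metadata.yaml", "w") as fh:
        yaml.safe_dump(
            {
                **{k: str(v) for k, v in meta.items()},
                "K": fit.level1.n_components,
                "H": fit.level2.n_components,
                "noise_variance": float(fit.noise_variance),
                "variance_partition_subject": float(fit.variance_partition[0]),
                "variance_partition_meal": float(fit.variance_partition[1]),
            },
            fh, sort_keys=True,
        )


def _refit_mfpca(config: PipelineConfig, data: MultilevelFunctionalData):
    return mfpca_mod.fit_mfpca(
        data, K=config.K, H=config.H, day_effects=config.day_effects,
        min_obs=config.min_obs_points,
    )


def stage_fosr(config: PipelineConfig) -> None:
    data = _load_curves(config)
    cov, design = _load_design(config, data)
    fit = fosr_mod.fit_fosr(data, design, smooth=config.smooth)
    bands = fit.bands
    if config.band_mode == "bootstrap":
        bands = fosr_mod.confidence_bands(
            fit, mode="bootstrap", data=data, design=design,
            n_boot=config.boot_reps, seed=config.seed,
        )
    out = Path(config.out_dir) / "fosr"
    meta = config.meta()
    rows = []
    est = fit.coefficients
    se = fit.coefficient_se
    for name in fit.columns:
        rows.append(
            pd.DataFrame(
                {
                    "covariate": name,
                    "time_min": fit.grid.times,
                    "estimate": est[name].to_numpy(),
                    "se": se[name].to_numpy(),
                    "lower": bands[(name, "lower")].to_numpy(),
                    "upper": bands[(name, "upper")].to_numpy(),
                }
            )
        )
    io_mod.write_table(pd.concat(rows, ignore_index=True),
                       out / "coefficients.csv", meta)
    alpha = fit.alpha.rename_axis("subject_id")
    alpha.columns = [f"t{t:g}" for t in fit.grid.times]
    io_mod.write_table(alpha.reset_index(), out / "alpha.csv", meta)
    io_mod.write_table(
        pd.DataFrame(
            {
                "time_min": fit.grid.times,
                "var_subject": fit.var_subject,
                "var_resid": fit.var_resid,
                "ols_fallback": fit.ols_fallback.astype(int),
            }
        ),
        out / "variance_components.csv", meta,
    )


def _load_fosr_outputs(config: PipelineConfig, data: MultilevelFunctionalData):
    out = Path(config.out_dir) / "fosr"
    coef = io_mod.read_table(out / "coefficients.csv")
    beta = coef.pivot(index="time_min", columns="covariate", values="estimate")
    alpha = io_mod.read_table(out / "alpha.csv").set_index("subject_id")
    alpha.index = alpha.index.astype(str)
    alpha.columns = [float(c[1:]) for c in alpha.columns]
    return beta, alpha


def stage_r2(config: PipelineConfig) -> None:
    data = _load_curves(config)
    out = Path(config.out_dir) / "r2"
    meta = config.meta()
    # MFPCA variants (refit: the fit object is cheap relative to serializing it)
    mfit = _refit_mfpca(config, data)
    (p_curve, p_glob), (f_curve, f_glob) = r2_mod.mfpca_r2(mfit, data)
    io_mod.write_table(
        pd.DataFrame(
            {
                "time_min": data.grid.times,
                "participant": p_curve.values,
                "full": f_curve.values,
            }
        ),
        out / "r2_mfpca.csv", meta,
    )
    beta, alpha = _load_fosr_outputs(config, data)
    cov, design = _load_design(config, data)
    beta = beta[design.columns]
    fixed = design.to_numpy(dtype=float) @ beta.to_numpy().T
    cond = fixed + alpha.reindex(data.subject_ids.astype(str)).to_numpy()
    m_curve = r2_mod.pointwise_r2(data, fixed, variant="fosr_marginal")
    c_curve = r2_mod.pointwise_r2(data, cond, variant="fosr_conditional")
    io_mod.write_table(
        pd.DataFrame(
            {
                "time_min": data.grid.times,
                "marginal": m_curve.values,
                "conditional": c_curve.values,
            }
        ),
        out / "r2_fosr.csv", meta,
    )
    io_mod.write_table(
        pd.DataFrame(
            {
                "variant": [
                    "mfpca_participant", "mfpca_full",
                    "fosr_marginal", "fosr_conditional",
                ],
                "global_r2": [
                    r2_mod.global_r2(c).value
                    for c in (p_curve, f_curve, m_curve, c_curve)
                ],
            }
        ),
        out / "r2_global.csv", meta,
    )


def stage_latent(config: PipelineConfig) -> None:
    data = _load_curves(config)
    beta, _ = _load_fosr_outputs(config, data)
    cov, design = _load_design(config, data)
    beta = beta[design.columns]
    resid_curves = data.curves - design.to_numpy(dtype=float) @ beta.to_numpy().T
    residuals = MultilevelFunctionalData(
        grid=data.grid, curves=resid_curves,
        subject_ids=data.subject_ids, meal_index=data.meal_index,
    )
    _, scores = latent_mod.residual_mfpca(
        residuals, K=config.K, H=config.H, min_obs=config.min_obs_points
    )
    outcomes = io_mod.read_table(_dataset_dir(config) / "outcomes.csv")
    outcomes = outcomes.assign(subject_id=outcomes["subject_id"].astype(str))
    z = outcomes.set_index("subject_id")["outcome"]
    subject_cov = (
        cov.groupby("subject_id", sort=False)
        .first()
        .drop(columns=["meal_index"], errors="ignore")
    )
    sub_level = [
        c for c in ("age", "weight", "gender_female", "hba1c")
        if c in subject_cov.columns
    ]
    result = latent_mod.outcome_regression(
        z, scores, subject_cov[sub_level], n_scores=config.n_scores
    )
    out = Path(config.out_dir) / "latent"
    meta = config.meta()
    io_mod.write_table(
        scores.scores.rename_axis("subject_id").reset_index(),
        out / "latent_scores.csv", meta,
    )
    coef = pd.concat([result.coef_scores, result.coef_covariates])
    io_mod.write_table(
        coef.rename_axis("term").rename("estimate").reset_index(),
        out / "outcome_coefficients.csv", meta,
    )
    io_mod.write_table(
        pd.DataFrame(
            {
                "r2_with_scores": [result.r2_with],
                "r2_without_scores": [result.r2_without],
                "delta_r2": [result.delta_r2],
                "n_subjects": [result.n],
                "n_scores": [config.n_scores],
            }
        ),
        out / "outcome_r2.csv", meta,
    )
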