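"""Synthetic multilevel postprandial-CGM data with known ground truth.

Generates datasets that follow the hierarchical Karhunen-Loeve structure the
downstream estimators assume:

    Y_ij(t) = mu(t) + nu_j(t) + sum_k a_ik phi_k(t) + sum_h b_ijh psi_h(t) + e_ijt

with subject-level scores a_ik ~ N(0, lambda_k), meal-level scores
b_ijh ~ N(0, eta_h) and i.i.d. measurement noise, and regression datasets

    Y_ij(t) = sum_l X_ijl beta_l(t) + alpha_i(t) + eps_ij(t)

where alpha_i is built from the subject-level eigenstructure and eps_ij from
the meal-level eigenstructure plus white noise.  Every draw is reproducible
from the config seed, and the realized scores are returned so recovery can be
tested against the truth.

Default settings emulate the structure of a free-living CGM + meal-diary
cohort of adults without diabetes: a 5-minute grid over the 6-hour window
after dinner, 3-6 recorded dinners per subject, a 33:67 subject:meal split of
the random-curve variance, and covariate marginals (age, weight, gender,
HbA1c, meal macronutrients, pre-meal glucose) matching published summary
tables for such a cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import MultilevelFunctionalData
from .grid import FunctionalGrid, make_default_grid

__all__ = [
    "TruncNormalSpec",
    "BernoulliSpec",
    "OutcomeSpec",
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedDataset",
    "default_covariate_spec",
    "default_mean_function",
    "default_eigenfunctions",
    "default_coefficient_functions",
    "default_outcome_spec",
    "default_mfpca_config",
    "default_fosr_config",
    "simulate_mfpca_dataset",
    "simulate_fosr_dataset",
    "simulate_outcome",
    "orthonormalize",
]

ORTHO_TOL = 1e-8


# ---------------------------------------------------------------------------
# covariate marginals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruncNormalSpec:
    """Truncated-normal marginal, parameterised by its *truncated* moments.

    ``mean`` and ``sd`` are the published summary mean/SD of the observed
    variable; the underlying normal parameters are solved by moment matching
    so that draws reproduce those summaries despite the truncation at
    [lower, upper].
    """

    mean: float
    sd: float
    lower: float
    upper: float
    level: str = "meal"  # "subject" or "meal"

    def frozen(self) -> stats.rv_continuous:
        mu, sigma = _truncnorm_underlying(self.mean, self.sd, self.lower, self.upper)
        a, b = (self.lower - mu) / sigma, (self.upper - mu) / sigma
        return stats.truncnorm(a, b, loc=mu, scale=sigma)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.frozen().rvs(size=size, random_state=rng)


@dataclass(frozen=True)
class BernoulliSpec:
    """0/1 marginal (e.g. a female-gender indicator)."""

    p: float
    level: str = "subject"

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return (rng.random(size) < self.p).astype(float)


def _truncnorm_underlying(mean: float, sd: float, lower: float, upper: float):
    """Solve for (mu, sigma) of the parent normal whose [lower, upper]
    truncation has the requested mean and SD."""

    def moments(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    sol = optimize.root(moments, x0=[mean, math.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - all shipped marginals converge
        raise ValueError(
            f"could not match truncated-normal moments for mean={mean}, sd={sd}"
        )
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def default_covariate_spec() -> dict[str, TruncNormalSpec | BernoulliSpec]:
    """Marginals matching the normoglycemic cohort summaries.

    Subject level: age (yr), weight (kg), female-gender indicator, HbA1c (%).
    Meal level: carbohydrates, fats, proteins, fiber (g) and the CGM glucose
    reading 5 minutes before the meal (mg/dL).  Draws are independent across
    covariates (a simplification; see the methods note).
    """
    return {
        "age": TruncNormalSpec(44.6, 13.7, 18.0, 81.0, level="subject"),
        "weight": TruncNormalSpec(73.7, 14.3, 41.0, 130.0, level="subject"),
        "gender_female": BernoulliSpec(0.621, level="subject"),
        "hba1c": TruncNormalSpec(5.25, 0.25, 3.10, 5.60, level="subject"),
        "carbohydrates": TruncNormalSpec(59.9, 40.5, 0.0, 513.0, level="meal"),
        "fats": TruncNormalSpec(30.1, 23.8, 0.0, 237.0, level="meal"),
        "proteins": TruncNormalSpec(27.5, 17.9, 0.0, 200.0, level="meal"),
        "fiber": TruncNormalSpec(8.8, 6.7, 0.0, 89.3, level="meal"),
        "glucose_initial": TruncNormalSpec(103.0, 15.3, 52.0, 237.0, level="meal"),
    }


# ---------------------------------------------------------------------------
# generating functions
# ---------------------------------------------------------------------------

def default_mean_function(grid: FunctionalGrid) -> np.ndarray:
    """Population postprandial mean: rise from ~100 mg/dL to a ~140 mg/dL
    peak near 55 min, then decay back toward baseline by 6 h."""
    t = grid.times
    return 100.0 + 40.0 * (t / 55.0) * np.exp(1.0 - t / 55.0)


def orthonormalize(raw: np.ndarray, grid: FunctionalGrid) -> np.ndarray:
    """Gram-Schmidt under the grid's L2 inner product (rows = functions)."""
    out = []
    for f in np.atleast_2d(np.asarray(raw, dtype=float)):
        g = f.copy()
        for q in out:
            g -= grid.inner(g, q) * q
        nrm = grid.norm(g)
        if nrm < 1e-12:
            raise ValueError("raw functions are linearly dependent")
        out.append(g / nrm)
    return np.vstack(out)


def default_eigenfunctions(
    grid: FunctionalGrid, n: int = 3, level: str = "subject"
) -> np.ndarray:
    """Orthonormal Fourier-type modes mimicking postprandial variation.

    Subject level: mode 1 is near-constant with mild curvature around 100
    min (overall level); mode 2 carries a pronounced peak around 60-80 min
    on top of a full-window cosine (peak height); mode 3 contrasts a late
    (~100 min) against an early (~45 min) peak on a full-window sine (peak
    timing).  The sinusoidal carriers spread each mode's support over the
    whole window, as empirical CGM eigenfunctions do.

    Meal level: peak-height, peak-timing and late-window shapes, with the
    subject-level span projected out before orthonormalization so the two
    hierarchical levels of the generator are exactly identifiable (the
    estimators never assume this cross-level orthogonality).
    """
    t = grid.times
    period = grid.span
    raw = np.vstack(
        [
            1.0 + 0.3 * np.exp(-(((t - 100.0) / 120.0) ** 2)),
            np.cos(2 * np.pi * t / period)
            + 0.6 * np.exp(-(((t - 70.0) / 60.0) ** 2)),
            np.sin(2 * np.pi * t / period)
            + 0.6
            * (
                np.exp(-(((t - 100.0) / 40.0) ** 2))
                - np.exp(-(((t - 45.0) / 40.0) ** 2))
            ),
        ]
    )
    if n > raw.shape[0]:
        raise ValueError(f"at most {raw.shape[0]} default eigenfunctions available")
    if level == "subject":
        return orthonormalize(raw[:n], grid)
    if level != "meal":
        raise ValueError(f"unknown eigenfunction level {level!r}")
    phi = orthonormalize(raw, grid)
    raw_meal = np.vstack(
        [
            np.exp(-(((t - 70.0) / 55.0) ** 2)),
            np.exp(-(((t - 105.0) / 40.0) ** 2))
            - np.exp(-(((t - 45.0) / 40.0) ** 2)),
            np.sin(2 * np.pi * t / period)
            + 0.5 * np.exp(-(((t - 160.0) / 60.0) ** 2)),
        ]
    )
    if n > raw_meal.shape[0]:
        raise ValueError(f"at most {raw_meal.shape[0]} default meal modes available")
    w = grid.quad_weights
    proj = raw_meal - ((raw_meal * w) @ phi.T) @ phi
    return orthonormalize(proj[:n], grid)


def _bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((t - center) / width) ** 2))


def _sigmoid(t: np.ndarray, center: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - center) / scale))


def default_coefficient_functions(
    grid: FunctionalGrid,
    covariate_spec: Mapping[str, TruncNormalSpec | BernoulliSpec] | None = None,
) -> dict[str, np.ndarray]:
    """Time-varying effects (mg/dL per covariate unit) with the qualitative
    shapes reported for free-living dinners: carbohydrates raise the response
    with a peak near 60 min, fats depress it during the first ~50 min then
    mildly raise it, fiber blunts the response after ~90 min, proteins are
    null, pre-meal glucose is strongly predictive early and decays, age peaks
    near 90 min, HbA1c shifts the whole curve.

    The intercept is chosen so that the expected response under the covariate
    marginals equals :func:`default_mean_function`.
    """
    if covariate_spec is None:
        covariate_spec = default_covariate_spec()
    t = grid.times
    beta: dict[str, np.ndarray] = {
        "age": 0.15 * _bump(t, 90.0, 120.0),
        "weight": 0.05 * np.ones_like(t),
        "gender_female": np.zeros_like(t),
        "hba1c": 8.0 * np.ones_like(t),
        "carbohydrates": 0.15 * _bump(t, 60.0, 80.0) + 0.02,
        "fats": -0.10 * (1.0 - _sigmoid(t, 50.0, 15.0)) + 0.03 * _sigmoid(t, 50.0, 15.0),
        "proteins": np.zeros_like(t),
        "fiber": -0.30 * _sigmoid(t, 90.0, 25.0),
        "glucose_initial": 0.9 - 0.6 * _sigmoid(t, 60.0, 40.0),
    }
    beta = {name: beta[name] for name in covariate_spec}
    means = {
        name: (spec.p if isinstance(spec, BernoulliSpec) else spec.mean)
        for name, spec in covariate_spec.items()
    }
    intercept = default_mean_function(grid).astype(float)
    for name, b in beta.items():
        intercept = intercept - means[name] * b
    return {"intercept": intercept, **beta}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeSpec:
    """Scalar subject-level outcome Z_i generated from level-1 scores.

    Z_i = intercept + sum_k gamma_k a_ik + sum_j beta_j X_ij + noise, with
    ``betas`` keyed by subject-level covariate names.
    """

    gammas: tuple[float, ...]
    betas: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("outcome noise_sd must be nonnegative")


@dataclass(frozen=True)
class SimulationConfig:
    """Full generating model for a synthetic multilevel CGM dataset."""

    n_subjects: int
    meals_per_subject: int | tuple[int, int] | Sequence[int]
    grid: FunctionalGrid
    mean_function: np.ndarray
    level1_eigenfunctions: np.ndarray  # (K, m)
    level1_eigenvalues: np.ndarray  # (K,)
    level2_eigenfunctions: np.ndarray  # (H, m)
    level2_eigenvalues: np.ndarray  # (H,)
    noise_sd: float = 3.0
    day_effects: np.ndarray | None = None  # (J_max, m), None = no day shift
    covariate_spec: Mapping[str, TruncNormalSpec | BernoulliSpec] | None = None
    coefficient_functions: Mapping[str, np.ndarray] | None = None
    outcome_spec: OutcomeSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        m = len(self.grid)
        for name in ("mean_function",):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (m,):
                raise ValueError(f"{name} must have length {m} to match the grid")
            object.__setattr__(self, name, arr)
        for fn_name, ev_name in (
            ("level1_eigenfunctions", "level1_eigenvalues"),
            ("level2_eigenfunctions", "level2_eigenvalues"),
        ):
            fns = np.atleast_2d(np.asarray(getattr(self, fn_name), dtype=float))
            evs = np.atleast_1d(np.asarray(getattr(self, ev_name), dtype=float))
            if fns.shape[1] != m:
                raise ValueError(f"{fn_name} must have {m} columns to match the grid")
            if evs.shape[0] != fns.shape[0]:
                raise ValueError(f"{ev_name} must have one entry per eigenfunction")
            if np.any(evs < 0):
                raise ValueError(f"{ev_name} must be nonnegative")
            if np.any(np.diff(evs) > 0):
                raise ValueError(f"{ev_name} must be sorted nonincreasing")
            gram = np.array(
                [[self.grid.inner(f, g) for g in fns] for f in fns]
            )
            if not np.allclose(gram, np.eye(fns.shape[0]), atol=ORTHO_TOL):
                raise ValueError(f"{fn_name} are not orthonormal under the grid "
                                 f"inner product (tol {ORTHO_TOL})")
            object.__setattr__(self, fn_name, fns)
            object.__setattr__(self, ev_name, evs)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.day_effects is not None:
            de = np.atleast_2d(np.asarray(self.day_effects, dtype=float))
            if de.shape[1] != m:
                raise ValueError("day_effects rows must match the grid length")
            object.__setattr__(self, "day_effects", de)
        if self.coefficient_functions is not None:
            cf = {
                name: np.asarray(vals, dtype=float)
                for name, vals in self.coefficient_functions.items()
            }
            for name, vals in cf.items():
                if vals.shape != (m,):
                    raise ValueError(
                        f"coefficient function {name!r} must have length {m}"
                    )
            object.__setattr__(self, "coefficient_functions", cf)

    @property
    def K(self) -> int:
        return self.level1_eigenfunctions.shape[0]

    @property
    def H(self) -> int:
        return self.level2_eigenfunctions.shape[0]

    def resolve_meal_counts(self, rng: np.random.Generator) -> np.ndarray:
        """Per-subject meal counts J_i (fixed, uniform-range, or explicit)."""
        mps = self.meals_per_subject
        if isinstance(mps, (int, np.integer)):
            return np.full(self.n_subjects, int(mps))
        if isinstance(mps, tuple) and len(mps) == 2:
            lo, hi = mps
            return rng.integers(lo, hi + 1, size=self.n_subjects)
        counts = np.asarray(mps, dtype=int)
        if counts.shape != (self.n_subjects,):
            raise ValueError("explicit meal counts must have one entry per subject")
        return counts


# Eigenvalues live on the integrated scale, (mg/dL)^2 * min, because the
# eigenfunctions are unit-norm in L2([0, 360]): sum(eigenvalues)/360 is the
# time-averaged pointwise curve variance.  252000 corresponds to ~700
# (mg/dL)^2 pointwise, i.e. a random-curve SD of ~26 mg/dL.
DEFAULT_TOTAL_VARIANCE = 252_000.0
DEFAULT_SUBJECT_SHARE = 0.33  # subject-level share of that mass
DEFAULT_MODE_SHARES = (0.42, 0.32, 0.26)  # within-level split over 3 modes


def _default_eigen(grid, total, share, mode_shares):
    lvl1 = total * share * np.asarray(mode_shares)
    lvl2 = total * (1.0 - share) * np.asarray(mode_shares)
    phi = default_eigenfunctions(grid, len(mode_shares), level="subject")
    psi = default_eigenfunctions(grid, len(mode_shares), level="meal")
    return phi, lvl1, psi, lvl2


def default_mfpca_config(
    n_subjects: int = 377,
    meals_per_subject: int | tuple[int, int] | Sequence[int] = (3, 6),
    grid: FunctionalGrid | None = None,
    total_variance: float = DEFAULT_TOTAL_VARIANCE,
    subject_share: float = DEFAULT_SUBJECT_SHARE,
    mode_shares: Sequence[float] = DEFAULT_MODE_SHARES,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> SimulationConfig:
    """Study-like hierarchical dataset: dinners from a no-diabetes cohort,
    33% of random-curve variance at the subject level, 3 active modes per
    level."""
    grid = grid or make_default_grid()
    phi, lam, psi, eta = _default_eigen(grid, total_variance, subject_share, mode_shares)
    return SimulationConfig(
        n_subjects=n_subjects,
        meals_per_subject=meals_per_subject,
        grid=grid,
        mean_function=default_mean_function(grid),
        level1_eigenfunctions=phi,
        level1_eigenvalues=lam,
        level2_eigenfunctions=psi,
        level2_eigenvalues=eta,
        noise_sd=noise_sd,
        seed=seed,
    )


def default_outcome_spec(
    config: SimulationConfig,
    gammas: tuple[float, ...] = (0.05, 0.04),
    partial_r2: float = 0.3,
) -> OutcomeSpec:
    """Outcome driven by the first ``len(gammas)`` subject-level scores with
    noise chosen so the scores explain ``partial_r2`` of Var(Z)."""
    lam = config.level1_eigenvalues[: len(gammas)]
    signal = float(np.sum(np.asarray(gammas) ** 2 * lam))
    if not 0 < partial_r2 < 1:
        raise ValueError("partial_r2 must be in (0, 1)")
    noise_sd = math.sqrt(signal * (1.0 - partial_r2) / partial_r2)
    return OutcomeSpec(gammas=gammas, noise_sd=noise_sd)


def default_fosr_config(
    n_subjects: int = 377,
    meals_per_subject: int | tuple[int, int] | Sequence[int] = (3, 6),
    grid: FunctionalGrid | None = None,
    total_variance: float = DEFAULT_TOTAL_VARIANCE,
    subject_share: float = DEFAULT_SUBJECT_SHARE,
    mode_shares: Sequence[float] = DEFAULT_MODE_SHARES,
    noise_sd: float = 3.0,
    with_outcome: bool = True,
    seed: int = 0,
) -> SimulationConfig:
    """Regression dataset: covariates with study-like marginals, time-varying
    effects, subject random functions from the level-1 eigenstructure."""
    grid = grid or make_default_grid()
    phi, lam, psi, eta = _default_eigen(grid, total_variance, subject_share, mode_shares)
    cov_spec = default_covariate_spec()
    config = SimulationConfig(
        n_subjects=n_subjects,
        meals_per_subject=meals_per_subject,
        grid=grid,
        mean_function=default_mean_function(grid),
        level1_eigenfunctions=phi,
        level1_eigenvalues=lam,
        level2_eigenfunctions=psi,
        level2_eigenvalues=eta,
        noise_sd=noise_sd,
        covariate_spec=cov_spec,
        coefficient_functions=default_coefficient_functions(grid, cov_spec),
        seed=seed,
    )
    if with_outcome:
        config = replace(config, outcome_spec=default_outcome_spec(config))
    return config


# ---------------------------------------------------------------------------
# realized datasets
# ---------------------------------------------------------------------------

@dataclass
class SimulationTruth:
    """Generating model plus the realized random draws."""

    config: SimulationConfig
    scores_level1: pd.DataFrame  # subjects x K, index = subject_id
    scores_level2: pd.DataFrame  # rows x H, with subject_id/meal_index columns
    alpha: pd.DataFrame | None = None  # subjects x grid, FoSR random functions

    @property
    def subject_ids(self) -> np.ndarray:
        return self.scores_level1.index.to_numpy()


@dataclass
class SimulatedDataset:
    """Curves, covariates, outcomes and the truth they were drawn from."""

    data: MultilevelFunctionalData
    truth: SimulationTruth
    covariates: pd.DataFrame | None = None  # aligned 1:1 with curve rows
    outcomes: pd.Series | None = None  # indexed by subject_id

    def __post_init__(self) -> None:
        if self.covariates is not None:
            if len(self.covariates) != self.data.n_rows:
                raise ValueError("covariates must align 1:1 with curve rows")
            sub_cols = [
                name
                for name, spec in (self.truth.config.covariate_spec or {}).items()
                if spec.level == "subject"
            ]
            for col in sub_cols:
                per_subject = self.covariates.groupby(
                    self.data.subject_ids
                )[col].nunique()
                if (per_subject > 1).any():
                    raise ValueError(
                        f"subject-level covariate {col!r} varies within a subject"
                    )


def _subject_ids(n: int) -> np.ndarray:
    width = len(str(n))
    return np.array([f"S{i + 1:0{width}d}" for i in range(n)])


def _draw_structure(config: SimulationConfig, rng: np.random.Generator):
    """Shared scaffolding: row layout, scores, random-function values."""
    counts = config.resolve_meal_counts(rng)
    ids = _subject_ids(config.n_subjects)
    subject_rows = np.repeat(ids, counts)
    meal_index = np.concatenate([np.arange(1, c + 1) for c in counts])
    n_rows = int(counts.sum())

    a = rng.normal(size=(config.n_subjects, config.K)) * np.sqrt(
        config.level1_eigenvalues
    )
    b = rng.normal(size=(n_rows, config.H)) * np.sqrt(config.level2_eigenvalues)

    alpha = a @ config.level1_eigenfunctions  # subjects x m
    within = b @ config.level2_eigenfunctions  # rows x m
    row_alpha = np.repeat(alpha, counts, axis=0)

    truth = SimulationTruth(
        config=config,
        scores_level1=pd.DataFrame(
            a, index=pd.Index(ids, name="subject_id"),
            columns=[f"a{k + 1}" for k in range(config.K)],
        ),
        scores_level2=pd.DataFrame(
            b, columns=[f"b{h + 1}" for h in range(config.H)]
        ).assign(subject_id=subject_rows, meal_index=meal_index),
        alpha=pd.DataFrame(alpha, index=pd.Index(ids, name="subject_id"),
                           columns=config.grid.times),
    )
    return counts, subject_rows, meal_index, row_alpha, within, truth


def _day_effect_rows(config: SimulationConfig, meal_index: np.ndarray) -> np.ndarray:
    if config.day_effects is None:
        return np.zeros((meal_index.size, len(config.grid)))
    de = config.day_effects
    idx = np.minimum(meal_index - 1, de.shape[0] - 1)
    return de[idx]


def simulate_mfpca_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw curves from the hierarchical eigen-decomposition model."""
    rng = np.random.default_rng(config.seed)
    counts, subject_rows, meal_index, row_alpha, within, truth = _draw_structure(
        config, rng
    )
    curves = (
        config.mean_function
        + _day_effect_rows(config, meal_index)
        + row_alpha
        + within
    )
    if config.noise_sd > 0:
        curves = curves + rng.normal(scale=config.noise_sd, size=curves.shape)
    data = MultilevelFunctionalData(
        grid=config.grid,
        curves=curves,
        subject_ids=subject_rows,
        meal_index=meal_index,
    )
    outcomes = None
    if config.outcome_spec is not None:
        outcomes = simulate_outcome(truth, config.outcome_spec)
    return SimulatedDataset(data=data, truth=truth, outcomes=outcomes)


def _draw_covariates(
    config: SimulationConfig,
    rng: np.random.Generator,
    counts: np.ndarray,
    subject_rows: np.ndarray,
    meal_index: np.ndarray,
) -> pd.DataFrame:
    n_rows = subject_rows.size
    cols: dict[str, np.ndarray] = {}
    for name, spec in config.covariate_spec.items():
        if spec.level == "subject":
            vals = np.repeat(spec.draw(rng, config.n_subjects), counts)
        elif spec.level == "meal":
            vals = spec.draw(rng, n_rows)
        else:
            raise ValueError(f"covariate {name!r} has unknown level {spec.level!r}")
        if isinstance(spec, TruncNormalSpec) and (
            np.any(vals < spec.lower) or np.any(vals > spec.upper)
        ):
            raise ValueError(f"covariate {name!r} drawn outside declared support")
        cols[name] = vals
    frame = pd.DataFrame(cols)
    frame.insert(0, "meal_index", meal_index)
    frame.insert(0, "subject_id", subject_rows)
    return frame


def simulate_fosr_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw curves from the function-on-scalar regression model."""
    if config.coefficient_functions is None:
        raise ValueError("config.coefficient_functions is required for FoSR data")
    if config.covariate_spec is None:
        raise ValueError("config.covariate_spec is required for FoSR data")
    rng = np.random.default_rng(config.seed)
    counts, subject_rows, meal_index, row_alpha, within, truth = _draw_structure(
        config, rng
    )
    covariates = _draw_covariates(config, rng, counts, subject_rows, meal_index)

    beta = config.coefficient_functions
    names = [n for n in beta if n != "intercept"]
    X = np.column_stack(
        [np.ones(subject_rows.size)]
        + [covariates[n].to_numpy(dtype=float) for n in names]
    )
    B = np.vstack([beta["intercept"]] + [beta[n] for n in names])
    fixed = X @ B

    curves = fixed + row_alpha + within
    if config.noise_sd > 0:
        curves = curves + rng.normal(scale=config.noise_sd, size=curves.shape)
    data = MultilevelFunctionalData(
        grid=config.grid,
        curves=curves,
        subject_ids=subject_rows,
        meal_index=meal_index,
    )
    outcomes = None
    if config.outcome_spec is not None:
        subject_cov = (
            covariates.groupby("subject_id", sort=False).first().drop(
                columns=["meal_index"]
            )
        )
        outcomes = simulate_outcome(truth, config.outcome_spec, subject_cov)
    return SimulatedDataset(
        data=data, truth=truth, covariates=covariates, outcomes=outcomes
    )


def simulate_outcome(
    truth: SimulationTruth,
    outcome_spec: OutcomeSpec,
    covariates: pd.DataFrame | None = None,
    seed: int | None = None,
) -> pd.Series:
    """Scalar outcomes Z_i from level-1 scores and subject covariates.

    Reproducible: the seed defaults to the config seed offset by a constant
    so outcome noise is independent of the curve draws yet deterministic.
    """
    a = truth.scores_level1.to_numpy()
    gammas = np.asarray(outcome_spec.gammas, dtype=float)
    if gammas.size > a.shape[1]:
        raise ValueError(
            f"outcome_spec has {gammas.size} gammas but only {a.shape[1]} "
            "level-1 scores are available"
        )
    z = outcome_spec.intercept + a[:, : gammas.size] @ gammas
    if outcome_spec.betas:
        if covariates is None:
            raise ValueError("outcome_spec.betas set but no covariate table given")
        for name, coef in outcome_spec.betas.items():
            if name not in covariates.columns:
                raise ValueError(f"outcome covariate {name!r} missing from table")
            z = z + coef * covariates.loc[truth.subject_ids, name].to_numpy(dtype=float)
    if seed is None:
        seed = (int(truth.config.seed) + 202206) % (2**31 - 1)
    rng = np.random.default_rng(seed)
    if outcome_spec.noise_sd > 0:
        z = z + rng.normal(scale=outcome_spec.noise_sd, size=z.size)
    return pd.Series(z, index=truth.scores_level1.index, name="outcome")
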