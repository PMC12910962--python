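"""Function-on-scalar regression by pointwise mixed models.

Fits Y_ij(t) = sum_l X_ijl beta_l(t) + alpha_i(t) + eps_ij(t) with the
fast-univariate-inference strategy: at each grid point t a scalar linear
mixed model with the same fixed-effect design and a subject random intercept
is fit by REML, and the per-t estimates are assembled into coefficient
functions beta_l(t), subject random functions alpha_i(t) (from the per-t
intercept BLUPs) and functional residuals.  Optional penalized-spline
smoothing of the raw coefficient sequences and 95% confidence bands
(pointwise Wald or subject-level cluster bootstrap) complete the fit.

Predictors are used on their natural scale — no standardization — so the
coefficient functions read directly as mg/dL per covariate unit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._lmm import fit_random_intercept
from .containers import MultilevelFunctionalData
from .grid import FunctionalGrid
from .smoothing import PSplineSmoother

__all__ = [
    "make_design",
    "FoSRFit",
    "fit_pointwise",
    "fit_fosr",
    "smooth_coefficients",
    "confidence_bands",
    "predict",
    "extract_residuals",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def make_design(
    covariates: pd.DataFrame,
    columns: list[str] | None = None,
    intercept: bool = True,
) -> pd.DataFrame:
    """Fixed-effect design aligned 1:1 with curve rows.

    Drops bookkeeping columns (subject_id, meal_index) unless explicitly
    requested, prepends an intercept, and rejects missing entries and
    rank-deficient designs (naming the collinear columns).
    """
    if columns is None:
        columns = [
            c for c in covariates.columns if c not in ("subject_id", "meal_index")
        ]
    X = covariates[columns].astype(float).copy()
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"design has missing entries in columns: {bad}")
    if intercept:
        X.insert(0, "intercept", 1.0)
    _check_full_rank(X)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, _, piv = _qr_pivot(arr)
        collinear = [X.columns[i] for i in sorted(piv[rank:])]
        raise ValueError(f"design is rank deficient; collinear columns: {collinear}")


def _qr_pivot(arr: np.ndarray):
    from scipy.linalg import qr

    return qr(arr, mode="economic", pivoting=True)


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------

@dataclass
class FoSRFit:
    """Assembled pointwise-fit results.

    ``beta``/``beta_se`` are (time x coefficient) frames of the raw per-t
    REML estimates; ``beta_smooth`` is present when smoothing was requested
    and is then the surface used by downstream predictions.  ``bands`` holds
    95% lower/upper limits with a (coefficient, side) column MultiIndex.
    ``residuals`` are the conditional residuals, so
    Y = X beta + alpha + residuals holds exactly on observed entries.
    """

    grid: FunctionalGrid
    columns: list[str]
    beta: pd.DataFrame  # index grid times, columns coefficient names
    beta_se: pd.DataFrame
    bands: pd.DataFrame  # columns MultiIndex (name, {"lower","upper"})
    band_level: float
    alpha: pd.DataFrame  # subjects x grid times
    residuals: np.ndarray  # rows x m, conditional residuals
    var_subject: np.ndarray  # per-t random-intercept variance
    var_resid: np.ndarray  # per-t residual variance
    ols_fallback: np.ndarray  # per-t flag: no random-intercept variance
    subject_ids: np.ndarray
    meal_index: np.ndarray
    beta_smooth: pd.DataFrame | None = None
    beta_se_smooth: pd.DataFrame | None = None
    smoother_lams: dict[str, float] = field(default_factory=dict)

    @property
    def coefficients(self) -> pd.DataFrame:
        """Coefficient surface used for prediction (smoothed when available)."""
        return self.beta_smooth if self.beta_smooth is not None else self.beta

    @property
    def coefficient_se(self) -> pd.DataFrame:
        return (
            self.beta_se_smooth if self.beta_se_smooth is not None else self.beta_se
        )


@dataclass
class PointwiseFits:
    """Raw per-grid-point mixed-model output."""

    beta: np.ndarray  # (m, L)
    cov_beta: np.ndarray  # (m, L, L)
    alpha: np.ndarray  # (n_subjects, m) predicted intercepts
    var_subject: np.ndarray
    var_resid: np.ndarray
    ols_fallback: np.ndarray
    subjects: np.ndarray


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def fit_pointwise(
    data: MultilevelFunctionalData, design: pd.DataFrame
) -> PointwiseFits:
    """REML random-intercept fit at every grid point.

    Each per-t fit uses only the rows observed at that t.  When the REML
    random-intercept variance is estimated at zero the fit coincides with
    ordinary least squares; those points are flagged in ``ols_fallback``.
    """
    if len(design) != data.n_rows:
        raise ValueError("design rows must align with curve rows")
    _check_full_rank(design)
    X = design.to_numpy(dtype=float)
    Y = data.curves
    obs = data.observed
    subjects = data.subjects
    sub_pos = {s: i for i, s in enumerate(subjects)}
    m = len(data.grid)
    L = X.shape[1]
    beta = np.empty((m, L))
    cov = np.empty((m, L, L))
    alpha = np.zeros((subjects.size, m))
    var_b = np.empty(m)
    var_e = np.empty(m)
    flags = np.zeros(m, dtype=bool)
    for k in range(m):
        rows = np.flatnonzero(obs[:, k])
        if rows.size < L + 1:
            raise ValueError(
                f"only {rows.size} curves observed at t={data.grid.times[k]} min; "
                "cannot fit the pointwise model"
            )
        fit = fit_random_intercept(Y[rows, k], X[rows], data.subject_ids[rows])
        beta[k] = fit.beta
        cov[k] = fit.cov_beta
        var_b[k] = fit.sigma2_b
        var_e[k] = fit.sigma2_e
        flags[k] = fit.singular
        for code, blup in zip(fit.group_codes, fit.blups):
            alpha[sub_pos[code], k] = blup
    return PointwiseFits(
        beta=beta, cov_beta=cov, alpha=alpha, var_subject=var_b,
        var_resid=var_e, ols_fallback=flags, subjects=subjects,
    )


def smooth_coefficients(
    beta: pd.DataFrame, grid: FunctionalGrid, lam: float | None = None
) -> tuple[pd.DataFrame, dict[str, float], dict[str, np.ndarray]]:
    """Penalized-spline smoothing of each raw coefficient sequence.

    Returns the smoothed frame, the GCV-selected penalty per coefficient and
    the hat matrices (for standard-error propagation).  Constants and linear
    sequences pass through unchanged (they are penalty-free).
    """
    smoother = PSplineSmoother(grid)
    out = {}
    lams: dict[str, float] = {}
    hats: dict[str, np.ndarray] = {}
    for name in beta.columns:
        res = smoother.fit(beta[name].to_numpy(), lam=lam)
        out[name] = res.values
        lams[name] = res.lam
        hats[name] = res.hat_matrix
    frame = pd.DataFrame(out, index=beta.index)
    return frame, lams, hats


def fit_fosr(
    data: MultilevelFunctionalData,
    design: pd.DataFrame,
    smooth: bool = False,
    band_level: float = 0.95,
) -> FoSRFit:
    """Full pointwise-strategy fit with Wald bands.

    Smoothing is off by default so the raw per-t estimates are reported
    transparently; enable it to post-smooth the coefficient sequences (the
    bands are then propagated through the linear smoother under a working
    independence-across-t approximation).
    """
    pw = fit_pointwise(data, design)
    times = data.grid.times
    cols = list(design.columns)
    beta = pd.DataFrame(pw.beta, index=times, columns=cols)
    se = pd.DataFrame(
        np.sqrt(np.maximum(np.diagonal(pw.cov_beta, axis1=1, axis2=2), 0.0)),
        index=times, columns=cols,
    )
    beta_smooth = beta_se_smooth = None
    lams: dict[str, float] = {}
    if smooth:
        beta_smooth, lams, hats = smooth_coefficients(beta, data.grid)
        se_sm = {}
        for name in cols:
            S = hats[name]
            se_sm[name] = np.sqrt(
                np.maximum(np.einsum("ij,j,ij->i", S, se[name].to_numpy() ** 2, S), 0.0)
            )
        beta_se_smooth = pd.DataFrame(se_sm, index=times)
    est = beta_smooth if smooth else beta
    est_se = beta_se_smooth if smooth else se
    bands = _wald_bands(est, est_se, band_level)
    alpha = pd.DataFrame(
        pw.alpha, index=pd.Index(pw.subjects, name="subject_id"), columns=times
    )
    fitted_fixed = design.to_numpy(dtype=float) @ est.to_numpy().T
    alpha_rows = alpha.reindex(data.subject_ids).to_numpy()
    residuals = data.curves - fitted_fixed - alpha_rows
    return FoSRFit(
        grid=data.grid,
        columns=cols,
        beta=beta,
        beta_se=se,
        bands=bands,
        band_level=band_level,
        alpha=alpha,
        residuals=residuals,
        var_subject=pw.var_subject,
        var_resid=pw.var_resid,
        ols_fallback=pw.ols_fallback,
        subject_ids=data.subject_ids,
        meal_index=data.meal_index,
        beta_smooth=beta_smooth,
        beta_se_smooth=beta_se_smooth,
        smoother_lams=lams,
    )


def _wald_bands(
    beta: pd.DataFrame, se: pd.DataFrame, level: float
) -> pd.DataFrame:
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2)
    pieces = {}
    for name in beta.columns:
        pieces[(name, "lower")] = beta[name] - z * se[name]
        pieces[(name, "upper")] = beta[name] + z * se[name]
    return pd.DataFrame(pieces, index=beta.index)


def confidence_bands(
    fit: FoSRFit,
    level: float = 0.95,
    mode: str = "pointwise",
    data: MultilevelFunctionalData | None = None,
    design: pd.DataFrame | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Confidence bands for the coefficient functions.

    ``mode='pointwise'``: Wald bands from the per-t model covariance.
    ``mode='bootstrap'``: percentile bands over ``n_boot`` subject-level
    (cluster) bootstrap refits; requires the fitting data and design.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    if mode == "pointwise":
        return _wald_bands(fit.coefficients, fit.coefficient_se, level)
    if mode != "bootstrap":
        raise ValueError(f"unknown band mode {mode!r}")
    if n_boot <= 0:
        raise ValueError("bootstrap requires a positive number of replicates")
    if n_boot < 50:
        warnings.warn(
            f"{n_boot} bootstrap replicates is too few for stable {level:.0%} bands",
            stacklevel=2,
        )
    if data is None or design is None:
        raise ValueError("bootstrap bands need the fitting data and design")
    rng = np.random.default_rng(seed)
    subjects = data.subjects
    smooth = fit.beta_smooth is not None
    draws = np.empty((n_boot, len(fit.grid), len(fit.columns)))
    for b in range(n_boot):
        picked = rng.choice(subjects, size=subjects.size, replace=True)
        rows, new_ids = [], []
        for rep, s in enumerate(picked):
            idx = np.flatnonzero(data.subject_ids == s)
            rows.append(idx)
            new_ids.append(np.full(idx.size, f"B{rep}"))
        rows = np.concatenate(rows)
        boot_data = MultilevelFunctionalData(
            grid=data.grid,
            curves=data.curves[rows],
            subject_ids=np.concatenate(new_ids),
            meal_index=data.meal_index[rows],
        )
        boot_design = design.iloc[rows].reset_index(drop=True)
        pw = fit_pointwise(boot_data, boot_design)
        est = pw.beta
        if smooth:
            frame = pd.DataFrame(est, index=fit.grid.times, columns=fit.columns)
            est = smooth_coefficients(frame, fit.grid)[0].to_numpy()
        draws[b] = est
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    pieces = {}
    for li, name in enumerate(fit.columns):
        pieces[(name, "lower")] = np.quantile(draws[:, :, li], lo_q, axis=0)
        pieces[(name, "upper")] = np.quantile(draws[:, :, li], hi_q, axis=0)
    return pd.DataFrame(pieces, index=fit.grid.times)


# ---------------------------------------------------------------------------
# prediction and residuals
# ---------------------------------------------------------------------------

def predict(
    fit: FoSRFit,
    design: pd.DataFrame,
    subject_ids: np.ndarray | None = None,
    mode: str = "marginal",
) -> np.ndarray:
    """Fitted curves for each design row.

    ``marginal`` returns sum_l X_l beta_l(t); ``conditional`` adds the
    subject random function alpha_i(t) (zero, with a logged flag, for
    subjects not seen at fit time, which requires ``subject_ids``).
    """
    if mode not in {"marginal", "conditional"}:
        raise ValueError(f"unknown prediction mode {mode!r}")
    if list(design.columns) != fit.columns:
        raise ValueError(
            f"design columns {list(design.columns)} do not match fit {fit.columns}"
        )
    fitted = design.to_numpy(dtype=float) @ fit.coefficients.to_numpy().T
    if mode == "conditional":
        if subject_ids is None:
            raise ValueError("conditional prediction needs subject_ids per row")
        alpha = fit.alpha.reindex(subject_ids)
        unseen = alpha.isna().all(axis=1).to_numpy()
        if unseen.any():
            logger.warning(
                "%d rows belong to subjects unseen at fit time; alpha set to 0",
                int(unseen.sum()),
            )
        fitted = fitted + np.nan_to_num(alpha.to_numpy())
    return fitted


def extract_residuals(
    fit: FoSRFit, data: MultilevelFunctionalData, design: pd.DataFrame
) -> MultilevelFunctionalData:
    """Fixed-effects-only functional residuals Y_ij(t) - sum_l X_l beta_l(t).

    The subject random function is deliberately *not* subtracted: these
    residuals retain the person-level structure that the residual-MFPCA
    outcome analysis extracts.
    """
    fitted = predict(fit, design, mode="marginal")
    return MultilevelFunctionalData(
        grid=data.grid,
        curves=data.curves - fitted,
        subject_ids=data.subject_ids,
        meal_index=data.meal_index,
    )
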