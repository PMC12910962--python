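"""Multilevel functional principal component analysis.

Decomposes repeated postprandial curves Y_ij(t) into a global mean mu(t),
optional per-meal-index shifts nu_j(t), a subject-level random function
U_i(t) = sum_k a_ik phi_k(t) and a meal-level random function
W_ij(t) = sum_h b_ijh psi_h(t), plus white measurement noise.  The two
covariance operators are estimated by method of moments:

* between-subject surface K_B(s,t) from cross-products of *distinct* meals of
  the same subject (these share only U_i, so their expectation is K_B);
* total surface K_T(s,t) from same-meal cross-products, whose off-diagonal
  expectation is K_B + K_W while the diagonal additionally carries the noise
  variance;
* K_W = K_T - K_B, with the noise variance read off as the excess of the raw
  K_T diagonal over its value extrapolated from the near-diagonal band.

Eigenfunctions at each level come from the quadrature-corrected discrete
eigenproblem, so they are orthonormal in L2[0, 360]; scores are best linear
unbiased predictions under the joint Gaussian model (or plain least-squares
projections for noise-free data).  Missing grid points are handled by
pairwise-complete covariance averaging and observed-point scoring — never by
imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate

from .containers import MultilevelFunctionalData
from .grid import FunctionalGrid

__all__ = [
    "LevelDecomposition",
    "MFPCAFit",
    "CovarianceEstimates",
    "estimate_mean_functions",
    "estimate_covariances",
    "eigendecompose_level",
    "estimate_scores",
    "fit_mfpca",
    "reconstruct",
    "select_K_H",
]

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8
ORTHO_TOL = 1e-6


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class LevelDecomposition:
    """Eigenstructure and scores at one hierarchical level."""

    eigenfunctions: np.ndarray  # (n_components, m)
    eigenvalues: np.ndarray  # (n_components,)
    scores: pd.DataFrame  # level 1: subjects x K; level 2: rows x H

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


@dataclass
class CovarianceEstimates:
    between: np.ndarray  # K_B(s,t)
    within: np.ndarray  # K_W(s,t), noise removed from the diagonal
    total: np.ndarray  # K_T(s,t) with diagonal replaced by its extrapolation
    sigma2: float  # measurement-noise variance


@dataclass
class MFPCAFit:
    """Fitted two-level decomposition, aligned with the data it was fit on."""

    grid: FunctionalGrid
    mu: np.ndarray
    nu: pd.DataFrame  # meal-index-wise shifts; zeros when day effects are off
    level1: LevelDecomposition
    level2: LevelDecomposition
    noise_variance: float
    variance_partition: tuple[float, float]  # (subject share, meal share)
    subject_ids: np.ndarray
    meal_index: np.ndarray

    def __post_init__(self) -> None:
        w = self.grid.quad_weights
        for lvl in (self.level1, self.level2):
            fns = lvl.eigenfunctions
            if fns.size:
                gram = (fns * w) @ fns.T
                if not np.allclose(gram, np.eye(fns.shape[0]), atol=ORTHO_TOL):
                    raise ValueError("eigenfunctions are not orthonormal within level")
            if np.any(lvl.eigenvalues < 0) or np.any(np.diff(lvl.eigenvalues) > 0):
                raise ValueError("eigenvalues must be nonnegative and nonincreasing")
        ps, pm = self.variance_partition
        if not (0 <= ps <= 1 and 0 <= pm <= 1 and abs(ps + pm - 1) < 1e-9):
            raise ValueError("variance_partition must be proportions summing to 1")


# ---------------------------------------------------------------------------
# means
# ---------------------------------------------------------------------------

def estimate_mean_functions(
    data: MultilevelFunctionalData,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Pointwise missing-aware mean mu(t) and meal-index shifts nu_j(t).

    nu_j(t) is the mean over curves with meal index j minus mu(t); the
    count-weighted average of the nu_j is zero by construction at fully
    observed grid points.
    """
    Y = data.curves
    obs = data.observed
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        t_bad = data.grid.times[np.argmax(n_obs == 0)]
        raise ValueError(f"no observations at grid time {t_bad} min")
    mu = np.nansum(np.where(obs, Y, 0.0), axis=0) / n_obs
    rows_nu = {}
    for j in np.unique(data.meal_index):
        sel = data.meal_index == j
        cnt = obs[sel].sum(axis=0)
        if np.any(cnt == 0):
            t_bad = data.grid.times[np.argmax(cnt == 0)]
            raise ValueError(
                f"no observations for meal index {j} at grid time {t_bad} min"
            )
        rows_nu[j] = np.nansum(np.where(obs[sel], Y[sel], 0.0), axis=0) / cnt - mu
    nu = pd.DataFrame.from_dict(rows_nu, orient="index")
    nu.index.name = "meal_index"
    nu.columns = data.grid.times
    return mu, nu


def _center(
    data: MultilevelFunctionalData, mu: np.ndarray, nu: pd.DataFrame | None
) -> np.ndarray:
    Yc = data.curves - mu
    if nu is not None:
        shift = nu.reindex(data.meal_index).to_numpy()
        shift = np.where(np.isfinite(shift), shift, 0.0)
        Yc = Yc - shift
    return Yc


# ---------------------------------------------------------------------------
# covariance surfaces
# ---------------------------------------------------------------------------

def _extrapolated_diagonal(K_T: np.ndarray, max_offset: int = 3) -> np.ndarray:
    """Estimate the noise-free diagonal of K_T by linear extrapolation of the
    near-diagonal band toward offset zero."""
    m = K_T.shape[0]
    diag = np.empty(m)
    for i in range(m):
        xs, ys = [], []
        for k in range(1, max_offset + 1):
            for j in (i - k, i + k):
                if 0 <= j < m and np.isfinite(K_T[i, j]):
                    xs.append(float(k))
                    ys.append(K_T[i, j])
        if len(xs) >= 2 and len(set(xs)) >= 2:
            slope, intercept = np.polyfit(xs, ys, 1)
            diag[i] = intercept
        elif ys:
            diag[i] = float(np.mean(ys))
        else:  # pragma: no cover - needs an almost empty surface
            diag[i] = K_T[i, i]
    return diag


def _smooth_surface(K: np.ndarray, grid: FunctionalGrid, s: float) -> np.ndarray:
    t = grid.times
    spl = interpolate.RectBivariateSpline(t, t, K, s=s)
    out = spl(t, t)
    return 0.5 * (out + out.T)


def estimate_covariances(
    centered: MultilevelFunctionalData,
    smooth: float | None = None,
) -> CovarianceEstimates:
    """Method-of-moments two-level covariance surfaces from centered curves.

    Parameters
    ----------
    centered
        Curves already centered by mu (and nu_j when day effects are used).
    smooth
        Optional positive smoothing factor applied to the between/within
        surfaces via a bivariate spline; ``None`` (default) leaves the raw
        method-of-moments surfaces, which is what the brute-force oracle in
        the tests reproduces.
    """
    Y = centered.curves
    obs = centered.observed
    Yf = np.where(obs, Y, 0.0)
    M = obs.astype(float)

    # same-meal cross-products -> K_T (+ sigma^2 on the diagonal)
    C_T = Yf.T @ Yf
    N_T = M.T @ M
    if np.any(N_T == 0):
        raise ValueError("some pair of grid points is never jointly observed")
    K_T_raw = C_T / N_T

    # distinct-meal cross-products within subject -> K_B
    codes = pd.factorize(centered.subject_ids)[0]
    n_sub = codes.max() + 1
    G = np.zeros((n_sub, Y.shape[1]))
    Gm = np.zeros((n_sub, Y.shape[1]))
    np.add.at(G, codes, Yf)
    np.add.at(Gm, codes, M)
    C_B = G.T @ G - C_T
    N_B = Gm.T @ Gm - N_T
    if not np.any(N_B > 0):
        raise ValueError(
            "no subject has two meals jointly observed; between/within levels "
            "are not identifiable"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        K_B = np.where(N_B > 0, C_B / np.maximum(N_B, 1), np.nan)
    if np.any(~np.isfinite(K_B)):
        raise ValueError("some pair of grid points has no within-subject meal pair")
    K_B = 0.5 * (K_B + K_B.T)

    diag_clean = _extrapolated_diagonal(K_T_raw)
    sigma2 = float(np.mean(np.maximum(np.diag(K_T_raw) - diag_clean, 0.0)))
    K_T = K_T_raw.copy()
    np.fill_diagonal(K_T, np.diag(K_T_raw) - sigma2)
    K_T = 0.5 * (K_T + K_T.T)

    K_W = K_T - K_B
    if smooth is not None:
        K_B = _smooth_surface(K_B, centered.grid, smooth)
        K_W = _smooth_surface(K_W, centered.grid, smooth)
    return CovarianceEstimates(between=K_B, within=K_W, total=K_T, sigma2=sigma2)


# ---------------------------------------------------------------------------
# eigendecomposition
# ---------------------------------------------------------------------------

def eigendecompose_level(
    K_surface: np.ndarray, grid: FunctionalGrid, keep_zero: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature-corrected eigendecomposition of a covariance surface.

    Returns eigenfunctions (rows) orthonormal in the functional inner product
    and their nonnegative eigenvalues, sorted nonincreasing; nonpositive
    eigenvalues are truncated and their functions dropped (``keep_zero=True``
    instead keeps every component with its eigenvalue floored at zero, so a
    requested rank can always be met).  Sign convention: each eigenfunction
    integrates to a nonnegative value, ties broken by a nonnegative value at
    t=0.
    """
    K_surface = np.asarray(K_surface, dtype=float)
    m = len(grid)
    if K_surface.shape != (m, m):
        raise ValueError("covariance surface must be square on the grid")
    asym = np.max(np.abs(K_surface - K_surface.T))
    scale = max(np.max(np.abs(K_surface)), 1.0)
    if asym > SYMMETRY_TOL * scale:
        raise ValueError(f"surface is not symmetric (max asymmetry {asym:.3g})")
    w = grid.quad_weights
    sw = np.sqrt(w)
    A = sw[:, None] * K_surface * sw[None, :]
    A = 0.5 * (A + A.T)
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if keep_zero:
        evals = np.maximum(evals, 0.0)
        keep = np.ones(evals.size, dtype=bool)
    else:
        keep = evals > max(1e-12, 1e-10 * max(evals.max(initial=0.0), 0.0))
    evals = evals[keep]
    fns = (evecs[:, keep] / sw[:, None]).T
    for i, f in enumerate(fns):
        integral = float(np.sum(w * f))
        if integral < -1e-10 or (abs(integral) <= 1e-10 and f[0] < 0):
            fns[i] = -f
    return fns, evals


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def estimate_scores(
    centered_data: MultilevelFunctionalData,
    level1_fns: np.ndarray,
    level1_vals: np.ndarray,
    level2_fns: np.ndarray,
    level2_vals: np.ndarray,
    sigma2: float,
    method: str = "blup",
    min_obs: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject scores a_ik and meal scores b_ijh.

    ``method='blup'`` computes best linear unbiased predictions under the
    joint Gaussian model with noise variance ``sigma2`` (shrunk toward zero);
    ``method='projection'`` solves the unpenalized per-subject least-squares
    problem, which is exact for noise-free complete data.  Components with a
    zero eigenvalue have zero prior variance, so their scores are pinned to
    0 (the BLUP limit).  Curves with fewer than ``min_obs`` observed points
    get NaN meal-level scores and do not contribute to their subject's fit.
    """
    if method not in {"blup", "projection"}:
        raise ValueError(f"unknown score method {method!r}")
    K = level1_fns.shape[0]
    H = level2_fns.shape[0]
    if K < 1 or H < 1:
        raise ValueError("need at least one component per level to score")
    act1 = np.flatnonzero(level1_vals > 0)
    act2 = np.flatnonzero(level2_vals > 0)
    Ka, Ha = act1.size, act2.size
    fns1 = level1_fns[act1]
    fns2 = level2_fns[act2]
    Y = centered_data.curves
    obs = centered_data.observed
    subjects = centered_data.subjects
    a = np.zeros((subjects.size, K))
    b = np.full((centered_data.n_rows, H), np.nan)

    use_ls = method == "projection" or sigma2 < 1e-12

    for si, subj in enumerate(subjects):
        rows = np.flatnonzero(centered_data.subject_ids == subj)
        usable = [r for r in rows if obs[r].sum() >= min_obs]
        skipped = [r for r in rows if obs[r].sum() < min_obs]
        for r in skipped:
            logger.warning(
                "curve (subject %s, meal %s) has %d < %d observed points; "
                "scores set to missing",
                subj, centered_data.meal_index[r], int(obs[r].sum()), min_obs,
            )
        if not usable:
            a[si] = np.nan
            continue
        for r in usable:
            b[r] = 0.0
        if Ka + Ha == 0:
            continue
        blocks, ys = [], []
        for pos, r in enumerate(usable):
            o = obs[r]
            z = np.zeros((int(o.sum()), Ka + len(usable) * Ha))
            z[:, :Ka] = fns1[:, o].T
            z[:, Ka + pos * Ha : Ka + (pos + 1) * Ha] = fns2[:, o].T
            blocks.append(z)
            ys.append(Y[r, o])
        Z = np.vstack(blocks)
        yv = np.concatenate(ys)
        if use_ls:
            theta, *_ = np.linalg.lstsq(Z, yv, rcond=None)
        else:
            prior = np.concatenate(
                [1.0 / level1_vals[act1],
                 np.tile(1.0 / level2_vals[act2], len(usable))]
            )
            A = Z.T @ Z / sigma2 + np.diag(prior)
            theta = np.linalg.solve(A, Z.T @ yv / sigma2)
        a[si, act1] = theta[:Ka]
        for pos, r in enumerate(usable):
            b[r, act2] = theta[Ka + pos * Ha : Ka + (pos + 1) * Ha]

    a_frame = pd.DataFrame(
        a, index=pd.Index(subjects, name="subject_id"),
        columns=[f"a{k + 1}" for k in range(K)],
    )
    b_frame = pd.DataFrame(b, columns=[f"b{h + 1}" for h in range(H)]).assign(
        subject_id=centered_data.subject_ids, meal_index=centered_data.meal_index
    )
    return a_frame, b_frame


# ---------------------------------------------------------------------------
# full fit / reconstruction / rank selection
# ---------------------------------------------------------------------------

def fit_mfpca(
    data: MultilevelFunctionalData,
    K: int,
    H: int,
    day_effects: bool = False,
    smooth: float | None = None,
    score_method: str = "blup",
    min_obs: int = 5,
) -> MFPCAFit:
    """Estimate the two-level decomposition with K subject-level and H
    meal-level components.

    ``day_effects=False`` (the default) fixes nu_j(t) = 0, reflecting the
    assumption that there is no systematic meal-index mean shift; set True to
    estimate the shifts.
    """
    if K < 1 or H < 1:
        raise ValueError("K and H must be at least 1")
    mu, nu_hat = estimate_mean_functions(data)
    if day_effects:
        nu = nu_hat
    else:
        nu = pd.DataFrame(
            np.zeros_like(nu_hat.to_numpy()), index=nu_hat.index, columns=nu_hat.columns
        )
    Yc = _center(data, mu, nu if day_effects else None)
    centered = MultilevelFunctionalData(
        grid=data.grid, curves=Yc, subject_ids=data.subject_ids,
        meal_index=data.meal_index,
    )
    cov = estimate_covariances(centered, smooth=smooth)
    phi, lam = eigendecompose_level(cov.between, data.grid, keep_zero=True)
    psi, eta = eigendecompose_level(cov.within, data.grid, keep_zero=True)
    phi, lam = phi[:K], lam[:K]
    psi, eta = psi[:H], eta[:H]
    a_scores, b_scores = estimate_scores(
        centered, phi, lam, psi, eta, cov.sigma2,
        method=score_method, min_obs=min_obs,
    )
    total = float(lam.sum() + eta.sum())
    if total > 0:
        partition = (float(lam.sum()) / total, float(eta.sum()) / total)
    else:  # degenerate (e.g. exactly-zero residual curves)
        partition = (0.5, 0.5)
    return MFPCAFit(
        grid=data.grid,
        mu=mu,
        nu=nu,
        level1=LevelDecomposition(phi, lam, a_scores),
        level2=LevelDecomposition(psi, eta, b_scores),
        noise_variance=cov.sigma2,
        variance_partition=partition,
        subject_ids=data.subject_ids,
        meal_index=data.meal_index,
    )


def reconstruct(fit: MFPCAFit, level: str = "full") -> np.ndarray:
    """Fitted curves from the decomposition.

    ``level='participant_only'`` uses mu + nu_j + sum_k a_ik phi_k;
    ``level='full'`` adds the meal-level expansion sum_h b_ijh psi_h.
    """
    if level not in {"participant_only", "full"}:
        raise ValueError(f"unknown reconstruction level {level!r}")
    nu_rows = fit.nu.reindex(fit.meal_index).to_numpy()
    nu_rows = np.where(np.isfinite(nu_rows), nu_rows, 0.0)
    a = fit.level1.scores.reindex(fit.subject_ids).to_numpy()
    out = fit.mu + nu_rows + np.nan_to_num(a) @ fit.level1.eigenfunctions
    if level == "full":
        b_cols = [c for c in fit.level2.scores.columns if c.startswith("b")]
        b = fit.level2.scores[b_cols].to_numpy()
        out = out + np.nan_to_num(b) @ fit.level2.eigenfunctions
    return out


@dataclass
class RankSelection:
    K: int
    H: int
    profile: pd.Series  # global full-model R^2 per candidate rank
    fits: dict[int, MFPCAFit] = field(default_factory=dict)


def select_K_H(
    data: MultilevelFunctionalData,
    candidates: tuple[int, ...] = (1, 2, 3, 4, 5),
    keep_fits: bool = False,
    **fit_options,
) -> RankSelection:
    """Choose K = H by the elbow of the global full-model R^2 profile.

    Fits each candidate rank and computes the global reconstruction R^2.
    The elbow is the candidate whose profile point lies farthest above the
    chord joining the first and last profile points — the discrete
    maximum-curvature (knee) criterion, which is robust to the estimation
    noise that makes raw second differences of the profile flip between
    adjacent ranks.  When the profile is flat beyond the first candidate
    (every later gain below ``flat_tol``) the first candidate is returned.
    Callers may override the choice from the returned profile.
    """
    from .r2 import global_r2, mfpca_r2

    flat_tol = 0.01
    candidates = tuple(sorted(set(int(c) for c in candidates)))
    if not candidates or candidates[0] < 1:
        raise ValueError("candidates must be positive integers")
    profile = {}
    fits = {}
    for c in candidates:
        fit = fit_mfpca(data, K=c, H=c, **fit_options)
        _, (_, full_global) = mfpca_r2(fit, data)
        profile[c] = full_global.value
        if keep_fits:
            fits[c] = fit
    r = pd.Series(profile).sort_index()
    vals = r.to_numpy()
    x = r.index.to_numpy(dtype=float)
    if vals.size == 1 or np.all(np.diff(vals) < flat_tol):
        best = int(r.index[0])
    else:
        chord = vals[0] + (vals[-1] - vals[0]) * (x - x[0]) / (x[-1] - x[0])
        best = int(r.index[int(np.argmax(vals - chord))])
    return RankSelection(K=best, H=best, profile=r, fits=fits)
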