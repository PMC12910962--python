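"""Latent-representation outcome analysis on functional residuals.

The fixed-effects-only residuals of the function-on-scalar fit are random
functions that still carry person-level structure.  Running the multilevel
principal-component decomposition on them compresses each subject into a
short vector of level-1 scores; regressing a scalar clinical outcome (e.g. a
HOMA-IR insulin-resistance index) on those scores alongside conventional
covariates, and comparing the coefficient of determination with and without
the score terms, quantifies how much predictive information the residual
curves add.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import MultilevelFunctionalData
from .mfpca import MFPCAFit, fit_mfpca

__all__ = [
    "LatentScores",
    "OutcomeRegressionResult",
    "residual_mfpca",
    "outcome_regression",
]


@dataclass
class LatentScores:
    """Per-subject level-1 residual scores with their eigenfunctions."""

    scores: pd.DataFrame  # subjects x K, index subject_id
    eigenfunctions: np.ndarray  # (K, m) for interpretation

    @property
    def subject_ids(self) -> np.ndarray:
        return self.scores.index.to_numpy()

    @property
    def K(self) -> int:
        return self.scores.shape[1]


@dataclass
class OutcomeRegressionResult:
    """Nested OLS comparison: outcome ~ covariates vs + residual scores."""

    coef_scores: pd.Series
    coef_covariates: pd.Series
    r2_with: float
    r2_without: float
    n: int

    @property
    def delta_r2(self) -> float:
        return self.r2_with - self.r2_without


def residual_mfpca(
    residuals: MultilevelFunctionalData, K: int, H: int, **fit_options
) -> tuple[MFPCAFit, LatentScores]:
    """Two-level decomposition of FoSR residual curves.

    Returns the full fit plus the subject-level score matrix, which is the
    latent representation used for outcome prediction.
    """
    fit = fit_mfpca(residuals, K=K, H=H, **fit_options)
    scores = LatentScores(
        scores=fit.level1.scores.copy(),
        eigenfunctions=fit.level1.eigenfunctions.copy(),
    )
    return fit, scores


def outcome_regression(
    outcomes: pd.Series,
    scores: LatentScores,
    covariates: pd.DataFrame | None = None,
    n_scores: int = 2,
) -> OutcomeRegressionResult:
    """OLS of a subject-level outcome on residual scores plus covariates.

    The baseline model uses the covariates (or intercept only); the extended
    model adds the first ``n_scores`` score columns.  Both R-squared values
    and their (always nonnegative) difference are reported.
    """
    if n_scores < 1 or n_scores > scores.K:
        raise ValueError(f"n_scores must be in 1..{scores.K}")
    idx = scores.scores.index
    z = outcomes.reindex(idx)
    if z.isna().any():
        missing = list(idx[z.isna()])[:5]
        raise ValueError(f"outcomes missing for subjects {missing}")
    score_cols = scores.scores.iloc[:, :n_scores]
    if covariates is not None:
        cov = covariates.reindex(idx).astype(float)
        if cov.isna().any().any():
            raise ValueError("covariates missing for some subjects")
    else:
        cov = pd.DataFrame(index=idx)
    n = len(idx)
    p_full = 1 + cov.shape[1] + n_scores
    if n <= p_full:
        raise ValueError(f"{n} subjects cannot support {p_full} parameters")
    X_base = sm.add_constant(cov, has_constant="add")
    X_full = pd.concat([X_base, score_cols], axis=1)
    base = sm.OLS(z.to_numpy(), X_base.to_numpy()).fit()
    full = sm.OLS(z.to_numpy(), X_full.to_numpy()).fit()
    coef_full = pd.Series(full.params, index=X_full.columns)
    return OutcomeRegressionResult(
        coef_scores=coef_full[score_cols.columns],
        coef_covariates=coef_full[X_base.columns],
        r2_with=float(full.rsquared),
        r2_without=float(base.rsquared),
        n=n,
    )
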