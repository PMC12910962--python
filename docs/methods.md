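# Methods

This note records the statistical models `cgmfda` implements, the estimator
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical conventions the code
relies on.

## Data model and notation

A dataset is a collection of postprandial glucose curves Y_ij(t), subject
i = 1..n, meal j = 1..J_i, observed on a shared grid T_m over the 6-hour
window t ∈ [0, 360] minutes (default: every 5 minutes, 73 points). Curves
may have missing grid points; nothing in the package imputes them — means
and covariances are missing-aware, scores use only observed points, and each
pointwise regression uses only the rows observed at that t.

All inner products, norms and integrals use trapezoidal quadrature on the
grid. Consequently eigenvalues are on the integrated scale, (mg/dL)²·min:
dividing the total eigenvalue mass by the 360-min span gives the
time-averaged pointwise curve variance.

## Multilevel functional PCA

Model: Y_ij(t) = μ(t) + ν_j(t) + U_i(t) + W_ij(t) + ε_ijt with
U_i = Σ_k a_ik φ_k, W_ij = Σ_h b_ijh ψ_h, scores Gaussian with variances
λ_k, η_h, and i.i.d. noise ε with variance σ².

**Means.** μ̂ is the pointwise missing-aware grand mean; ν̂_j the mean of
meal-index-j curves minus μ̂ (count-weighted sum zero by construction).
Day effects default to *off* (ν ≡ 0): free-living dinners carry no
meal-index-specific mean shift, and estimating 3–6 extra curves from the
same data only adds variance. `fit_mfpca(day_effects=True)` enables them.

**Covariances by method of moments.** For centered curves,
E[Yc_ij(s) Yc_ik(t)] over *distinct* meals j ≠ k of one subject equals the
between-subject surface K_B(s,t); same-meal products estimate
K_T = K_B + K_W off the diagonal, plus σ² on it. Both are computed by exact
vectorized identities (per-subject sums minus same-row products) that match
a literal loop over all index pairs — the test suite asserts this equality
to machine precision — with pairwise-complete counts under missingness. The
noise variance is read off as the mean excess of the raw K_T diagonal over
its value extrapolated from the near-diagonal band (linear extrapolation in
the offset, using offsets 1–3); K_W = K_T − K_B with the corrected diagonal.
Optional bivariate-spline smoothing of the surfaces exists behind a flag but
is off by default so the transparent estimator remains the one under test.

**Eigendecomposition.** The discrete problem uses the quadrature-weight
correction (eigendecompose W^{1/2} K W^{1/2}), so returned eigenfunctions
are orthonormal in L2[0, 360], not merely as vectors. Negative eigenvalues —
an expected artifact of the subtraction K_W = K_T − K_B — are truncated to
zero. Sign convention: nonnegative integral, ties broken by a nonnegative
value at t = 0. Within-level orthonormality is asserted at 1e-6; cross-level
orthogonality is *not* asserted (the model does not imply it).

**Scores.** Default scoring is BLUP under the joint Gaussian model: per
subject, stack the observed points of all meals, regress on the shared φ
columns and per-meal ψ blocks with ridge precision σ²/λ_k, σ²/η_h.
Components whose eigenvalue is zero have zero prior variance, so their
scores are pinned at 0. A `projection` method (unpenalized per-subject least
squares) is provided; it is exact for noise-free complete data. Curves with
fewer than `min_obs` (default 5) observed points are excluded from their
subject's fit and get missing meal-level scores, with a logged warning.

A note on exactness: when both hierarchical levels are active, the
method-of-moments between-surface contains O(1/√n) cross-level sampling
terms (products of U_i with within-subject meal averages), so the estimated
bases are slightly rotated and even the noise-free saturated reconstruction
has a small error floor (~1e-5 relative in the test scenario). With a single
active level the estimator is exact, and the tests distinguish the two
cases.

**Rank selection.** `select_K_H` fits K = H over a candidate list and
computes the global full-model R² profile. The elbow is the candidate whose
profile point lies farthest above the chord joining the first and last
profile points — the discrete maximum-curvature (knee) criterion. Raw second
differences of the profile were tried first and proved unstable: rank-1 fits
over-explain (the two levels' estimated first eigenfunctions differ slightly
and jointly span two directions), which makes the curvature at ranks 2 and 3
nearly tie and flip across seeds, while the chord criterion picks the
generating rank reliably. A flat profile beyond the first candidate (all
later gains < 0.01) returns the first candidate. The profile is returned so
callers can override.

## Function-on-scalar regression

Model: Y_ij(t) = Σ_l X_ijl β_l(t) + α_i(t) + ε_ij(t), subject random
function α_i, predictors on their natural scale (no standardization — the
coefficient functions read directly as mg/dL per covariate unit). An
intercept column is included by default and can be disabled.

**Pointwise estimation.** At each grid point a scalar linear mixed model
with a subject random intercept is fit by REML; the per-t estimates are
assembled into β̂_l(t), α̂_i(t) (from the per-t intercept BLUPs) and
functional residuals. The random-effect structure per t is intercept-only:
the full α_i(t) emerges from assembling the per-t predictions, which is the
tractable pointwise reading of the model and keeps every per-t fit a
one-variance-component problem.

The per-t solver is written in-house: the REML criterion is profiled to a
1-D search over the variance ratio γ = σ²_α/σ²_ε, with every fixed-γ
quantity closed-form via the Woodbury identity on per-subject blocks. This
runs at well under a millisecond per fit, which is what makes the 200-replicate
calibration studies and cluster bootstrap cheap. It agrees with statsmodels
MixedLM (REML) on coefficients and variance components to ~1e-4 relative,
and its fixed-effect covariance equals the analytic GLS expression exactly;
the test suite checks both routes. When the γ̂ = 0 boundary is optimal the
fit coincides with OLS and the grid point is flagged (`ols_fallback`); a
perfect-fit degeneracy (zero residual variance) short-circuits to exact OLS.

**Smoothing (optional, off by default).** Raw coefficient sequences can be
post-smoothed with a cubic P-spline: B-spline basis on uniform knots,
second-order *divided-difference* penalty at the Greville sites (so constants
and straight lines are reproduced exactly despite the clamped boundary
knots), penalty weight by GCV over a fixed log-grid. The smoother is linear;
its hat matrix propagates pointwise standard errors under a working
independence-across-t approximation, which understates cross-t covariance
but leaves pointwise bands usable. Smoothing defaults to off for
transparency of the per-t estimates.

**Inference.** Default bands are pointwise Wald intervals from the per-t
model covariance; a subject-level (cluster) bootstrap with percentile bands
is available since the pointwise-vs-joint nature of published bands in this
area is usually unstated. Under the null the pointwise 95% bands cover zero
at ~95% of grid points on average (measured 95.3% over 200 replicates at
n=100 subjects, 4 meals, in the acceptance script).

**Residuals.** `extract_residuals` returns fixed-effects-only residuals
Y − ΣXβ̂: the subject random function is deliberately left in, because the
downstream latent-score analysis extracts exactly that person-level
structure. The fit object's own `residuals` field is conditional
(Y = Xβ̂ + α̂ + ε̂ holds exactly by construction).

## Functional R²

Pointwise: R̃²(t) = 1 − Σ_ij (Y_ij(t) − Ỹ_ij(t))² / Σ_ij (Y_ij(t) − Ȳ(t))²
over all curves observed at t (unbalanced designs simply sum over the
observed (i, j) set; Ȳ(t) uses the same set). Values can be negative and
are not clipped — a fit worse than the pointwise grand mean is a
diagnostic. Points with zero denominator are flagged NaN and excluded.

Global: the time average of the pointwise curve, trapezoid integral divided
by the span of the valid subgrid. Dividing by the span (rather than
reporting the bare integral) makes a constant curve aggregate to its own
value and is exact for linear curves.

Variants: MFPCA participant-level (μ̂ + ν̂ + level-1 expansion) vs full
(plus level-2); FoSR marginal (ΣXβ̂) vs conditional (plus α̂_i). Conditional
dominates marginal pointwise on training data because the per-subject BLUP
shrinks the group-mean residual by a factor in [0, 1), which can only reduce
the residual sum of squares. Conditional evaluation is defined on training
subjects; unseen subjects get α̂ = 0 and a flag.

## Latent residual scores and outcome regression

FoSR fixed-effects residuals are decomposed by the same MFPCA machinery; the
per-subject level-1 score vector is the latent representation. The outcome
model is plain OLS of a subject-level scalar on the first `n_scores`
(default 2) score columns plus any subject-level covariates; the baseline
model omits the scores, and the reported delta R² is the (always
nonnegative, by nesting) increment. Estimated scores are attenuated
relative to the realized ones — BLUP shrinkage plus eigenfunction estimation
error — so a designed partial R² of 0.30 measures as ~0.22–0.30 at n = 300;
the acceptance band [0.2, 0.4] reflects that attenuation.

## The synthetic-data generator

The generator draws from exactly the models above, so recovery is testable
against stored truth (all realized scores are kept).

Defaults, chosen once as the study conditions:

- Grid 0–360 min by 5; n = 377 subjects; J_i uniform on {3..6} (a 7-day wear
  with the first day discarded leaves at most six usable dinners).
- Mean μ(t): rise from 100 mg/dL to a ~140 mg/dL peak near 55 min, decaying
  toward baseline by 6 h.
- Eigenfunctions: subject level — a near-constant mode with mild curvature
  around 100 min (overall level), a 60–80-min peak on a cosine carrier (peak
  height), a late-vs-early timing contrast on a sine carrier; meal level —
  peak-height, peak-timing and late-window shapes with the subject-level
  span projected out before orthonormalization. The projection makes the two
  hierarchical levels exactly identifiable in truth: with identical bases at
  both levels, subject scores are structurally confounded with within-subject
  meal-score means (best attainable correlation √(λ/(λ + η/J)) ≈ 0.8), and
  no estimator could meet the package's recovery contracts. The estimators
  never assume this orthogonality.
- Variance: total eigenvalue mass 252,000 (mg/dL)²·min (≈ 700 (mg/dL)²
  pointwise, curve SD ≈ 26 mg/dL), split 33:67 between subject and meal
  levels, and (0.42, 0.32, 0.26) across the three modes within each level —
  three genuinely active modes with a cliff after rank 3, which is what
  makes rank selection meaningful. Measurement noise SD 3 mg/dL.
- Covariates: independent truncated normals (Bernoulli for the
  female-gender indicator) matching published normoglycemic-cohort
  summaries — age 44.6 (13.7) yr, weight 73.7 (14.3) kg, female 62.1%,
  HbA1c 5.25 (0.25)%, carbohydrates 59.9 (40.5) g, fats 30.1 (23.8) g,
  proteins 27.5 (17.9) g, fiber 8.8 (6.7) g, pre-meal glucose 103 (15.3)
  mg/dL, each bounded by the published ranges. The truncated-normal
  parameters are solved by moment matching so the *truncated* mean/SD equal
  the published values; parameterising naively by (mean, sd) would bias the
  carbohydrate mean upward by ~6 g because the zero bound sits only 1.5 SD
  below the mean.
- Coefficient functions: carbohydrates raise the response with a ~60-min
  peak (~0.15 mg/dL per g), fats depress it before ~50 min then mildly raise
  it, fiber blunts it after ~90 min, proteins and gender are null, age peaks
  near 90 min, HbA1c shifts the whole curve, pre-meal glucose is strong
  early and decays. The intercept is set so the expected response under the
  covariate marginals equals μ(t).
- Outcome: Z_i = Σ γ_k a_ik + Σ β X_i + noise, with the default noise SD
  solved so the first two scores carry a partial R² of 0.30.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: covariate correlations (carbs–fiber correlation
in real diets is substantial; draws here are independent and flagged as
unrealistic), circadian meal-timing structure, sensor drift and calibration
artifacts, non-Gaussian score distributions, and any physiological
(differential-equation) glucose dynamics. Recovery results certify the
estimators under the stated model, not the model's fit to any cohort.

## Preprocessing conventions

Windows are aligned by nearest-sample matching within half the nominal step
(2.5 min), preserving raw values; unmatched grid points stay missing. The
pre-meal glucose covariate is the sample nearest t = −5 min within the same
tolerance, else missing (behaviour for streams with no such sample is a
definition, flagged for review, not a published rule). Quality filters work
at the window level: windows starting within 24 h of wear start are dropped
(configurable), as are windows whose longest contiguous signal loss strictly
exceeds 120 min — the gap span is measured between the nearest observed
neighbours (or window edge), so 25 consecutive missing 5-min points count as
a 130-min loss. Timestamps are timezone-naive local clock time. A
finger-stick calibration-count rule used in some protocols requires data not
modelled here and is a documented no-op. After filtering, meal indices are
renumbered 1..J_i per subject.

## Problem sizes and reproducibility

The shipped test and acceptance scenarios use n = 300 subjects × 6 meals for
recovery, 200 replicates of n = 100 × 4 for band calibration, and n = 60–80
for end-to-end pipeline checks — sizes at which the Monte-Carlo error of
each assertion is small relative to its tolerance while the whole suite runs
in about a minute. Every random draw flows from an explicit integer seed;
the pipeline writes a config hash and seed into each output's metadata
block, and identical configurations reproduce byte-identical tables.

## Known limitations

- Two hierarchical levels only; no covariate-adjusted FPCA; no
  function-on-function regression.
- Band propagation through the coefficient smoother ignores cross-t
  covariance of the raw estimates.
- Conditional R² is a training-data quantity; no cross-validated variant.
- The per-t random-effect structure is an intercept; richer α_i(·)
  structures (random slopes in t-varying covariates) are out of scope.
- Scalar-outcome analysis is cross-sectional OLS; longitudinal outcome
  trajectories are not modelled.
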