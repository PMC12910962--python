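# cgmfda

Multilevel functional data analysis of postprandial continuous glucose
monitoring (CGM) trajectories.

Most studies collapse the glucose response to a meal into scalars (2-hour
AUC, peak glucose). `cgmfda` instead treats each 6-hour post-meal trace —
glucose sampled every 5 minutes on the grid t = 0, 5, …, 360 minutes — as a
function Y_ij(t), with subject *i* contributing repeated meals *j*. It is
aimed at biostatisticians and epidemiologists analysing free-living CGM +
meal-diary cohorts, and at anyone who needs a tested, ground-truth-driven
reference implementation of the methods below.

## Models

**Multilevel functional PCA (MFPCA).** Curves decompose into hierarchical
Karhunen–Loève expansions

    Y_ij(t) = μ(t) + ν_j(t) + Σ_k a_ik φ_k(t) + Σ_h b_ijh ψ_h(t) + ε_ijt,

with orthonormal eigenfunctions φ_k (between-subject) and ψ_h
(within-subject, meal-to-meal), Gaussian scores a_ik ~ N(0, λ_k),
b_ijh ~ N(0, η_h), and white measurement noise. Estimation is by
method-of-moments covariance surfaces (distinct-meal cross-products identify
the between-subject operator), quadrature-corrected eigendecomposition, and
BLUP scoring; the split Σλ̂ / (Σλ̂ + Ση̂) is the subject-level variance share.

**Function-on-scalar regression (FoSR).** Time-varying covariate effects
with a subject random function,

    Y_ij(t) = Σ_l X_ijl β_l(t) + α_i(t) + ε_ij(t),

fit by the fast pointwise strategy: an exact profiled-REML random-intercept
model at every grid point, assembled into coefficient functions β̂_l(t) with
95% confidence bands (Wald or cluster bootstrap). Predictors stay on their
natural scale.

**Functional R².** Pointwise R̃²(t) = 1 − SS_res(t)/SS_tot(t) across all
(i, j) curves, aggregated globally as (1/360)∫ R̃²(t) dt by trapezoid rule —
in participant-level vs full variants for MFPCA and marginal (fixed effects)
vs conditional (plus α̂_i) variants for FoSR.

**Latent residual scores.** Fixed-effects-only residuals
ε̂_ij(t) = Y_ij(t) − ΣX β̂(t) are themselves decomposed by MFPCA; each
subject's level-1 score vector then enters an OLS regression for a scalar
outcome (e.g. an insulin-resistance index), and the incremental R² over a
covariate-only model measures what the residual curves add.

A synthetic-data generator produces datasets from exactly these models with
known truth (cohort-realistic covariate marginals, a 33:67 subject:meal
variance split, 3–6 dinners per subject), so every estimator is tested
against the parameters that generated its input. A preprocessing module
turns raw CGM streams + meal diaries into aligned windows, with the
conservative exclusions (first 24 h of wear; >2 h contiguous signal loss)
applied before modelling and no imputation anywhere.

## Worked example

```python
import cgmfda as cf
from cgmfda.fosr import fit_fosr, make_design, extract_residuals
from cgmfda.latent import residual_mfpca, outcome_regression
from cgmfda.r2 import fosr_r2, mfpca_r2

config = cf.default_fosr_config(n_subjects=300, meals_per_subject=6, seed=1)
dataset = cf.simulate_fosr_dataset(config)

mfit = cf.fit_mfpca(dataset.data, K=3, H=3)
(_, p_glob), (_, f_glob) = mfpca_r2(mfit, dataset.data)

design = make_design(dataset.covariates)
ffit = fit_fosr(dataset.data, design)
(_, m_glob), (_, c_glob) = fosr_r2(ffit, dataset.data, design)

resid = extract_residuals(ffit, dataset.data, design)
_, scores = residual_mfpca(resid, K=3, H=3)
reg = outcome_regression(dataset.outcomes, scores, n_scores=2)
```

Output of the accompanying print statements:

```
subject-level variance share: 32.7%
meal-level variance share:    67.3%
participant-level global R2:  0.349
full-model global R2:         0.920
FoSR marginal global R2:      0.102
FoSR conditional global R2:   0.481
carbohydrate effect peaks at  70 min (0.176 mg/dL per g)
outcome R2 without scores:    0.000
outcome R2 with 2 scores:     0.278  (delta 0.278)
```

Reading this: the decomposition attributes about a third of the random-curve
variance to stable between-person differences (the generator's true split is
33:67) and reconstructs most of the data with three modes per level. Fixed
meal/person covariates alone explain ~10% of pointwise variance; adding each
person's predicted random function raises that to ~48%, i.e. who you are
matters more than what the diary records. The carbohydrate coefficient
function peaks near 70 minutes at ~0.18 mg/dL per gram. The residual-score
regression recovers an incremental outcome R² of 0.28 against a designed
truth of 0.30.

## Command line

A thin CLI wraps the same library calls:

```bash
cgmfda run --out-dir results/demo --n-subjects 100 --seed 7
cgmfda preprocess --cgm cgm.csv --meals meals.csv --out-dir results/real
```

Stages (`simulate | preprocess | mfpca | fosr | r2 | latent | run`) share an
artifact directory of CSV tables; every file carries a `# config_hash / seed`
metadata block, and identical configs reproduce byte-identical outputs.

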