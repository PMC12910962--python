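import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cgmfda._lmm import fit_random_intercept
from cgmfda.containers import MultilevelFunctionalData
from cgmfda.fosr import (
    confidence_bands,
    extract_residuals,
    fit_fosr,
    fit_pointwise,
    make_design,
    predict,
    smooth_coefficients,
)
from cgmfda.simulate import default_fosr_config, simulate_fosr_dataset



@pytest.fixture(scope="module")
def small_fosr():
    config = default_fosr_config(n_subjects=60, meals_per_subject=4,
                                 noise_sd=3.0, seed=31, with_outcome=False)
    dataset = simulate_fosr_dataset(config)
    design = make_design(dataset.covariates)
    fit = fit_fosr(dataset.data, design)
    return config, dataset, design, fit


class TestRandomInterceptSolver:
    """The fast profiled-REML solver against statsmodels MixedLM."""

    @pytest.mark.parametrize("seed,sd_b", [(0, 5.0), (1, 0.5), (2, 10.0)])
    def test_matches_statsmodels_reml(self, seed, sd_b):
        rng = np.random.default_rng(seed)
        groups = np.repeat(np.arange(60), 4)
        X = np.column_stack([np.ones(240), rng.normal(size=(240, 2))])
        y = (X @ np.array([2.0, 1.5, -0.7])
             + rng.normal(scale=sd_b, size=60)[groups]
             + rng.normal(scale=3.0, size=240))
        ours = fit_random_intercept(y, X, groups)
        ref = sm.MixedLM(y, X, groups).fit(reml=True)
        assert np.allclose(ours.beta, ref.fe_params, atol=1e-4)
        assert ours.sigma2_e == pytest.approx(ref.scale, rel=1e-3)
        assert ours.sigma2_b == pytest.approx(
            float(np.asarray(ref.cov_re).ravel()[0]), rel=1e-3, abs=1e-3
        )
        # SEs against the analytic GLS covariance at the reference
        # variance components (statsmodels' own bse_fe comes from a
        # numerical Hessian and differs from the GLS value by up to ~2%)
        n = y.size
        Z = np.zeros((n, groups.max() + 1))
        Z[np.arange(n), groups] = 1.0
        V = (float(np.asarray(ref.cov_re).ravel()[0]) * Z @ Z.T
             + ref.scale * np.eye(n))
        cov_gls = np.linalg.inv(X.T @ np.linalg.inv(V) @ X)
        assert np.allclose(np.sqrt(np.diag(ours.cov_beta)),
                           np.sqrt(np.diag(cov_gls)), rtol=1e-3)

    def test_gls_closed_form_oracle_single_point(self):
        # 10 curves, explicit V construction at the solver's variance ratio
        rng = np.random.default_rng(7)
        groups = np.array([0, 0, 1, 1, 2, 2, 3, 3, 4, 4])
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        y = X @ np.array([1.0, 2.0]) + rng.normal(size=10)
        fit = fit_random_intercept(y, X, groups)
        Z = np.zeros((10, 5))
        Z[np.arange(10), groups] = 1.0
        V = fit.sigma2_b * Z @ Z.T + fit.sigma2_e * np.eye(10)
        Vi = np.linalg.inv(V)
        beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.allclose(fit.beta, beta_gls, atol=1e-10)


class TestPointwiseFit:
    def test_exact_recovery_without_randomness(self, grid):
        config = default_fosr_config(n_subjects=30, meals_per_subject=3,
                                     noise_sd=0.0, seed=5, with_outcome=False)
        config = dataclasses.replace(
            config,
            level1_eigenvalues=np.zeros(3),
            level2_eigenvalues=np.zeros(3),
        )
        dataset = simulate_fosr_dataset(config)
        design = make_design(dataset.covariates)
        fit = fit_fosr(dataset.data, design)
        for name in fit.columns:
            assert np.allclose(
                fit.beta[name].to_numpy(),
                config.coefficient_functions[name], atol=1e-8,
            )
        assert fit.ols_fallback.all()

    def test_subject_variance_component_recovered(self, grid):
        # constant subject random intercept with pointwise variance 25:
        # a flat first eigenfunction with integrated mass 25 * span
        t = np.ones(len(grid)) / np.sqrt(grid.span)
        config = default_fosr_config(n_subjects=200, meals_per_subject=4,
                                     noise_sd=3.0, seed=13, with_outcome=False)
        config = dataclasses.replace(
            config,
            level1_eigenfunctions=t[None, :],
            level1_eigenvalues=np.array([25.0 * grid.span]),
        )
        dataset = simulate_fosr_dataset(config)
        design = make_design(dataset.covariates)
        fit = fit_fosr(dataset.data, design)
        assert 15.0 <= np.median(fit.var_subject) <= 35.0

    def test_row_permutation_invariance(self, small_fosr):
        _, dataset, design, fit = small_fosr
        rng = np.random.default_rng(0)
        perm = rng.permutation(dataset.data.n_rows)
        data_p = MultilevelFunctionalData(
            dataset.data.grid, dataset.data.curves[perm],
            dataset.data.subject_ids[perm], dataset.data.meal_index[perm],
        )
        fit_p = fit_fosr(data_p, design.iloc[perm].reset_index(drop=True))
        assert np.allclose(fit_p.beta.to_numpy(), fit.beta.to_numpy(),
                           atol=1e-8)

    def test_covariate_rescaling_equivariance(self, small_fosr):
        _, dataset, design, fit = small_fosr
        scaled = design.copy()
        scaled["carbohydrates"] = scaled["carbohydrates"] * 10.0
        fit_s = fit_fosr(dataset.data, scaled)
        assert np.allclose(
            fit_s.beta["carbohydrates"].to_numpy() * 10.0,
            fit.beta["carbohydrates"].to_numpy(), atol=1e-6,
        )

    def test_rank_deficient_design_names_columns(self, small_fosr):
        _, dataset, design, _ = small_fosr
        bad = design.copy()
        bad["carbs_twice"] = 2.0 * bad["carbohydrates"]
        # one member of the collinear pair must be named
        with pytest.raises(ValueError, match="carb"):
            fit_pointwise(dataset.data, bad)

    def test_missing_design_entries_rejected(self, small_fosr):
        _, dataset, _, _ = small_fosr
        cov = pd.DataFrame({"x": np.ones(dataset.data.n_rows)})
        cov.loc[0, "x"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            make_design(cov)

    def test_coefficient_error_decreases_with_n(self, grid):
        ises = {}
        for n in (50, 400):
            config = default_fosr_config(n_subjects=n, meals_per_subject=4,
                                         noise_sd=3.0, seed=41,
                                         with_outcome=False)
            dataset = simulate_fosr_dataset(config)
            fit = fit_fosr(dataset.data, make_design(dataset.covariates))
            ise = 0.0
            for name in ("carbohydrates", "fiber", "fats"):
                diff = (fit.beta[name].to_numpy()
                        - config.coefficient_functions[name])
                ise += grid.inner(diff, diff)
            ises[n] = ise
        assert ises[400] < ises[50]


class TestSmoothing:
    def test_constant_curve_unchanged(self, grid):
        frame = pd.DataFrame({"c": np.full(len(grid), 3.7)}, index=grid.times)
        sm_frame, _, _ = smooth_coefficients(frame, grid)
        assert np.allclose(sm_frame["c"], 3.7, atol=1e-8)

    def test_linear_curve_unchanged(self, grid):
        frame = pd.DataFrame({"l": 0.02 * grid.times - 1.0}, index=grid.times)
        sm_frame, _, _ = smooth_coefficients(frame, grid)
        assert np.allclose(sm_frame["l"], frame["l"], atol=1e-6)

    def test_noise_reduced_on_noisy_sinusoid(self, grid):
        rng = np.random.default_rng(3)
        truth = np.sin(2 * np.pi * grid.times / 360.0)
        noisy = truth + rng.normal(scale=0.3, size=len(grid))
        frame = pd.DataFrame({"s": noisy}, index=grid.times)
        sm_frame, _, _ = smooth_coefficients(frame, grid)
        ise_raw = grid.inner(noisy - truth, noisy - truth)
        diff = sm_frame["s"].to_numpy() - truth
        ise_smooth = grid.inner(diff, diff)
        assert ise_smooth < ise_raw


class TestBands:
    def test_bands_contain_point_estimate(self, small_fosr):
        *_, fit = small_fosr
        for name in fit.columns:
            assert (fit.bands[(name, "lower")] <= fit.beta[name]).all()
            assert (fit.beta[name] <= fit.bands[(name, "upper")]).all()

    def test_bands_widen_with_level(self, small_fosr):
        *_, fit = small_fosr
        widths = {}
        for level in (0.90, 0.95, 0.99):
            bands = confidence_bands(fit, level=level)
            widths[level] = float(
                (bands[("carbohydrates", "upper")]
                 - bands[("carbohydrates", "lower")]).mean()
            )
        assert widths[0.90] < widths[0.95] < widths[0.99]

    def test_bootstrap_contract(self, small_fosr):
        _, dataset, design, fit = small_fosr
        with pytest.raises(ValueError, match="positive"):
            confidence_bands(fit, mode="bootstrap", n_boot=0,
                             data=dataset.data, design=design)
        with pytest.warns(UserWarning, match="too few"):
            confidence_bands(fit, mode="bootstrap", n_boot=10, seed=1,
                             data=dataset.data, design=design)
        with pytest.raises(ValueError, match="level"):
            confidence_bands(fit, level=1.5)

    def test_bootstrap_bands_bracket_estimates_roughly(self, small_fosr):
        _, dataset, design, fit = small_fosr
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bands = confidence_bands(fit, mode="bootstrap", n_boot=60,
                                     seed=2, data=dataset.data, design=design)
        inside = (
            (bands[("carbohydrates", "lower")] <= fit.beta["carbohydrates"])
            & (fit.beta["carbohydrates"] <= bands[("carbohydrates", "upper")])
        )
        assert inside.mean() > 0.9


class TestPredictionAndResiduals:
    def test_conditional_minus_marginal_is_alpha(self, small_fosr):
        _, dataset, design, fit = small_fosr
        marg = predict(fit, design, mode="marginal")
        cond = predict(fit, design, subject_ids=dataset.data.subject_ids,
                       mode="conditional")
        alpha_rows = fit.alpha.reindex(dataset.data.subject_ids).to_numpy()
        assert np.allclose(cond - marg, alpha_rows, atol=1e-12)

    def test_conditional_fit_no_worse_than_marginal(self, small_fosr):
        _, dataset, design, fit = small_fosr
        marg = predict(fit, design, mode="marginal")
        cond = predict(fit, design, subject_ids=dataset.data.subject_ids,
                       mode="conditional")
        mse_m = np.nanmean((dataset.data.curves - marg) ** 2)
        mse_c = np.nanmean((dataset.data.curves - cond) ** 2)
        assert mse_c <= mse_m

    def test_unseen_subject_gets_zero_alpha(self, small_fosr, caplog):
        _, dataset, design, fit = small_fosr
        one = design.iloc[[0]]
        with caplog.at_level("WARNING"):
            cond = predict(fit, one, subject_ids=np.array(["nobody"]),
                           mode="conditional")
        marg = predict(fit, one, mode="marginal")
        assert np.allclose(cond, marg)
        assert "unseen" in caplog.text

    def test_conditional_residual_identity_exact(self, small_fosr):
        _, dataset, design, fit = small_fosr
        fitted = predict(fit, design, subject_ids=dataset.data.subject_ids,
                         mode="conditional")
        assert np.allclose(fitted + fit.residuals, dataset.data.curves,
                           atol=1e-10)

    def test_perfect_marginal_fit_gives_zero_residuals(self, grid):
        config = default_fosr_config(n_subjects=20, meals_per_subject=3,
                                     noise_sd=0.0, seed=3, with_outcome=False)
        config = dataclasses.replace(
            config, level1_eigenvalues=np.zeros(3),
            level2_eigenvalues=np.zeros(3),
        )
        dataset = simulate_fosr_dataset(config)
        design = make_design(dataset.covariates)
        fit = fit_fosr(dataset.data, design)
        resid = extract_residuals(fit, dataset.data, design)
        assert np.max(np.abs(resid.curves)) < 1e-7

    def test_residual_grand_mean_zero_under_ols(self, grid):
        # no subject structure: the per-t fits drop to OLS, whose residuals
        # average exactly to zero when an intercept is present
        config = default_fosr_config(n_subjects=80, meals_per_subject=3,
                                     noise_sd=4.0, seed=29, with_outcome=False)
        config = dataclasses.replace(
            config, level1_eigenvalues=np.zeros(3),
            level2_eigenvalues=np.zeros(3),
        )
        dataset = simulate_fosr_dataset(config)
        design = make_design(dataset.covariates)
        fit = fit_fosr(dataset.data, design)
        resid = extract_residuals(fit, dataset.data, design)
        means = resid.curves.mean(axis=0)
        assert np.max(np.abs(means[fit.ols_fallback])) < 1e-6
        assert np.max(np.abs(means)) < 0.5

    def test_residuals_retain_subject_random_functions(self, grid):
        # fixed-effects-only residuals keep alpha_i; with many meals the
        # subject-mean residual tracks the true random function closely
        config = default_fosr_config(n_subjects=200, meals_per_subject=12,
                                     noise_sd=3.0, seed=37, with_outcome=False)
        dataset = simulate_fosr_dataset(config)
        design = make_design(dataset.covariates)
        fit = fit_fosr(dataset.data, design)
        resid = extract_residuals(fit, dataset.data, design)
        sub_means = np.vstack([
            resid.curves[resid.subject_ids == s].mean(axis=0)
            for s in resid.subjects
        ])
        truth = dataset.truth.alpha.reindex(resid.subjects).to_numpy()
        corr = np.corrcoef(sub_means.ravel(), truth.ravel())[0, 1]
        assert corr >= 0.9
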