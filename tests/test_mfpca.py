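import dataclasses

import numpy as np
import pandas as pd
import pytest

import cgmfda as cf
from cgmfda.containers import MultilevelFunctionalData
from cgmfda.grid import FunctionalGrid
from cgmfda.mfpca import (
    eigendecompose_level,
    estimate_covariances,
    estimate_mean_functions,
    estimate_scores,
    fit_mfpca,
    reconstruct,
    select_K_H,
)
from cgmfda.simulate import default_eigenfunctions, simulate_mfpca_dataset

from conftest import rank1_config


def small_grid(m=9, span=360.0):
    return FunctionalGrid(times=np.linspace(0.0, span, m), step=span / (m - 1))


def mfd(grid, curves, subjects, meals):
    return MultilevelFunctionalData(
        grid=grid, curves=np.asarray(curves, dtype=float),
        subject_ids=np.asarray(subjects), meal_index=np.asarray(meals),
    )


class TestMeanFunctions:
    def test_identical_curves_give_mu_and_zero_nu(self):
        g = small_grid()
        c = np.linspace(90, 120, len(g))
        data = mfd(g, np.tile(c, (6, 1)), ["A"] * 3 + ["B"] * 3, [1, 2, 3] * 2)
        mu, nu = estimate_mean_functions(data)
        assert np.allclose(mu, c)
        assert np.allclose(nu.to_numpy(), 0.0)

    def test_two_meal_groups_split_around_overall_mean(self):
        g = small_grid()
        rows = [np.full(len(g), 100.0), np.full(len(g), 110.0)] * 2
        data = mfd(g, rows, ["A", "A", "B", "B"], [1, 2, 1, 2])
        mu, nu = estimate_mean_functions(data)
        assert np.allclose(mu, 105.0)
        assert np.allclose(nu.loc[1], -5.0)
        assert np.allclose(nu.loc[2], 5.0)

    def test_count_weighted_day_effects_sum_to_zero(self, grid):
        config = cf.default_mfpca_config(n_subjects=30, seed=3)
        data = simulate_mfpca_dataset(config).data
        mu, nu = estimate_mean_functions(data)
        counts = pd.Series(data.meal_index).value_counts()
        weighted = sum(
            counts[j] * nu.loc[j].to_numpy() for j in nu.index
        ) / counts.sum()
        assert np.max(np.abs(weighted)) < 1e-9

    def test_spurious_day_effects_shrink_with_n(self, grid):
        devs = {}
        for n in (50, 500):
            config = cf.default_mfpca_config(n_subjects=n, meals_per_subject=4,
                                             noise_sd=3.0, seed=6)
            data = simulate_mfpca_dataset(config).data
            _, nu = estimate_mean_functions(data)
            devs[n] = np.max(np.abs(nu.to_numpy()))
        assert devs[500] < devs[50]

    def test_all_missing_time_reported(self):
        g = small_grid()
        curves = np.ones((4, len(g)))
        curves[:, 3] = np.nan
        data = mfd(g, curves, ["A", "A", "B", "B"], [1, 2, 1, 2])
        with pytest.raises(ValueError, match=str(g.times[3])):
            estimate_mean_functions(data)


def brute_force_surfaces(data):
    """Literal loops over all index pairs — the oracle for the
    method-of-moments covariance estimators (complete data)."""
    Y = data.curves
    m = Y.shape[1]
    subs = data.subject_ids
    K_T = np.zeros((m, m))
    n_T = 0
    for r in range(Y.shape[0]):
        K_T += np.outer(Y[r], Y[r])
        n_T += 1
    K_T /= n_T
    K_B = np.zeros((m, m))
    n_B = 0
    for s in np.unique(subs):
        rows = np.flatnonzero(subs == s)
        for i in rows:
            for j in rows:
                if i != j:
                    K_B += np.outer(Y[i], Y[j])
                    n_B += 1
    K_B /= n_B
    K_B = 0.5 * (K_B + K_B.T)
    return K_B, K_T


class TestCovarianceEstimation:
    def test_matches_brute_force_on_tiny_balanced_fixture(self):
        g = small_grid(m=9)
        rng = np.random.default_rng(0)
        curves = rng.normal(size=(8, 9))
        data = mfd(g, curves, np.repeat(["A", "B", "C", "D"], 2),
                   np.tile([1, 2], 4))
        est = estimate_covariances(data)
        K_B, K_T_raw = brute_force_surfaces(data)
        assert np.allclose(est.between, K_B, atol=1e-12)
        # off-diagonal of the total surface is untouched by the noise split
        off = ~np.eye(9, dtype=bool)
        assert np.allclose(est.total[off], K_T_raw[off], atol=1e-12)
        assert np.allclose(
            est.within[off], (K_T_raw - K_B)[off], atol=1e-12
        )

    def test_surfaces_recover_generating_covariances(self, grid):
        config = rank1_config(grid, lam=100.0, eta=50.0, noise_sd=0.0,
                              n=500, J=6, seed=14)
        dataset = simulate_mfpca_dataset(config)
        centered = MultilevelFunctionalData(
            grid, dataset.data.curves - config.mean_function,
            dataset.data.subject_ids, dataset.data.meal_index,
        )
        est = estimate_covariances(centered)
        phi = config.level1_eigenfunctions[0]
        psi = config.level2_eigenfunctions[0]
        true_B = 100.0 * np.outer(phi, phi)
        true_W = 50.0 * np.outer(psi, psi)
        assert (np.linalg.norm(est.between - true_B)
                <= 0.10 * np.linalg.norm(true_B))
        assert (np.linalg.norm(est.within - true_W)
                <= 0.10 * np.linalg.norm(true_W))

    def test_zero_meal_level_mass_gives_vanishing_within_surface(self, grid):
        config = rank1_config(grid, lam=100.0, eta=0.0, noise_sd=0.0,
                              n=800, J=4, seed=2)
        dataset = simulate_mfpca_dataset(config)
        centered = MultilevelFunctionalData(
            grid, dataset.data.curves - config.mean_function,
            dataset.data.subject_ids, dataset.data.meal_index,
        )
        est = estimate_covariances(centered)
        assert np.max(np.abs(est.within)) < 0.05 * np.max(np.abs(est.between))

    def test_symmetry_is_exact(self, standard_mfpca):
        _, dataset, _ = standard_mfpca
        mu, _ = estimate_mean_functions(dataset.data)
        centered = MultilevelFunctionalData(
            dataset.data.grid, dataset.data.curves - mu,
            dataset.data.subject_ids, dataset.data.meal_index,
        )
        est = estimate_covariances(centered)
        assert np.array_equal(est.between, est.between.T)
        assert np.array_equal(est.within, est.within.T)

    def test_single_meal_subjects_not_identifiable(self):
        g = small_grid()
        data = mfd(g, np.ones((3, len(g))), ["A", "B", "C"], [1, 1, 1])
        with pytest.raises(ValueError, match="two meals"):
            estimate_covariances(data)


class TestEigendecomposition:
    def test_rank_one_surface_recovered_exactly(self, grid):
        phi = default_eigenfunctions(grid, 1)[0]
        fns, vals = eigendecompose_level(4.0 * np.outer(phi, phi), grid)
        assert vals.shape == (1,)
        assert vals[0] == pytest.approx(4.0, abs=1e-10)
        assert np.allclose(np.abs(fns[0]), np.abs(phi), atol=1e-8)

    def test_two_component_eigenvalues_recovered(self, grid):
        fns_true = default_eigenfunctions(grid, 3)[:2]
        K = 4.0 * np.outer(fns_true[0], fns_true[0]) + 1.0 * np.outer(
            fns_true[1], fns_true[1]
        )
        _, vals = eigendecompose_level(K, grid)
        assert np.allclose(vals[:2], [4.0, 1.0], atol=1e-8)

    def test_zero_surface_gives_empty_retained_set(self, grid):
        fns, vals = eigendecompose_level(np.zeros((len(grid), len(grid))), grid)
        assert vals.size == 0 and fns.shape[0] == 0

    def test_asymmetric_surface_rejected(self, grid):
        K = np.zeros((len(grid), len(grid)))
        K[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose_level(K, grid)

    def test_sign_convention_nonnegative_integral(self, standard_mfpca):
        _, _, fit = standard_mfpca
        w = fit.grid.quad_weights
        for fns in (fit.level1.eigenfunctions, fit.level2.eigenfunctions):
            for f in fns:
                assert np.sum(w * f) >= -1e-10


class TestScores:
    def test_projection_exact_for_noise_free_complete_data(self, grid):
        config = cf.default_mfpca_config(n_subjects=40, meals_per_subject=4,
                                         noise_sd=0.0, seed=5)
        dataset = simulate_mfpca_dataset(config)
        centered = MultilevelFunctionalData(
            grid, dataset.data.curves - config.mean_function,
            dataset.data.subject_ids, dataset.data.meal_index,
        )
        a, b = estimate_scores(
            centered,
            config.level1_eigenfunctions, config.level1_eigenvalues,
            config.level2_eigenfunctions, config.level2_eigenvalues,
            sigma2=0.0, method="projection",
        )
        assert np.allclose(a.to_numpy(),
                           dataset.truth.scores_level1.to_numpy(), atol=1e-6)
        cols = [c for c in b.columns if c.startswith("b")]
        assert np.allclose(b[cols].to_numpy(),
                           dataset.truth.scores_level2[cols].to_numpy(),
                           atol=1e-6)

    def test_zero_curves_give_zero_scores(self, grid):
        centered = MultilevelFunctionalData(
            grid, np.zeros((6, len(grid))),
            np.repeat(["A", "B", "C"], 2), np.tile([1, 2], 3),
        )
        phi = default_eigenfunctions(grid, 2, level="subject")
        psi = default_eigenfunctions(grid, 2, level="meal")
        a, b = estimate_scores(centered, phi, np.array([2.0, 1.0]),
                               psi, np.array([2.0, 1.0]), sigma2=1.0)
        assert np.allclose(a.to_numpy(), 0.0)
        assert np.allclose(b[["b1", "b2"]].to_numpy(), 0.0)

    def test_blup_scores_shrink_below_eigenvalue(self, grid):
        # in a noisy regime the BLUP predictions are visibly shrunk: their
        # sample variance stays below the prior eigenvalue
        config = rank1_config(grid, lam=100.0, eta=50.0, noise_sd=5.0,
                              n=500, J=6, seed=23)
        dataset = simulate_mfpca_dataset(config)
        fit = fit_mfpca(dataset.data, K=1, H=1)
        assert fit.level1.scores["a1"].var(ddof=1) < fit.level1.eigenvalues[0]

    def test_sparse_curve_scores_flagged_missing(self, grid, caplog):
        curves = np.random.default_rng(1).normal(size=(4, len(grid)))
        curves[3, 3:] = np.nan  # 3 observed points < min_obs
        centered = MultilevelFunctionalData(
            grid, curves, ["A", "A", "B", "B"], [1, 2, 1, 2]
        )
        phi = default_eigenfunctions(grid, 1, level="subject")
        psi = default_eigenfunctions(grid, 1, level="meal")
        with caplog.at_level("WARNING"):
            a, b = estimate_scores(centered, phi, np.array([1.0]),
                                   psi, np.array([1.0]), sigma2=0.5,
                                   min_obs=5)
        assert np.isnan(b["b1"].iloc[3])
        assert "observed points" in caplog.text


class TestFullFit:
    def test_variance_partition_recovers_33_67_split(self, standard_mfpca):
        _, _, fit = standard_mfpca
        assert abs(fit.variance_partition[0] - 0.33) < 0.05
        assert fit.variance_partition[0] + fit.variance_partition[1] == (
            pytest.approx(1.0)
        )

    def test_first_eigenfunction_recovered(self, standard_mfpca):
        config, _, fit = standard_mfpca
        align = abs(fit.grid.inner(fit.level1.eigenfunctions[0],
                                   config.level1_eigenfunctions[0]))
        assert align >= 0.95

    def test_total_variance_conserved_noise_free(self, grid):
        config = cf.default_mfpca_config(n_subjects=300, meals_per_subject=6,
                                         noise_sd=0.0, seed=17)
        dataset = simulate_mfpca_dataset(config)
        fit = fit_mfpca(dataset.data, K=3, H=3)
        total_hat = fit.level1.eigenvalues.sum() + fit.level2.eigenvalues.sum()
        total_true = (config.level1_eigenvalues.sum()
                      + config.level2_eigenvalues.sum())
        assert abs(total_hat - total_true) < 0.10 * total_true

    def test_orthonormality_within_levels(self, standard_mfpca):
        _, _, fit = standard_mfpca
        w = fit.grid.quad_weights
        for fns in (fit.level1.eigenfunctions, fit.level2.eigenfunctions):
            gram = (fns * w) @ fns.T
            assert np.allclose(gram, np.eye(fns.shape[0]), atol=1e-6)

    def test_bootstrap_resample_refits_cleanly(self, standard_mfpca):
        _, dataset, _ = standard_mfpca
        rng = np.random.default_rng(3)
        picked = rng.choice(dataset.data.subjects, size=80, replace=True)
        rows, ids = [], []
        for k, s in enumerate(picked):
            idx = np.flatnonzero(dataset.data.subject_ids == s)
            rows.append(idx)
            ids.append([f"R{k}"] * idx.size)
        boot = MultilevelFunctionalData(
            dataset.data.grid,
            dataset.data.curves[np.concatenate(rows)],
            np.concatenate(ids),
            dataset.data.meal_index[np.concatenate(rows)],
        )
        fit = fit_mfpca(boot, K=3, H=3)
        assert 0 <= fit.variance_partition[0] <= 1


class TestReconstruction:
    def test_zero_scores_reconstruct_the_mean_surface(self, grid):
        config = rank1_config(grid, lam=0.0, eta=0.0, noise_sd=1.0, n=30, J=3,
                              seed=1)
        dataset = simulate_mfpca_dataset(config)
        fit = fit_mfpca(dataset.data, K=1, H=1)
        fit.level1.scores.iloc[:, :] = 0.0
        fit.level2.scores[["b1"]] = 0.0
        rec = reconstruct(fit, "participant_only")
        assert np.allclose(rec, fit.mu)

    def test_full_reconstruction_never_worse_than_participant_only(
        self, standard_mfpca
    ):
        _, dataset, fit = standard_mfpca
        err_part = np.mean(
            (dataset.data.curves - reconstruct(fit, "participant_only")) ** 2
        )
        err_full = np.mean(
            (dataset.data.curves - reconstruct(fit, "full")) ** 2
        )
        assert err_full <= err_part

    def test_noise_free_saturated_fit_reproduces_data(self, grid):
        # subject-level-only truth: the between surface is estimated without
        # cross-level sampling terms, so the saturated projection fit is exact
        config = cf.default_mfpca_config(n_subjects=50, meals_per_subject=4,
                                         noise_sd=0.0, seed=19)
        config = dataclasses.replace(config, level2_eigenvalues=np.zeros(3))
        dataset = simulate_mfpca_dataset(config)
        fit = fit_mfpca(dataset.data, K=3, H=3, score_method="projection")
        rec = reconstruct(fit, "full")
        assert np.max(np.abs(rec - dataset.data.curves)) < 1e-6

    def test_noise_free_two_level_fit_near_exact(self, grid):
        # with both levels active the estimated bases carry O(1/sqrt(n))
        # cross-level rotations; reconstruction is near- but not machine-exact
        config = cf.default_mfpca_config(n_subjects=50, meals_per_subject=4,
                                         noise_sd=0.0, seed=19)
        dataset = simulate_mfpca_dataset(config)
        fit = fit_mfpca(dataset.data, K=3, H=3, score_method="projection")
        rec = reconstruct(fit, "full")
        resid = rec - dataset.data.curves
        rel = np.sum(resid**2) / np.sum(
            (dataset.data.curves - dataset.data.curves.mean(0)) ** 2
        )
        assert rel < 1e-4

    def test_unknown_level_tag_rejected(self, standard_mfpca):
        _, _, fit = standard_mfpca
        with pytest.raises(ValueError, match="level"):
            reconstruct(fit, "both")


class TestRankSelection:
    def test_elbow_found_at_generating_rank(self, standard_mfpca):
        _, dataset, _ = standard_mfpca
        sel = select_K_H(dataset.data, candidates=(1, 2, 3, 4, 5))
        assert sel.K == 3 and sel.H == 3

    def test_single_component_truth_gives_elbow_one(self, grid):
        config = rank1_config(grid, lam=34000.0, eta=70000.0, noise_sd=3.0,
                              n=200, J=4, seed=7)
        dataset = simulate_mfpca_dataset(config)
        sel = select_K_H(dataset.data, candidates=(1, 2, 3, 4))
        assert sel.K == 1

    def test_profile_nondecreasing_up_to_noise(self, standard_mfpca):
        _, dataset, _ = standard_mfpca
        sel = select_K_H(dataset.data, candidates=(1, 2, 3, 4, 5))
        gains = np.diff(sel.profile.to_numpy())
        assert np.all(gains > -1e-3)
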