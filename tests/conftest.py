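import numpy as np
import pytest

import cgmfda as cf
from cgmfda.fosr import fit_fosr, make_design
from cgmfda.simulate import (
    SimulationConfig,
    default_eigenfunctions,
    default_mean_function,
)


@pytest.fixture(scope="session")
def grid():
    return cf.make_default_grid()


@pytest.fixture(scope="session")
def standard_mfpca():
    """The standard recovery scenario: n=300 subjects, 6 meals each,
    33:67 subject:meal variance split over 3 modes per level, noise SD 3."""
    config = cf.default_mfpca_config(
        n_subjects=300, meals_per_subject=6, noise_sd=3.0, seed=11
    )
    dataset = cf.simulate_mfpca_dataset(config)
    fit = cf.fit_mfpca(dataset.data, K=3, H=3)
    return config, dataset, fit


@pytest.fixture(scope="session")
def standard_fosr():
    """Regression scenario with study-like covariates and an outcome whose
    true partial R^2 on the first two subject scores is 0.3."""
    config = cf.default_fosr_config(
        n_subjects=300, meals_per_subject=6, noise_sd=3.0, seed=1
    )
    dataset = cf.simulate_fosr_dataset(config)
    design = make_design(dataset.covariates)
    fit = fit_fosr(dataset.data, design)
    return config, dataset, design, fit


def rank1_config(grid, lam=100.0, eta=50.0, noise_sd=0.0, n=500, J=6, seed=0):
    """Single-mode-per-level generator with orthogonal level bases."""
    phi = default_eigenfunctions(grid, 1, level="subject")
    psi = default_eigenfunctions(grid, 1, level="meal")
    return SimulationConfig(
        n_subjects=n,
        meals_per_subject=J,
        grid=grid,
        mean_function=default_mean_function(grid),
        level1_eigenfunctions=phi,
        level1_eigenvalues=np.array([lam]),
        level2_eigenfunctions=psi,
        level2_eigenvalues=np.array([eta]),
        noise_sd=noise_sd,
        seed=seed,
    )
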