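"""Shared fixtures: reduced-scale synthetic datasets and fits.

The reduced fixture shrinks the monitoring program to 2 reefs x 2 sites
over a 1994-2001 window with n = 100 trials and drops the spline and
dummy blocks, keeping the nested random effects and the interrupted
time-series terms; it is small enough for repeated MCMC in tests while
exercising the full hierarchy.
"""

import warnings

import pytest

import reefdesign as rd

REDUCED_PRIORS = rd.PriorSpec(coef_sd=5.0, logsd_mean=-1.2, logsd_sd=0.15)


@pytest.fixture(scope="session")
def reduced_model():
    return rd.ModelConfig(smooth=False, covariates=("bleaching",), dummies=())


@pytest.fixture(scope="session")
def reduced_gen(reduced_model):
    return rd.GeneratorConfig(
        reefs=("SL1", "SL2"),
        sites_per_reef=2,
        start_year=1994,
        end_year=2001,
        n_trials=100,
        model=reduced_model,
        seed=7,
    )


@pytest.fixture(scope="session")
def reduced_dataset(reduced_gen):
    dataset, truth = rd.generate_dataset(reduced_gen)
    return dataset, truth


@pytest.fixture(scope="session")
def reduced_matrices(reduced_dataset, reduced_model):
    dataset, _ = reduced_dataset
    return rd.build_design_matrices(dataset, reduced_model)


@pytest.fixture(scope="session")
def reduced_fit(reduced_dataset, reduced_model):
    """A long MCMC run on the reduced dataset (shared across tests)."""
    dataset, _ = reduced_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples = rd.fit_mcmc(
            dataset, reduced_model, REDUCED_PRIORS,
            chains=4, iterations=16_000, seed=3,
        )
    return samples


@pytest.fixture(scope="session")
def reduced_design_prior(reduced_fit):
    return rd.summarize_gaussian(reduced_fit)


@pytest.fixture(scope="session")
def full_dataset():
    """A full-scale Scott-Reef-like dataset (7 reefs x 3 sites x 25 times)."""
    dataset, truth = rd.generate_dataset(rd.GeneratorConfig(seed=11))
    return dataset, truth


@pytest.fixture(scope="session")
def full_matrices(full_dataset):
    dataset, _ = full_dataset
    return rd.build_design_matrices(dataset)


@pytest.fixture(scope="session")
def full_fit(full_matrices):
    """MCMC posterior of the full-scale synthetic dataset (shared)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rd.fit_mcmc(
            full_matrices, priors=rd.PriorSpec(),
            chains=4, iterations=4000, seed=3,
        )


@pytest.fixture(scope="session")
def full_joint_prior(full_fit):
    """Joint (theta, xi) Gaussian design prior from the full-scale fit."""
    return rd.summarize_gaussian(full_fit, scope="all")
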