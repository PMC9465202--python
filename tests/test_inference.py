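"""Inference layer: priors, MCMC, DIC, Laplace, Gaussian summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest

import reefdesign as rd
from reefdesign.inference import LaplaceWarning
from tests.conftest import REDUCED_PRIORS


def _empty_dataset():
    surveys = pd.DataFrame(columns=["reef", "site", "time", "y", "n"])
    covariates = pd.DataFrame(
        {"time": [2000.0], "bleaching": [1], "cyclone_hours": [0.0]}
    )
    dummies = pd.DataFrame(
        {"reef": ["SL1"], "cyclone_loc": [0], "severe_cyclone_loc": [0],
         "bleaching_loc": [0]}
    )
    return rd.HistoricalDataset(surveys, covariates, dummies, event_time=2000.0)


NO_DATA_MODEL = rd.ModelConfig(
    smooth=False, nested_random_effects=False, covariates=(), dummies=(),
    its=False,
)


class TestMCMC:
    def test_prior_recovery_with_no_data(self):
        # with an empty dataset the posterior is the prior: per-parameter
        # mean/sd within 3 Monte Carlo standard errors
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            samples = rd.fit_mcmc(
                _empty_dataset(), NO_DATA_MODEL, rd.PriorSpec(),
                chains=2, iterations=6000, seed=1,
            )
        draws = samples.to_dataframe()
        n_eff_floor = 200  # conservative: autocorrelated random walk
        for name in ("intercept", "time"):
            x = draws[name]
            se_mean = 10.0 / np.sqrt(n_eff_floor)
            assert abs(x.mean()) < 3 * se_mean
            assert abs(x.std() - 10.0) < 3 * se_mean

    def test_identical_seed_gives_bitwise_identical_draws(self, reduced_dataset,
                                                          reduced_model):
        dataset, _ = reduced_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = rd.fit_mcmc(dataset, reduced_model, REDUCED_PRIORS,
                            chains=2, iterations=600, seed=9)
            b = rd.fit_mcmc(dataset, reduced_model, REDUCED_PRIORS,
                            chains=2, iterations=600, seed=9)
            c = rd.fit_mcmc(dataset, reduced_model, REDUCED_PRIORS,
                            chains=2, iterations=600, seed=10)
        assert np.array_equal(a.draws, b.draws)
        assert not np.array_equal(a.draws, c.draws)

    def test_convergence_diagnostics_reported(self, reduced_fit):
        rhat = {k: v for k, v in reduced_fit.rhat.items() if np.isfinite(v)}
        assert rhat
        assert max(rhat.values()) < 1.05

    def test_draws_write_and_reload(self, reduced_fit, tmp_path):
        paths = reduced_fit.write(tmp_path)
        back = pd.read_csv(paths["draws"])
        assert list(back.columns) == list(reduced_fit.names)
        assert len(back) == reduced_fit.stacked().shape[0]


class TestDIC:
    def test_decomposition_identity_and_degenerate_pd(self, reduced_matrices,
                                                      reduced_fit):
        dic, pd_, dbar = rd.compute_dic(reduced_fit, reduced_matrices)
        assert dic == pytest.approx(dbar + pd_)
        assert pd_ >= 0
        # degenerate posterior: every draw identical -> pD exactly 0
        one = reduced_fit.draws[:1, :1, :].repeat(600, axis=1)
        frozen = rd.PosteriorSamples(
            reduced_fit.index, one, reduced_fit.seed, {}, {}
        )
        _, pd0, _ = rd.compute_dic(frozen, reduced_matrices)
        assert pd0 == pytest.approx(0.0, abs=1e-9)

    def test_pd_near_parameter_count_for_well_identified_glm(self):
        # for a fixed-effects logistic model with vague priors and strong
        # data, pD approaches the parameter count (the Gaussian
        # conjugate shrinkage limit): here 2 parameters
        model = rd.ModelConfig(
            smooth=False, nested_random_effects=False, covariates=(),
            dummies=(), its=False,
        )
        gen = rd.GeneratorConfig(
            reefs=("SL1", "SL2"), sites_per_reef=3, n_trials=1250,
            model=model, seed=5, true_sds=(("sigma_reef", 1e-6),
                                           ("sigma_site", 1e-6)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dataset, _ = rd.generate_dataset(gen)
            samples = rd.fit_mcmc(dataset, model, rd.PriorSpec(),
                                  chains=2, iterations=6000, seed=2)
            _, pd_, _ = rd.compute_dic(samples, rd.build_design_matrices(
                dataset, model))
        assert pd_ == pytest.approx(2.0, rel=0.10)

    def test_extra_noise_covariate_increases_pd(self):
        # fixed-effects-only candidates: the effective parameter count
        # tracks the column count, so a pure-noise covariate (the data
        # are generated without any cyclone effect) raises pD
        base_model = rd.ModelConfig(
            smooth=False, nested_random_effects=False,
            covariates=("bleaching",), dummies=(),
        )
        richer = rd.ModelConfig(
            smooth=False, nested_random_effects=False,
            covariates=("bleaching", "sqrt_cyclone"), dummies=(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dataset, _ = rd.generate_dataset(
                rd.GeneratorConfig(
                    reefs=("SL1", "SL2"), sites_per_reef=2,
                    start_year=1994, end_year=2006, n_trials=100,
                    model=base_model, seed=4,
                )
            )
        wins = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(3):
                base = rd.fit_mcmc(dataset, base_model, REDUCED_PRIORS,
                                   chains=2, iterations=3000, seed=seed)
                more = rd.fit_mcmc(dataset, richer, REDUCED_PRIORS,
                                   chains=2, iterations=3000, seed=seed)
                _, pd_base, _ = rd.compute_dic(
                    base, rd.build_design_matrices(dataset, base_model))
                _, pd_more, _ = rd.compute_dic(
                    more, rd.build_design_matrices(dataset, richer))
                wins += pd_more > pd_base
        assert wins >= 2


class TestLaplace:
    def test_exact_for_gaussian_posterior(self):
        # Gaussian likelihood x Gaussian prior: the Laplace recovers the
        # conjugate posterior to machine-ish precision
        rng = np.random.default_rng(3)
        prec = np.array([[2.0, 0.3, 0.0], [0.3, 1.5, -0.2], [0.0, -0.2, 1.0]])
        mean = np.array([0.5, -1.0, 2.0])

        def logpost(u):
            d = u - mean
            return float(-0.5 * d @ prec @ d)

        def grad(u):
            return -prec @ (u - mean)

        approx = rd.laplace_from_logpost(
            logpost, grad, np.zeros(3), ["a", "b", "c"]
        )
        assert np.allclose(approx.mean, mean, atol=1e-6)
        assert np.allclose(approx.cov, np.linalg.inv(prec), atol=1e-5)

    def test_no_new_data_returns_the_design_prior_exactly(
        self, reduced_matrices, reduced_design_prior
    ):
        from reefdesign.inference import BinomialRows, _Posterior, _marginal_laplace

        idx = reduced_matrices.index
        rows = BinomialRows(
            np.empty((0, idx.n_beta + idx.K)), np.empty(0, dtype=int),
            np.empty(0), np.empty(0),
        )
        post = _Posterior(rows, idx, reduced_design_prior)
        post.attach_reef_map(reduced_matrices.unit_reef_index)
        out = _marginal_laplace(post, reduced_design_prior.mean.copy())
        assert np.allclose(out.mean, reduced_design_prior.mean, atol=1e-6)
        assert np.allclose(out.cov, reduced_design_prior.cov, atol=1e-6,
                           rtol=1e-4)

    def test_boundary_count_flags_flat_direction(self):
        # a single saturated record (y = n) pushes the success probability
        # to the boundary; without a prior the logit direction is flat
        def logpost(u):
            return float(5 * u[0] - 5 * np.logaddexp(0.0, u[0]))

        def grad(u):
            pi = 1.0 / (1.0 + np.exp(-u[0]))
            return np.array([5 * (1.0 - pi)])

        with pytest.warns(LaplaceWarning):
            approx = rd.laplace_from_logpost(
                logpost, grad, np.zeros(1), ["logit"]
            )
        assert approx.cov[0, 0] > 1e3  # clipped near-flat curvature


class TestGaussianSummary:
    def test_moments_recovered_from_known_gaussian(self):
        rng = np.random.default_rng(8)
        mean = np.array([1.0, -2.0])
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        draws = rng.multivariate_normal(mean, cov, size=4000)
        idx = rd.ParameterIndex(NO_DATA_MODEL, (), ())
        samples = rd.PosteriorSamples(
            idx, draws[None, :, :], 0, {}, {}
        )
        approx = rd.summarize_gaussian(samples, scope="all")
        se = np.sqrt(np.diag(cov) / 4000)
        assert np.all(np.abs(approx.mean - mean) < 3 * se)
        assert np.allclose(approx.cov, cov, atol=0.2)

    def test_duplicated_draw_gives_psd_clip_warning(self):
        idx = rd.ParameterIndex(NO_DATA_MODEL, (), ())
        draws = np.ones((1, 50, idx.n_theta))
        samples = rd.PosteriorSamples(idx, draws, 0, {}, {})
        with pytest.warns(LaplaceWarning):
            approx = rd.summarize_gaussian(samples, scope="all")
        assert np.allclose(approx.cov, 0.0)

    def test_scope_restriction_and_unknown_names(self, reduced_fit):
        beta_only = rd.summarize_gaussian(
            reduced_fit, scope=list(reduced_fit.index.beta_names)
        )
        assert beta_only.dim == reduced_fit.index.n_beta
        with pytest.raises(KeyError):
            rd.summarize_gaussian(reduced_fit, scope=["not_a_parameter"])

    def test_json_round_trip(self, reduced_design_prior, tmp_path):
        path = tmp_path / "prior.json"
        reduced_design_prior.to_json(path)
        back = rd.GaussianApprox.from_json(path)
        assert back.names == reduced_design_prior.names
        assert np.allclose(back.mean, reduced_design_prior.mean)
        assert np.allclose(back.cov, reduced_design_prior.cov)
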