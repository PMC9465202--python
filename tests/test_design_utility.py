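"""Design utility: Gaussian KLD, Taylor extrapolation, Monte Carlo gain."""

import warnings

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import multivariate_normal

import reefdesign as rd
from reefdesign.design_utility import TaylorCenter, _taylor_fixed_row


def _gauss(mean, cov, names=None):
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    names = names or [f"p{i}" for i in range(mean.size)]
    return rd.GaussianApprox(mean, cov, names)


class TestKLDGaussian:
    def test_identical_gaussians_give_zero(self):
        g = _gauss([0.3, -1.0], [[2.0, 0.5], [0.5, 1.0]])
        assert abs(rd.kld_gaussian(g, g)) < 1e-12

    def test_unit_mean_shift_is_exactly_half(self):
        prior = _gauss([0.0], [[1.0]])
        post = _gauss([1.0], [[1.0]])
        assert rd.kld_gaussian(post, prior) == pytest.approx(0.5, abs=1e-12)

    def test_variance_contraction_matches_frozen_closed_form(self):
        # KL(N(0,1) || N(0,4)) = 0.5 (1/4 - 1 + ln 4) = 0.3181471805599453
        prior = _gauss([0.0], [[4.0]])
        post = _gauss([0.0], [[1.0]])
        assert rd.kld_gaussian(post, prior) == pytest.approx(
            0.3181471805599453, abs=1e-12
        )

    def test_matches_numerical_integration_oracle_1d(self):
        prior = _gauss([0.7], [[2.3]])
        post = _gauss([-0.4], [[0.9]])

        def integrand(x):
            lp = -0.5 * (x + 0.4) ** 2 / 0.9 - 0.5 * np.log(2 * np.pi * 0.9)
            lq = -0.5 * (x - 0.7) ** 2 / 2.3 - 0.5 * np.log(2 * np.pi * 2.3)
            return np.exp(lp) * (lp - lq)

        oracle, _ = integrate.quad(integrand, -12, 12)
        assert rd.kld_gaussian(post, prior) == pytest.approx(oracle, rel=1e-6)

    def test_permutation_invariance_is_exact(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(3, 3))
        prior = _gauss(rng.normal(size=3), a @ a.T + np.eye(3), ["a", "b", "c"])
        b = rng.normal(size=(3, 3))
        post = _gauss(rng.normal(size=3), b @ b.T + np.eye(3), ["a", "b", "c"])
        base = rd.kld_gaussian(post, prior)
        perm = [2, 0, 1]
        post_p = _gauss(
            post.mean[perm], post.cov[np.ix_(perm, perm)],
            [post.names[i] for i in perm],
        )
        prior_p = _gauss(
            prior.mean[perm], prior.cov[np.ix_(perm, perm)],
            [prior.names[i] for i in perm],
        )
        assert rd.kld_gaussian(post_p, prior_p) == pytest.approx(base, abs=1e-10)

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = rng.normal(size=(2, 2))
            b = rng.normal(size=(2, 2))
            prior = _gauss(rng.normal(size=2), a @ a.T + 0.1 * np.eye(2))
            post = _gauss(rng.normal(size=2), b @ b.T + 0.1 * np.eye(2))
            assert rd.kld_gaussian(post, prior) >= -1e-12

    def test_dimension_mismatch_and_singular_prior(self):
        with pytest.raises(rd.DesignError, match="dimension"):
            rd.kld_gaussian(_gauss([0.0], [[1.0]]), _gauss([0, 0], np.eye(2)))
        singular = _gauss([0.0, 0.0], [[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(np.linalg.LinAlgError):
            rd.kld_gaussian(_gauss([0, 0], np.eye(2)), singular)


class TestTaylorExtrapolation:
    def test_linear_model_extrapolates_exactly(self, reduced_matrices):
        # no spline block: the time-dependent part is linear in both
        # time variables, so the first-order expansion is exact
        m = reduced_matrices
        scen = rd.Scenario(label="a", t_next=2001.33)
        centerpt = TaylorCenter.from_matrices(m)
        theta = np.zeros(m.index.n_theta)
        theta[: m.index.n_beta] = np.linspace(0.1, -0.2, m.index.n_beta)
        xi = 0.05 * np.ones(m.index.n_xi)
        unit = m.units[0]
        mu_taylor = rd.taylor_mean_response(theta, xi, unit, scen, centerpt, m)
        direct = (
            float(m.fixed_row(unit[0], scen.t_next, 0.0, 0.0) @ theta[: m.index.n_beta])
            + xi[m.index.sl_gamma][0]
        )
        assert mu_taylor == pytest.approx(direct, abs=1e-12)

    def test_spline_taylor_error_is_second_order(self, full_matrices):
        # against direct evaluation of the smooth, the expansion error
        # shrinks ~ quadratically with the extrapolation step
        m = full_matrices
        centerpt = TaylorCenter.from_matrices(m)
        theta = np.zeros(m.index.n_theta)
        theta[m.index.sl_delta] = np.array([0.01, -0.02, 0.015])
        delta = theta[m.index.sl_delta]
        a = centerpt.a
        errors = []
        steps = [0.125, 0.25, 0.5]
        for dt in steps:
            x = a + dt
            taylor = float(
                (m.spline_basis(np.array([a]))[0]
                 + m.spline_basis_deriv(np.array([a]))[0] * dt) @ delta
            )
            direct = float(m.spline_basis(np.array([x]))[0] @ delta)
            errors.append(abs(taylor - direct))
        # ratio of consecutive errors ~ 4 for halved steps
        assert errors[2] / errors[1] == pytest.approx(4.0, rel=0.5)
        assert errors[1] / errors[0] == pytest.approx(4.0, rel=0.5)

    def test_next_time_must_exceed_last_survey(self, reduced_matrices):
        scen = rd.Scenario(label="bad", t_next=1990.0)
        with pytest.raises(rd.DesignError, match="exceed"):
            _taylor_fixed_row(
                reduced_matrices, "SL1", scen,
                TaylorCenter.from_matrices(reduced_matrices),
            )


class TestSimulateFutureData:
    def test_extreme_negative_logit_gives_zero_counts(self, reduced_matrices):
        m = reduced_matrices
        theta = np.zeros(m.index.n_theta)
        theta[0] = -500.0
        d = rd.Design(tuple(m.units))
        y = rd.simulate_future_data(
            d, rd.Scenario(t_next=2001.33), theta, np.zeros(m.index.n_xi),
            n=1250, seed=0, matrices=m,
        )
        assert np.all(y == 0)

    def test_binomial_mean_at_even_odds(self, reduced_matrices):
        m = reduced_matrices
        theta = np.zeros(m.index.n_theta)
        d = rd.Design(m.units[:1])
        draws = [
            rd.simulate_future_data(
                d, rd.Scenario(t_next=2001.33), theta, np.zeros(m.index.n_xi),
                n=1250, seed=s, matrices=m,
            )[0]
            for s in range(400)
        ]
        se = np.sqrt(0.25 * 1250)
        assert abs(np.mean(draws) - 625) < 3 * se / np.sqrt(400)

    def test_empty_design_returns_empty(self, reduced_matrices):
        y = rd.simulate_future_data(
            rd.Design(()), rd.Scenario(t_next=2001.33),
            np.zeros(reduced_matrices.index.n_theta),
            np.zeros(reduced_matrices.index.n_xi),
            matrices=reduced_matrices,
        )
        assert y.size == 0


@pytest.fixture(scope="module")
def reduced_joint_prior(reduced_fit):
    return rd.summarize_gaussian(reduced_fit, scope="all")


class TestExpectedUtility:
    def test_empty_design_gains_nothing(self, reduced_matrices,
                                        reduced_joint_prior):
        est = rd.expected_utility(
            rd.Design((), "empty"), rd.Scenario(t_next=2001.33),
            reduced_joint_prior, reduced_matrices, J=5, seed=1,
        )
        assert abs(est.mean) < 1e-6

    def test_common_random_numbers_reproduce_exactly(
        self, reduced_matrices, reduced_joint_prior
    ):
        d = rd.Design(reduced_matrices.units[:2])
        scen = rd.Scenario(t_next=2001.33)
        a = rd.expected_utility(d, scen, reduced_joint_prior,
                                reduced_matrices, J=10, seed=3)
        b = rd.expected_utility(d, scen, reduced_joint_prior,
                                reduced_matrices, J=10, seed=3)
        assert a.mean == b.mean and a.se == b.se

    def test_monotone_under_design_augmentation(self, reduced_matrices,
                                                reduced_joint_prior):
        # nested designs with shared substreams: more units, more gain
        scen = rd.Scenario(t_next=2001.33)
        units = reduced_matrices.units
        small = rd.expected_utility(
            rd.Design(units[:1]), scen, reduced_joint_prior,
            reduced_matrices, J=40, seed=7,
        )
        big = rd.expected_utility(
            rd.Design(units), scen, reduced_joint_prior,
            reduced_matrices, J=40, seed=7,
        )
        paired_se = np.sqrt(small.se**2 + big.se**2)
        assert big.mean >= small.mean - paired_se

    def test_theta_only_prior_mode_runs(self, reduced_matrices, reduced_fit):
        # sensitivity mode: theta-only prior with hierarchy-drawn effects
        prior_t = rd.summarize_gaussian(reduced_fit, scope="theta")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = rd.expected_utility(
                rd.Design(reduced_matrices.units), rd.Scenario(t_next=2001.33),
                prior_t, reduced_matrices, J=5, seed=2,
            )
        assert est.mean > 0

    def test_unknown_unit_rejected(self, reduced_matrices, reduced_joint_prior):
        with pytest.raises(rd.DesignError, match="not dataset units"):
            rd.expected_utility(
                rd.Design((("XX9", 1),)), rd.Scenario(t_next=2001.33),
                reduced_joint_prior, reduced_matrices, J=2, seed=0,
            )


class TestConjugateGaussianCore:
    """The generic estimator on the tractable Gaussian-Gaussian toy."""

    @staticmethod
    def _toy(m_obs, tau=1.0, sigma=1.0):
        prior = _gauss([0.0], [[tau**2]], ["theta"])

        def simulate(draw, rng):
            return draw[0] + sigma * rng.standard_normal(m_obs)

        def update(y):
            def logpost(u):
                return float(
                    -0.5 * u[0] ** 2 / tau**2
                    - 0.5 * np.sum((y - u[0]) ** 2) / sigma**2
                )

            def grad(u):
                return np.array(
                    [-u[0] / tau**2 + np.sum(y - u[0]) / sigma**2]
                )

            return rd.laplace_from_logpost(logpost, grad, np.zeros(1), ["theta"])

        return prior, simulate, update

    def test_standard_error_decays_as_root_j(self):
        # spread of independent estimates shrinks ~ J^(-1/2)
        prior, simulate, update = self._toy(3)
        js = [50, 200, 800]
        ses = []
        for J in js:
            est = rd.expected_kld_gain(prior, simulate, update, J=J, seed=10)
            ses.append(est.se)
        slope = np.polyfit(np.log(js), np.log(ses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_three_d_kld_against_monte_carlo_oracle(self):
        rng = np.random.default_rng(21)
        a = rng.normal(size=(3, 3))
        b = rng.normal(size=(3, 3))
        prior = _gauss(rng.normal(size=3), a @ a.T + np.eye(3))
        post = _gauss(rng.normal(size=3), b @ b.T + np.eye(3))
        closed = rd.kld_gaussian(post, prior)
        x = rng.multivariate_normal(post.mean, post.cov, size=400_000)
        lp = multivariate_normal.logpdf(x, post.mean, post.cov)
        lq = multivariate_normal.logpdf(x, prior.mean, prior.cov)
        mc = float(np.mean(lp - lq))
        assert closed == pytest.approx(mc, rel=0.01)
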