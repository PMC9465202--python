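"""Model layer: knots, spline basis, design matrices, likelihood."""

import numpy as np
import pytest
from scipy.stats import binom
from hypothesis import given, settings, strategies as st

import reefdesign as rd
from reefdesign.model import RankDeficiencyWarning


class TestKnotPlacement:
    def test_single_knot_is_the_median(self):
        assert rd.place_knots(np.array([0.0, 1, 2, 3, 4]), 1) == pytest.approx([2.0])

    def test_three_knots_at_quartiles(self):
        # frozen from the order-statistics linear-interpolation quantile
        # convention on {1..7} at p = 1/4, 2/4, 3/4
        knots = rd.place_knots(np.arange(1.0, 8.0), 3)
        assert knots == pytest.approx([2.5, 4.0, 5.5])

    def test_too_few_distinct_times_is_an_error(self):
        with pytest.raises(rd.ModelError, match="distinct times"):
            rd.place_knots(np.array([1.0, 2.0, 3.0]), 3)

    def test_duplicated_times_are_collapsed(self):
        knots = rd.place_knots(np.array([0.0, 1, 1, 2, 3, 4, 4]), 1)
        assert knots == pytest.approx([2.0])


class TestSplineValue:
    def test_zero_coefficients_reduce_to_a_line(self):
        x = np.linspace(-3, 3, 11)
        out = rd.spline_value(x, 0.7, -0.2, np.zeros(3), np.array([-1.0, 0.0, 1.0]))
        assert np.allclose(out, 0.7 - 0.2 * x)

    def test_value_at_the_only_knot_has_no_basis_contribution(self):
        assert rd.spline_value(0.5, 1.0, 2.0, np.array([9.9]), np.array([0.5])) == (
            pytest.approx(1.0 + 2.0 * 0.5)
        )

    def test_direct_arithmetic_example(self):
        # beta0=0, beta1=1, one knot at 0, delta=0.5, x=2: 2 + 0.5*8 = 6
        assert rd.spline_value(2.0, 0.0, 1.0, np.array([0.5]), np.array([0.0])) == (
            pytest.approx(6.0)
        )

    def test_continuity_on_a_fine_grid(self):
        knots = np.array([-1.0, 0.3, 2.0])
        delta = np.array([0.2, -0.1, 0.05])
        x = np.linspace(-3, 3, 20001)
        vals = rd.spline_value(x, 0.0, 0.0, delta, knots)
        assert np.max(np.abs(np.diff(vals))) < 1e-2


class TestDesignMatrices:
    def test_full_dataset_column_accounting(self, full_matrices):
        # intercept + time + 3 time-varying + 3 dummies + 2 ITS = 10
        assert full_matrices.X.shape == (525, 10)
        assert full_matrices.B.shape == (525, 3)
        assert len(full_matrices.units) == 21
        assert full_matrices.fixed_columns[0] == "intercept"

    def test_raw_and_standardized_bases_give_identical_mean(self, full_dataset):
        dataset, truth = full_dataset
        m_std = rd.build_design_matrices(dataset, rd.ModelConfig())
        m_raw = rd.build_design_matrices(
            dataset, rd.ModelConfig(basis_mode="raw")
        )
        theta_raw = truth.theta.copy()
        # delta_std = S delta_raw  <=>  delta_raw = S^-1 delta_std
        theta_raw[m_raw.index.sl_delta] = m_std.S_inv @ truth.theta[
            m_std.index.sl_delta
        ]
        mu_std = m_std.mu(truth.theta, truth.xi)
        mu_raw = m_raw.mu(theta_raw, truth.xi)
        assert np.max(np.abs(mu_std - mu_raw)) < 1e-8

    def test_single_reef_dummy_columns_trigger_rank_warning(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dataset, _ = rd.generate_dataset(
                rd.GeneratorConfig(reefs=("SL1",), seed=1)
            )
        with pytest.warns(RankDeficiencyWarning):
            rd.build_design_matrices(dataset, rd.ModelConfig())


class TestLinearPredictor:
    def test_all_zero_parameters_give_zero(self, reduced_matrices):
        params = rd.ParameterVector.zeros(reduced_matrices.index)
        assert rd.linear_predictor(0, params, reduced_matrices) == 0.0

    def test_single_site_effect_passes_through(self, reduced_matrices):
        params = rd.ParameterVector.zeros(reduced_matrices.index)
        rec = reduced_matrices.records.iloc[0]
        params[f"gamma_{rec['reef']}_{rec['site']}"] = 1.2
        mu = rd.linear_predictor(
            (rec["reef"], rec["site"], rec["time"]), params, reduced_matrices
        )
        assert mu == pytest.approx(1.2)

    def test_matches_hand_computed_sum(self, reduced_matrices):
        m = reduced_matrices
        params = rd.ParameterVector.zeros(m.index)
        rng = np.random.default_rng(5)
        params.theta[:] = rng.normal(scale=0.3, size=m.index.n_theta)
        params.xi[:] = rng.normal(scale=0.2, size=m.index.n_xi)
        i = 7
        expected = float(
            m.X[i] @ params.beta
            + params.xi[m.index.sl_gamma][m.site_index[i]]
        )
        assert rd.linear_predictor(i, params, m) == pytest.approx(expected)


class TestSuccessProbAndLikelihood:
    @pytest.mark.parametrize(
        "mu,pi", [(0.0, 0.5), (np.log(3), 0.75), (-np.log(3), 0.25)]
    )
    def test_logistic_values(self, mu, pi):
        assert rd.success_prob(mu) == pytest.approx(pi)

    def test_numerically_stable_at_extreme_logits(self):
        assert 0.0 <= rd.success_prob(-700.0) < 1e-200
        assert rd.success_prob(700.0) == pytest.approx(1.0)

    def test_single_bernoulli_record(self):
        import pandas as pd

        surveys = pd.DataFrame(
            [{"reef": "SL1", "site": 1, "time": 2000.0, "y": 0, "n": 1}]
        )
        covariates = pd.DataFrame(
            {"time": [2000.0], "bleaching": [1], "cyclone_hours": [0.0]}
        )
        dummies = pd.DataFrame(
            {"reef": ["SL1"], "cyclone_loc": [0], "severe_cyclone_loc": [0],
             "bleaching_loc": [0]}
        )
        ds = rd.HistoricalDataset(surveys, covariates, dummies, event_time=2000.0)
        config = rd.ModelConfig(
            smooth=False, nested_random_effects=False, covariates=(), dummies=(),
            its=False,
        )
        with pytest.warns(RankDeficiencyWarning):
            m = rd.build_design_matrices(ds, config)
        params = rd.ParameterVector.zeros(m.index)  # mu = 0 -> pi = 0.5
        assert rd.log_likelihood(m, params) == pytest.approx(np.log(0.5))

    def test_matches_independent_binomial_pmf(self, reduced_matrices):
        m = reduced_matrices
        params = rd.ParameterVector.zeros(m.index)
        rng = np.random.default_rng(2)
        params.theta[:] = rng.normal(scale=0.2, size=m.index.n_theta)
        pi = rd.success_prob(m.mu(params.theta, params.xi))
        oracle = float(np.sum(binom.logpmf(m.y, m.n, pi)))
        assert rd.log_likelihood(m, params) == pytest.approx(oracle, abs=1e-8)

    def test_additivity_over_duplicated_records(self, reduced_matrices):
        # two identical records contribute exactly twice one record's term
        m = reduced_matrices
        params = rd.ParameterVector.zeros(m.index)
        single = float(
            binom.logpmf(m.y[0], m.n[0], rd.success_prob(0.0))
        )
        pi = rd.success_prob(m.mu(params.theta, params.xi))
        total = float(np.sum(binom.logpmf(m.y, m.n, pi)))
        y2 = np.concatenate([m.y, m.y[:1]])
        n2 = np.concatenate([m.n, m.n[:1]])
        pi2 = np.concatenate([pi, pi[:1]])
        assert float(np.sum(binom.logpmf(y2, n2, pi2))) == pytest.approx(
            total + single
        )

    def test_likelihood_maximized_at_empirical_proportion(self):
        # for one record, d/dpi log pmf = 0 at pi = y/n
        y, n = 400.0, 1250.0
        pis = np.array([y / n - 1e-6, y / n, y / n + 1e-6])
        vals = binom.logpmf(y, n, pis)
        assert vals[1] >= vals[0] and vals[1] >= vals[2]


class TestParameterVector:
    def test_pack_split_round_trip_is_exact(self, reduced_matrices):
        idx = reduced_matrices.index
        rng = np.random.default_rng(0)
        pv = rd.ParameterVector(
            idx, rng.normal(size=idx.n_theta), rng.normal(size=idx.n_xi)
        )
        back = rd.ParameterVector.split(idx, pv.pack())
        assert np.array_equal(back.theta, pv.theta)
        assert np.array_equal(back.xi, pv.xi)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_name_indexing_agrees_with_packing(self, seed):
        config = rd.ModelConfig()
        idx = rd.ParameterIndex(
            config, ("SL1", "SL2"), (("SL1", 1), ("SL1", 2), ("SL2", 1))
        )
        rng = np.random.default_rng(seed)
        packed = rng.normal(size=idx.n_total)
        pv = rd.ParameterVector.split(idx, packed)
        for i, name in enumerate(idx.names):
            assert pv[name] == packed[i]

    def test_wrong_length_rejected(self, reduced_matrices):
        idx = reduced_matrices.index
        with pytest.raises(rd.ModelError):
            rd.ParameterVector(idx, np.zeros(idx.n_theta + 1), np.zeros(idx.n_xi))

    def test_reduction_to_logistic_linear_when_smooth_and_disturbances_off(
        self, reduced_matrices
    ):
        # with delta = 0 and all disturbance coefficients 0, only the
        # intercept + time trend survives: the log likelihood must equal
        # a plain logistic-linear model's, exactly
        m = reduced_matrices
        params = rd.ParameterVector.zeros(m.index)
        params["intercept"] = 0.4
        params["time"] = -0.05
        x = m.x_centered
        mu = 0.4 - 0.05 * x
        oracle = float(
            np.sum(binom.logpmf(m.y, m.n, rd.success_prob(mu)))
        )
        assert rd.log_likelihood(m, params) == pytest.approx(oracle, abs=1e-8)
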