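"""Design-stage metrics: sample size, CP/PP, expectations, timing solver.

Closed-form oracles used here were derived independently of the
implementation: the Gaussian integral for the expected conditional power
reduces to ``Phi((thetaA/k - z_{1-a}) / sqrt(1 - t + 1/t))`` and the
predictive-power analog to ``Phi(sqrt(t) (thetaA/k - z_{1-a}) / sqrt(2 - t))``
(complete the square in the normal-normal convolution); the implementation
itself integrates numerically.
"""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from dmdtrial import (
    DesignSpec,
    Metric,
    TimingQuery,
    TimingRule,
    conditional_power,
    expected_cp,
    expected_pp,
    full_information_sd,
    predictive_power,
    prob_cp_exceeds,
    prob_pp_exceeds,
    sample_size_two_proportions,
    solve_interim_time,
    z_statistic,
)
from dmdtrial.design import InvalidDesignError


def closed_form_expected_cp(t, theta_A, k, alpha):
    ratio = theta_A / k
    return norm.cdf((ratio - norm.ppf(1 - alpha)) / math.sqrt(1 - t + 1 / t))


def closed_form_expected_pp(t, theta_A, k, alpha):
    ratio = theta_A / k
    return norm.cdf(math.sqrt(t) * (ratio - norm.ppf(1 - alpha)) / math.sqrt(2 - t))


class TestSampleSize:
    @pytest.mark.parametrize(
        "pi_I, pi_C, n_expected",
        [
            (0.7, 0.4, 112),
            (0.7, 0.5, 248),
            (0.8, 0.5, 104),
            (0.8, 0.6, 218),
            (0.9, 0.6, 84),
            (0.9, 0.7, 164),
        ],
    )
    def test_standard_designs(self, pi_I, pi_C, n_expected):
        assert sample_size_two_proportions(pi_I, pi_C, 0.025, 0.9) == n_expected

    def test_zero_effect_rejected(self):
        with pytest.raises(InvalidDesignError):
            sample_size_two_proportions(0.7, 0.7, 0.025, 0.9)
        with pytest.raises(InvalidDesignError):
            sample_size_two_proportions(0.4, 0.7, 0.025, 0.9)

    def test_monotone_in_effect(self):
        # a larger separation at the same control rate needs fewer subjects
        assert sample_size_two_proportions(0.8, 0.4) < sample_size_two_proportions(0.7, 0.4)


class TestFullInformationSd:
    def test_example_design(self):
        k = full_information_sd(0.7, 0.4, 112)
        assert k == pytest.approx(math.sqrt(0.45 / 56))
        assert round(k, 2) == 0.09

    def test_hand_value(self):
        assert full_information_sd(0.7, 0.5, 248) == pytest.approx(math.sqrt(0.46 / 124))

    def test_degenerate_rates_zero_variance(self):
        assert full_information_sd(1.0, 0.0, 100) == 0.0

    def test_odd_total_rejected(self):
        with pytest.raises(ValueError):
            full_information_sd(0.7, 0.4, 111)


class TestZStatistic:
    def test_zero_estimate(self):
        assert z_statistic(0.0, 0.5, 0.09) == 0.0

    def test_full_information_is_wald(self):
        assert z_statistic(0.3, 1.0, 0.09) == pytest.approx(0.3 / 0.09)

    def test_interim_example(self):
        # interim rates 20/28 vs 11/28 with plug-in k at per-arm size 56
        g_t = 9 / 28
        k_hat = math.sqrt((20 / 28 * 8 / 28 + 11 / 28 * 17 / 28) / 56)
        assert z_statistic(g_t, 0.5, k_hat) == pytest.approx(2.556, abs=5e-3)

    def test_domain(self):
        with pytest.raises(ValueError):
            z_statistic(0.1, 0.0, 0.09)
        with pytest.raises(ValueError):
            z_statistic(0.1, 1.2, 0.09)


class TestConditionalPower:
    def test_empirical_trend_identity(self):
        # with theta' = g_t = k z_t / sqrt(t), CP is a function of z_t alone
        z_t, t, k, alpha = 1.3, 0.6, 0.09, 0.025
        theta_prime = k * z_t / math.sqrt(t)
        expected = norm.cdf((z_t / math.sqrt(t) - norm.ppf(1 - alpha)) / math.sqrt(1 - t))
        assert conditional_power(z_t, t, theta_prime, k, alpha) == pytest.approx(expected, abs=1e-12)

    def test_half_when_trend_sits_on_boundary(self):
        t, k, alpha = 0.5, 0.09, 0.025
        z_t = math.sqrt(t) * norm.ppf(1 - alpha)
        theta_prime = k * z_t / math.sqrt(t)
        assert conditional_power(z_t, t, theta_prime, k, alpha) == pytest.approx(0.5, abs=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            conditional_power(1.0, 1.0, 0.3, 0.09)

    @given(
        z=st.floats(-3, 3),
        t=st.floats(0.1, 0.9),
        theta=st.floats(-0.5, 0.5),
        k=st.floats(0.02, 0.5),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_bounds_and_monotonicity(self, z, t, theta, k):
        cp = conditional_power(z, t, theta, k)
        assert 0.0 <= cp <= 1.0
        assert conditional_power(z + 0.1, t, theta, k) > cp
        assert conditional_power(z, t, theta + 0.01, k) > cp

    def test_matches_second_stage_monte_carlo(self):
        # final-stage statistic given the interim state:
        #   Z1 | z_t ~ N(sqrt(t) z_t + theta' (1-t)/k, 1-t); reject if Z1 >= z_{1-a}
        rng = np.random.default_rng(20240917)
        n_mc = 100_000
        z_a = norm.ppf(0.975)
        for _ in range(20):
            z_t = rng.uniform(-1.5, 3.0)
            t = rng.uniform(0.2, 0.9)
            theta = rng.uniform(-0.1, 0.4)
            k = rng.uniform(0.05, 0.3)
            mean = math.sqrt(t) * z_t + theta * (1 - t) / k
            z1 = mean + math.sqrt(1 - t) * rng.standard_normal(n_mc)
            freq = float((z1 >= z_a).mean())
            se = math.sqrt(max(freq * (1 - freq), 1e-6) / n_mc)
            cp = conditional_power(z_t, t, theta, k)
            assert abs(cp - freq) <= 3 * se + 1e-4


class TestPredictivePower:
    def test_half_at_boundary(self):
        t = 0.4
        z_t = math.sqrt(t) * norm.ppf(0.975)
        assert predictive_power(z_t, t) == pytest.approx(0.5, abs=1e-12)

    @given(z=st.floats(-4, 4), t=st.floats(0.05, 0.95))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_is_shrunk_conditional_power(self, z, t):
        """PP = Phi(sqrt(t) Phi^-1(CP_empirical)): PP always tempers CP toward 1/2."""
        arg = (z / math.sqrt(t) - norm.ppf(0.975)) / math.sqrt(1 - t)
        assume(abs(arg) < 5)  # beyond ~5 SD the cdf/ppf roundtrip loses precision
        cp_emp = norm.cdf(arg)
        pp = predictive_power(z, t)
        assert pp == pytest.approx(float(norm.cdf(math.sqrt(t) * norm.ppf(cp_emp))), abs=1e-10)
        assert abs(pp - 0.5) <= abs(cp_emp - 0.5) + 1e-12
        if cp_emp != 0.5:
            assert (pp - 0.5) * (cp_emp - 0.5) >= 0

    def test_matches_flat_prior_monte_carlo(self):
        # theta ~ N(g_t, k^2/t) given the interim data, then the second stage
        rng = np.random.default_rng(7)
        n_mc = 200_000
        z_a = norm.ppf(0.975)
        for z_t, t in [(1.0, 0.3), (2.0, 0.5), (0.0, 0.7), (-0.5, 0.6)]:
            k = 0.09
            g_t = k * z_t / math.sqrt(t)
            theta = rng.normal(g_t, k / math.sqrt(t), size=n_mc)
            mean = math.sqrt(t) * z_t + theta * (1 - t) / k
            z1 = mean + math.sqrt(1 - t) * rng.standard_normal(n_mc)
            freq = float((z1 >= z_a).mean())
            se = math.sqrt(freq * (1 - freq) / n_mc) + 1e-6
            assert abs(predictive_power(z_t, t) - freq) <= 3 * se + 1e-3


class TestExpectedPower:
    def test_example_profile(self, trial_design):
        values = [
            round(expected_cp(t, trial_design.theta_A, trial_design.k), 2)
            for t in (0.5, 0.6, 0.7, 0.8, 0.9)
        ]
        assert values == [0.81, 0.83, 0.85, 0.88, 0.90]

    @pytest.mark.parametrize("fn, closed", [
        (expected_cp, closed_form_expected_cp),
        (expected_pp, closed_form_expected_pp),
    ])
    def test_quadrature_matches_closed_form(self, fn, closed):
        ts = np.linspace(0.1, 0.9, 10)
        ratios = np.linspace(0.5, 5.0, 10)
        for t in ts:
            for r in ratios:
                k = 0.09
                theta = r * k
                assert fn(t, theta, k, 0.025) == pytest.approx(
                    closed(t, theta, k, 0.025), abs=1e-6
                )

    def test_half_at_critical_ratio(self):
        # thetaA/k exactly at the critical value makes the integrand symmetric
        k = 0.1
        theta = k * norm.ppf(0.975)
        for t in (0.3, 0.5, 0.8):
            assert expected_pp(t, theta, k) == pytest.approx(0.5, abs=1e-6)

    def test_expected_pp_below_expected_cp(self):
        k = 0.09
        for t in (0.3, 0.5, 0.7, 0.9):
            for ratio in (2.5, 3.0, 4.0):
                assert expected_pp(t, ratio * k, k) < expected_cp(t, ratio * k, k)

    def test_increasing_in_effect(self):
        k = 0.09
        vals = [expected_cp(0.5, r * k, k) for r in (1.0, 2.0, 3.0, 4.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestExceedanceProbabilities:
    def test_threshold_limits(self, trial_design):
        # a vanishing threshold is always exceeded, a sure one never is;
        # convergence in the upper tail is slow (the CP quantile grows only
        # like Phi^-1(c*)), so the c* -> 1 limit is checked loosely
        args = (trial_design.theta_A, trial_design.k, trial_design.alpha)
        assert prob_cp_exceeds(0.5, 1e-30, *args) == pytest.approx(1.0, abs=1e-6)
        assert prob_cp_exceeds(0.5, 1 - 1e-12, *args) < 0.01
        assert prob_pp_exceeds(0.5, 1e-30, *args) == pytest.approx(1.0, abs=1e-6)
        assert prob_pp_exceeds(0.5, 1 - 1e-12, *args) < 0.01
        ladder = [prob_cp_exceeds(0.5, c, *args) for c in (0.01, 0.3, 0.6, 0.9, 0.99)]
        assert all(a > b for a, b in zip(ladder, ladder[1:]))

    @pytest.mark.parametrize("fn, metric", [(prob_cp_exceeds, "cp"), (prob_pp_exceeds, "pp")])
    def test_matches_numeric_inversion(self, fn, metric):
        # independent oracle: the metric is monotone in z_t, so find the
        # crossing point numerically (no algebra) and take the normal tail
        # of the interim statistic beyond it
        from scipy.optimize import brentq

        z_a = norm.ppf(0.975)
        for t in (0.3, 0.5, 0.7, 0.9):
            for c_star in (0.5, 0.7, 0.8, 0.9):
                theta, k = 0.3, 0.0896
                mu = math.sqrt(t) * theta / k

                def metric_of_z(z):
                    if metric == "cp":
                        return norm.cdf((z / math.sqrt(t) - z_a) / math.sqrt(1 - t))
                    return norm.cdf((math.sqrt(t) * z - t * z_a) / math.sqrt(t * (1 - t)))

                z_cross = brentq(lambda z: metric_of_z(z) - c_star, -50, 50, xtol=1e-13)
                val = float(norm.sf(z_cross - mu))
                assert fn(t, c_star, theta, k) == pytest.approx(val, abs=1e-10)

    def test_monotone_in_time_for_example(self, trial_design):
        probs = [
            prob_cp_exceeds(t, 0.8, trial_design.theta_A, trial_design.k)
            for t in (0.5, 0.6, 0.7, 0.8, 0.9)
        ]
        assert all(b > a for a, b in zip(probs, probs[1:]))


class TestSolveInterimTime:
    def test_expected_cp_rule(self, trial_design):
        for c_star, t_expected in [(0.8, 0.5), (0.85, 0.7), (0.9, 0.9)]:
            t = solve_interim_time(trial_design, TimingQuery(c_star=c_star))
            assert t == t_expected

    def test_singleton_grid(self, trial_design):
        q = TimingQuery(c_star=0.8, t_grid=(0.65,))
        assert solve_interim_time(trial_design, q) == 0.65

    def test_tie_breaks_to_earliest(self, trial_design):
        # duplicate grid values are exactly tied: the smaller (equal) t wins
        q = TimingQuery(c_star=0.8, t_grid=(0.5, 0.5))
        assert solve_interim_time(trial_design, q) == 0.5

    def test_exceedance_rule_runs(self, trial_design):
        q = TimingQuery(c_star=0.8, gamma=0.75, rule=TimingRule.EXCEEDANCE, metric=Metric.CP)
        t = solve_interim_time(trial_design, q)
        assert t in (0.5, 0.6, 0.7, 0.8, 0.9)
        # gamma=0.75 sits between P at t=0.5 (~0.71) and t=0.7 (~0.78)
        assert t in (0.6, 0.7)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            TimingQuery(c_star=0.8, t_grid=())


class TestDesignSpec:
    def test_derived_quantities(self, trial_design):
        assert trial_design.n_total == 112
        assert trial_design.theta_A == pytest.approx(0.3)
        assert trial_design.k == pytest.approx(0.0896, abs=5e-4)

    def test_invalid_design(self):
        with pytest.raises(InvalidDesignError):
            DesignSpec(0.4, 0.7)
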