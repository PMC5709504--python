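"""Analytic mean dynamics: ODE system, series solutions, asymptotics,
steady-state stage proportions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stagecycle import (
    HypoexpParams,
    asymptotic_law,
    exact_stage_mean,
    exact_total_mean,
    integrate_mean_ode,
    mean_ode_rhs,
    proportion_ode_rhs,
    stage_means_k4,
    stationary_proportions,
    steady_state_proportions,
    subdominant_decay_threshold,
    total_mean_infinite_k,
)
from stagecycle.meandynamics import (
    extrapolated_total_mean_limit,
    subdominant_mode_max,
)


class TestMeanOde:
    def test_single_stage_is_plain_exponential_growth(self):
        rhs = mean_ode_rhs([3.0], HypoexpParams((0.1,)))
        assert rhs[0] == pytest.approx(0.1 * 3.0)

    def test_even_distribution_gives_total_rate_m_over_c(self):
        # with M_j = M/k the total derivative collapses to M/C
        k, C, M = 4, 10.0, 8.0
        rates = HypoexpParams((k / C,) * k)
        rhs = mean_ode_rhs([M / k] * k, rates)
        assert rhs.sum() == pytest.approx(M / C)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mean_ode_rhs([1.0, 0.0], HypoexpParams((0.1,)))

    def test_numerical_integration_matches_k4_closed_forms(self):
        k, C = 4, 10.0
        ts = np.linspace(0.0, 30.0, 31)
        num = integrate_mean_ode(HypoexpParams((k / C,) * k), [1, 0, 0, 0], ts)
        np.testing.assert_allclose(num, stage_means_k4(ts, C), atol=1e-8)


class TestExactSeries:
    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_initial_condition(self, k):
        assert exact_stage_mean(0.0, 1, k, 10.0) == pytest.approx(1.0, abs=1e-12)
        for j in range(2, k + 1):
            assert exact_stage_mean(0.0, j, k, 10.0) == pytest.approx(0.0, abs=1e-12)

    def test_k4_series_matches_closed_forms(self):
        C = 10.0
        for t in (5.0, 10.0, 20.0):
            closed = stage_means_k4(t, C)
            series = [exact_stage_mean(t, j, 4, C) for j in range(1, 5)]
            np.testing.assert_allclose(series, closed, atol=1e-10)

    def test_k1_is_exponential(self):
        for t in (0.0, 3.0, 30.0):
            assert exact_stage_mean(t, 1, 1, 10.0) == pytest.approx(np.exp(t / 10.0))
            assert exact_total_mean(t, 1, 10.0) == pytest.approx(np.exp(t / 10.0))

    def test_stage_index_out_of_range(self):
        with pytest.raises(ValueError):
            exact_stage_mean(1.0, 5, 4, 10.0)

    def test_total_at_t0_is_one(self):
        for k in (1, 2, 9, 30):
            assert exact_total_mean(0.0, k, 10.0) == pytest.approx(1.0, abs=1e-9)

    def test_total_equals_sum_of_stages(self):
        k, C = 5, 10.0
        for t in (2.0, 12.0, 27.0):
            total = sum(exact_stage_mean(t, j, k, C) for j in range(1, k + 1))
            assert exact_total_mean(t, k, C) == pytest.approx(total, abs=1e-9)

    @pytest.mark.parametrize("k", [1, 2, 4, 5, 10])
    def test_total_matches_ode_integration(self, k):
        C = 10.0
        ts = np.linspace(0.0, 30.0, 16)
        num = integrate_mean_ode(
            HypoexpParams((k / C,) * k), [1] + [0] * (k - 1), ts
        ).sum(axis=1)
        exact = [exact_total_mean(t, k, C) for t in ts]
        np.testing.assert_allclose(num, exact, atol=1e-8)

    def test_multi_stage_mean_below_single_stage(self):
        # lower CCT variance slows mean growth: M_k(t) < M_1(t) for k > 1
        C = 10.0
        for k in (2, 5, 10, 20):
            for t in (1.0, 5.0, 15.0, 30.0):
                assert exact_total_mean(t, k, C) < exact_total_mean(t, 1, C)


class TestAsymptotics:
    def test_k1_recovers_unit_law(self):
        law = asymptotic_law(1)
        assert law.alpha_k == pytest.approx(1.0)
        assert law.prefactor == pytest.approx(1.0)

    def test_alpha_tends_to_ln2(self):
        assert asymptotic_law(10**6).alpha_k == pytest.approx(np.log(2), abs=1e-5)

    def test_prefactor_limit(self):
        assert round(asymptotic_law(10**6).prefactor, 3) == 0.721

    def test_alpha_strictly_decreasing(self):
        alphas = [asymptotic_law(k).alpha_k for k in range(1, 50)]
        assert np.all(np.diff(alphas) < 0)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            asymptotic_law(0)

    def test_law_evaluates_exponential(self):
        law = asymptotic_law(4)
        assert law(10.0, 10.0) == pytest.approx(law.prefactor * np.exp(law.alpha_k))


class TestSubdominantModes:
    def test_k2_mode_is_negative(self):
        # the only subdominant mode at k=2 is sqrt(2)*(-1) - 1
        assert subdominant_mode_max(2) == pytest.approx(-(1 + np.sqrt(2)))

    def test_max_attained_at_first_mode(self):
        # brute force: the slowest-decaying subdominant mode is r = 1 (= k-1)
        for k in range(3, 41):
            r = np.arange(1, k)
            re = (2 ** (1 / k) * np.exp(2j * np.pi * r / k) - 1).real
            assert np.argmax(re) in (0, k - 2)
            assert subdominant_mode_max(k) == pytest.approx(re[0])

    def test_threshold_is_28(self):
        assert subdominant_decay_threshold(40) == 28


class TestInfiniteKLimits:
    def test_integer_time_coefficient_three_quarters(self):
        lim = extrapolated_total_mean_limit(1.0)
        assert lim == pytest.approx(0.75 * 2.0, rel=0.01)

    def test_floor_law_at_non_integer_time(self):
        # at t/C = 1.5 the mean approaches 2^floor(1.5) = 2
        assert exact_total_mean(1.5, 10**4, 1.0) == pytest.approx(
            total_mean_infinite_k(1.5, 1.0), rel=0.02
        )

    def test_floor_law_values(self):
        assert total_mean_infinite_k(0.4, 1.0) == 1.0
        assert total_mean_infinite_k(2.7, 1.0) == 4.0
        assert total_mean_infinite_k(2.0, 1.0) == 3.0  # (3/4) * 4


class TestSteadyStateProportions:
    def test_k1_trivial(self):
        np.testing.assert_array_equal(steady_state_proportions(1), [1.0])

    @given(st.integers(min_value=1, max_value=200))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_sum_to_one_and_decreasing(self, k):
        p = steady_state_proportions(k)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(np.diff(p) < 0) or k == 1

    def test_recurrence_fixed_point(self):
        # Mhat_1 = 2 Mhat_k/(1 + Mhat_k); Mhat_j = Mhat_{j-1}/(1 + Mhat_k)
        p = steady_state_proportions(6)
        mk = p[-1]
        assert p[0] == pytest.approx(2 * mk / (1 + mk), abs=1e-12)
        np.testing.assert_allclose(p[1:], p[:-1] / (1 + mk), atol=1e-12)

    def test_first_to_last_ratio_tends_to_two(self):
        p = steady_state_proportions(10**6)
        assert p[0] / p[-1] == pytest.approx(2.0, abs=1e-5)

    def test_matches_general_rate_eigenvector(self):
        k, C = 5, 10.0
        p = stationary_proportions(HypoexpParams((k / C,) * k))
        np.testing.assert_allclose(p, steady_state_proportions(k), atol=1e-10)


class TestProportionOde:
    def test_rejects_unnormalised_input(self):
        with pytest.raises(ValueError):
            proportion_ode_rhs([0.5, 0.3], 0.5)

    def test_k1_stationary(self):
        assert proportion_ode_rhs([1.0], 0.7)[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 5, 9])
    def test_steady_state_is_fixed_point(self, k):
        rhs = proportion_ode_rhs(steady_state_proportions(k), 0.5)
        assert np.max(np.abs(rhs)) < 1e-10

    @given(st.integers(min_value=1, max_value=12), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_conservation_on_simplex(self, k, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(k))
        assert abs(proportion_ode_rhs(p, 0.5).sum()) < 1e-12

    def test_long_time_integration_converges_to_closed_form(self):
        from scipy.integrate import solve_ivp

        k, lam1 = 5, 0.5
        sol = solve_ivp(
            lambda _t, y: proportion_ode_rhs(y, lam1),
            (0.0, 400.0),
            np.full(k, 1.0 / k),
            rtol=1e-12,
            atol=1e-14,
            method="DOP853",
        )
        np.testing.assert_allclose(
            sol.y[:, -1], steady_state_proportions(k), atol=1e-8
        )

    def test_proportions_not_proportional_to_durations_for_unequal_rates(self):
        # random partition of C into 5 stage means: the stationary stage
        # occupancy is NOT the normalised stage durations
        rng = np.random.default_rng(42)
        C, k = 10.0, 5
        cuts = np.sort(rng.uniform(0, C, k - 1))
        mu = np.diff(np.concatenate([[0.0], cuts, [C]]))
        rates = HypoexpParams(tuple(1.0 / mu))
        stat = stationary_proportions(rates)
        assert np.max(np.abs(stat - mu / mu.sum())) > 0.01
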