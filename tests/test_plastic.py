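"""Plastic (resource-synchronized) strategies vs constant strategies."""

import math

import numpy as np
import pytest

from broodopt import (LifeHistory, ResourceModel, annual_growth_rate,
                      lyapunov_env_constant, lyapunov_env_plastic, optimal_cv,
                      optimal_constant_brood, optimal_constant_brood_env,
                      per_year_optimal_brood, simulate_strategy_trajectories)
from conftest import grid_refine_argmax


class TestPerYearOptimalBrood:
    def test_zero_cost_closed_form(self, baseline_lh):
        for X in (0.05, 0.3, 1.2):
            assert per_year_optimal_brood(X, baseline_lh) == pytest.approx(
                X / (0.2 * 0.99), rel=1e-10)

    def test_poor_years_give_zero_brood_under_high_cost(self, baseline_lh):
        """When the marginal adult cost of the first offspring exceeds its
        survival prospects (alpha (1-muA0) >= 1), poor years shut down
        reproduction entirely."""
        lh = baseline_lh.with_alpha(1.5)
        assert per_year_optimal_brood(1e-4, lh) == 0.0
        # below that cost the optimum merely shrinks toward zero
        lh_low = baseline_lh.with_alpha(0.8)
        assert 0 < per_year_optimal_brood(1e-4, lh_low) < 1e-3

    def test_matches_grid_oracle_on_random_inputs(self, baseline_lh):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            X = float(rng.uniform(0.02, 1.5))
            alpha = float(rng.uniform(0.0, 2.0))
            lh = baseline_lh.with_alpha(alpha)
            b = per_year_optimal_brood(X, lh)
            hi = 3 * X / (0.2 * 0.99)
            b_ref, g_ref = grid_refine_argmax(
                lambda bb: annual_growth_rate(bb, lh, X), 0.0, hi, step=hi / 4000)
            assert annual_growth_rate(b, lh, X) == pytest.approx(g_ref, abs=1e-8)
            assert b == pytest.approx(b_ref, abs=1e-4)


class TestLyapunovEnvPlastic:
    def test_cv_zero_equals_deterministic_optimum(self, baseline_lh):
        for alpha in (0.0, 1.0):
            lh = baseline_lh.with_alpha(alpha)
            plastic = lyapunov_env_plastic(lh, ResourceModel(0.5, 0.0))
            det = optimal_constant_brood(lh).growth_rate
            assert plastic == pytest.approx(det, abs=1e-10)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0, 2.0])
    @pytest.mark.parametrize("cv", [0.25, 1.0, 2.0])
    def test_dominates_best_constant_strategy(self, baseline_lh, alpha, cv):
        """Synchronizing to the resource always beats any fixed brood size."""
        lh = baseline_lh.with_alpha(alpha)
        env = ResourceModel(0.5, cv)
        plastic = lyapunov_env_plastic(lh, env)
        const = optimal_constant_brood_env(lh, env)
        assert plastic >= const.growth_rate - 1e-9

    def test_zero_cost_growth_decreasing_in_cv(self, baseline_lh):
        vals = [lyapunov_env_plastic(baseline_lh, ResourceModel(0.5, cv))
                for cv in (0.0, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_optimized_log_growth_convex_in_log_resource_at_high_cost(self, baseline_lh):
        """The Jensen mechanism: with costly broods, the per-year optimized
        log growth is convex in log resource, so variability can pay."""
        lh = baseline_lh.with_alpha(1.5)
        z = np.linspace(math.log(0.05), math.log(2.0), 40)
        g = np.array([math.log(annual_growth_rate(
            per_year_optimal_brood(math.exp(zz), lh), lh, math.exp(zz)))
            for zz in z])
        assert np.all(np.diff(g, 2) > -1e-8)


class TestOptimalCv:
    def test_constant_world_best_without_brood_cost(self, baseline_lh):
        best_cv, growth = optimal_cv(baseline_lh, cv_range=(0.0, 2.0))
        assert best_cv == 0.0
        assert growth == pytest.approx(optimal_constant_brood(baseline_lh).growth_rate)

    def test_variable_world_best_at_high_brood_cost(self, baseline_lh):
        best_cv, growth = optimal_cv(baseline_lh.with_alpha(1.0))
        assert best_cv > 0.0
        assert growth > lyapunov_env_plastic(
            baseline_lh.with_alpha(1.0), ResourceModel(0.5, 0.0))

    def test_longer_lived_adults_prefer_more_variation(self):
        """Lower intrinsic adult mortality shifts the optimal CV upward."""
        hi_mort = LifeHistory.from_values(muA0=0.07, alpha=1.0)
        lo_mort = LifeHistory.from_values(muA0=0.03, alpha=1.0)
        cv_hi, _ = optimal_cv(hi_mort)
        cv_lo, _ = optimal_cv(lo_mort)
        assert cv_lo > cv_hi


class TestStrategyTrajectories:
    def test_reproducible_and_paired(self, baseline_lh):
        env = ResourceModel(0.5, 1.0)
        p1, c1 = simulate_strategy_trajectories(baseline_lh, env, 50, seed=21)
        p2, c2 = simulate_strategy_trajectories(baseline_lh, env, 50, seed=21)
        np.testing.assert_array_equal(p1.log_population, p2.log_population)
        np.testing.assert_array_equal(p1.resource, c1.resource)
        assert p1.strategy == "plastic" and c1.strategy == "constant"
        # plastic broods re-optimized every year, constant brood fixed
        assert np.unique(c1.brood).size == 1
        assert np.unique(p1.brood).size > 1

    def test_long_run_growth_matches_quadrature(self, baseline_lh):
        """Monte-Carlo time average vs the plastic Lyapunov integral."""
        lh = baseline_lh.with_alpha(1.0)
        env = ResourceModel(0.5, 1.0)
        plastic, _ = simulate_strategy_trajectories(lh, env, 30_000, seed=4)
        log_steps = plastic.annual_log_growth
        se = log_steps.std(ddof=1) / math.sqrt(log_steps.size)
        analytic = math.log(lyapunov_env_plastic(lh, env))
        assert abs(plastic.mean_log_growth - analytic) < 3 * se

    def test_plastic_grows_where_constant_declines(self, baseline_lh):
        """At high brood cost and CV=1 the plastic population grows while the
        best constant strategy declines."""
        lh = baseline_lh.with_alpha(1.5)
        env = ResourceModel(0.5, 1.0)
        assert lyapunov_env_plastic(lh, env) > 1.0
        assert optimal_constant_brood_env(lh, env).growth_rate < 1.0
        plastic, constant = simulate_strategy_trajectories(lh, env, 20_000, seed=8)
        assert plastic.mean_log_growth > 0
        assert constant.mean_log_growth < 0
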