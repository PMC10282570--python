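"""Poisson individual variation: analytic Lyapunov rate vs simulators."""

import math

import numpy as np
import pytest

from broodopt import (LifeHistory, StochasticRunConfig, annual_growth_rate,
                      arithmetic_mean_growth_poisson, lyapunov_poisson,
                      optimal_constant_brood, optimal_mean_brood_individual,
                      simulate_annual_draw_map, simulate_branching)


class TestLyapunovPoisson:
    def test_degenerate_zero_mean_is_pure_survival(self, baseline_lh):
        assert lyapunov_poisson(0.0, baseline_lh) == pytest.approx(0.93)

    def test_below_deterministic_growth(self, baseline_lh):
        """Variation in brood size always costs the population (geometric
        vs arithmetic averaging of annual growth)."""
        det = annual_growth_rate(2.0, baseline_lh)
        assert lyapunov_poisson(2.0, baseline_lh) < det

    def test_truncation_converged(self, baseline_lh):
        a = lyapunov_poisson(2.0, baseline_lh.with_alpha(0.3), tail_tol=1e-10)
        b = lyapunov_poisson(2.0, baseline_lh.with_alpha(0.3), tail_tol=1e-12)
        assert abs(a - b) < 1e-9

    @pytest.mark.parametrize("mean_brood", [0.5, 2.0, 5.0])
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.5])
    def test_jensen_bound(self, baseline_lh, mean_brood, alpha):
        lh = baseline_lh.with_alpha(alpha)
        geo = lyapunov_poisson(mean_brood, lh)
        ari = arithmetic_mean_growth_poisson(mean_brood, lh)
        assert geo <= ari + 1e-12


class TestAnnualDrawMap:
    def test_deterministic_under_seed(self, baseline_lh):
        cfg = StochasticRunConfig(100, 50, 3, seed=11)
        a = simulate_annual_draw_map(2.0, baseline_lh, cfg)
        b = simulate_annual_draw_map(2.0, baseline_lh, cfg)
        np.testing.assert_array_equal(a.population, b.population)

    def test_long_run_matches_analytic_lyapunov(self, baseline_lh):
        """Time-average log growth converges to the Poisson-weighted sum."""
        lh = baseline_lh.with_alpha(0.3)
        cfg = StochasticRunConfig(100, 200_000, 1, seed=7)
        res = simulate_annual_draw_map(2.0, lh, cfg)
        analytic = math.log(lyapunov_poisson(2.0, lh))
        assert abs(res.log_growth_mean - analytic) < 3 * res.log_growth_se

    def test_decline_at_near_certain_adult_death(self):
        lh = LifeHistory.from_values(muA0=0.99)
        cfg = StochasticRunConfig(100, 50, 1, seed=0)
        res = simulate_annual_draw_map(0.0, lh, cfg)
        assert res.growth_rate == pytest.approx(0.01, rel=1e-9)


class TestBranchingProcess:
    def test_survival_fraction_without_reproduction(self, baseline_lh):
        cfg = StochasticRunConfig(100_000, 1, 1, seed=5)
        res = simulate_branching(0.0, baseline_lh, cfg)
        frac = res.population[0, 1] / res.population[0, 0]
        se = math.sqrt(0.93 * 0.07 / 100_000)
        assert abs(frac - 0.93) < 3 * se

    def test_one_generation_matches_arithmetic_expectation(self, baseline_lh):
        """Law of large numbers: realized one-year growth at large N matches
        the Poisson-weighted arithmetic mean of the kernel."""
        lh = baseline_lh.with_alpha(0.3)
        cfg = StochasticRunConfig(100_000, 1, 1, seed=9)
        res = simulate_branching(2.0, lh, cfg)
        expected = arithmetic_mean_growth_poisson(2.0, lh)
        growth = res.population[0, 1] / res.population[0, 0]
        # conservative binomial-style error bound on the mean contribution
        se = 3.0 / math.sqrt(100_000)
        assert abs(growth - expected) < 3 * se

    def test_counts_are_integers_and_truncate_at_extinction(self):
        lh = LifeHistory.from_values(muA0=0.9, alpha=2.0)
        cfg = StochasticRunConfig(5, 40, 20, seed=13)
        res = simulate_branching(0.2, lh, cfg)
        assert np.all(res.population == np.round(res.population))
        assert np.all(res.population >= 0)
        assert res.extinct_fraction > 0
        # once a replicate hits zero it stays at zero
        for row in res.population:
            zeros = np.where(row == 0)[0]
            if zeros.size:
                assert np.all(row[zeros[0]:] == 0)

    def test_mean_trajectory_tracks_annual_draw_map(self, baseline_lh):
        """Replicate-averaged branching and annual-draw trajectories share the
        same expected growth, so their mean-trajectory log slopes agree."""
        lh = baseline_lh.with_alpha(0.3)
        branch = simulate_branching(2.0, lh, StochasticRunConfig(20, 25, 30, seed=3))
        annual = simulate_annual_draw_map(2.0, lh, StochasticRunConfig(20, 25, 100, seed=3))
        g_branch = math.log(branch.population.mean(0)[-1]
                            / branch.population.mean(0)[0]) / 25
        g_annual = math.log(annual.population.mean(0)[-1]
                            / annual.population.mean(0)[0]) / 25
        assert abs(g_branch - g_annual) / abs(g_annual) < 0.05


class TestOptimalMeanBrood:
    def test_high_cost_favours_no_offspring(self, baseline_lh):
        opt = optimal_mean_brood_individual(baseline_lh.with_alpha(3.0))
        assert opt.brood_size == 0.0

    def test_zero_cost_optimum_matches_grid_oracle(self, baseline_lh):
        from conftest import grid_refine_argmax
        opt = optimal_mean_brood_individual(baseline_lh)
        b_ref, _ = grid_refine_argmax(
            lambda b: lyapunov_poisson(b, baseline_lh), 0.0, 10.0, step=0.01)
        assert opt.brood_size == pytest.approx(b_ref, abs=1e-3)

    def test_switch_to_zero_at_lower_cost_than_deterministic(self, baseline_lh):
        """Individual variation makes reproduction give out at a smaller brood
        cost than in the deterministic model."""

        def switch(opt_fn):
            lo, hi = 0.0, 4.0
            for _ in range(12):
                mid = 0.5 * (lo + hi)
                if opt_fn(mid) > 0:
                    lo = mid
                else:
                    hi = mid
            return hi

        det = switch(lambda a: optimal_constant_brood(
            baseline_lh.with_alpha(a)).brood_size)
        ind = switch(lambda a: optimal_mean_brood_individual(
            baseline_lh.with_alpha(a)).brood_size)
        assert ind < det
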