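"""Two-environment translocation thought experiment.

Two species with identical baseline rates are matched so their long-run
growth is equal: a "masting" species in a two-state world (good years with
probability p_good: fast juvenile growth and no brood cost; bad years: slow
growth, high brood cost) using the per-state optimal broods, and a
"constant-world" species whose single brood cost alpha is solved so that its
optimal growth equals the masting species' overall (geometric-mean) growth.
Swapping their environments — each keeping its evolved strategy — lets the
model quantify the demographic cost of translocation or environmental
change; across the whole (resource-ratio, masting-frequency) plane the move
never helps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .deterministic import annual_growth_rate, optimal_constant_brood
from .params import BroodOptimum, LifeHistory

#: solver tolerance on the growth-matching alpha
_ALPHA_XTOL = 1e-10


@dataclass(frozen=True)
class TwoStateEnvironment:
    """IID two-state masting world: good years vs bad years."""

    p_good: float
    r_good: float
    r_bad: float
    alpha_good: float = 0.0
    alpha_bad: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.p_good <= 1:
            raise ValueError(f"p_good must lie in [0, 1], got {self.p_good}")
        if not self.r_good >= self.r_bad > 0:
            raise ValueError("need r_good >= r_bad > 0")
        if self.alpha_good < 0 or self.alpha_bad < 0:
            raise ValueError("brood cost alphas must be non-negative")


@dataclass
class CaseStudyResult:
    """Full translocation analysis for one parameter set."""

    good_optimum: BroodOptimum
    bad_optimum: BroodOptimum
    masting_baseline_growth: float
    matched_alpha: float
    constant_optimum: BroodOptimum
    constant_baseline_growth: float
    r_const: float
    masting_to_constant_growth: float
    masting_to_constant_pct: float
    constant_to_masting_growth: float
    constant_to_masting_pct: float


def geometric_mean_growth(states: list[tuple[float, float]]) -> float:
    """Probability-weighted geometric mean exp(sum p_i ln R_i).

    The Lyapunov-consistent long-run growth rate for IID multiplicative
    year-to-year dynamics; always at most the arithmetic mean.
    """
    total_p = sum(p for p, _ in states)
    if not math.isclose(total_p, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"state probabilities must sum to 1, got {total_p}")
    acc = 0.0
    for p, R in states:
        if R <= 0:
            raise ValueError(f"growth rates must be positive, got {R}")
        if p > 0:
            acc += p * math.log(R)
    return math.exp(acc)


def _base_lh(muA0: float, muJ: float, L0: float, alpha: float) -> LifeHistory:
    return LifeHistory.from_values(r0=1.0, muJ=muJ, L0=L0, muA0=muA0,
                                   alpha=alpha)


def masting_species_strategy(env: TwoStateEnvironment, muA0: float,
                             muJ: float, L0: float
                             ) -> tuple[BroodOptimum, BroodOptimum, float]:
    """Per-state optimal broods and the overall geometric-mean growth.

    The masting species evolves a distinct optimal brood for each year type
    (it perceives the environmental cue perfectly); the overall growth
    weights the per-state optimal growth rates by the year-type frequencies.
    """
    good = optimal_constant_brood(_base_lh(muA0, muJ, L0, env.alpha_good),
                                  r=env.r_good)
    bad = optimal_constant_brood(_base_lh(muA0, muJ, L0, env.alpha_bad),
                                 r=env.r_bad)
    overall = geometric_mean_growth([(env.p_good, good.growth_rate),
                                     (1.0 - env.p_good, bad.growth_rate)])
    return good, bad, overall


def match_alpha_constant(target_growth: float, r_const: float, muA0: float,
                         muJ: float, L0: float, alpha_max: float = 50.0
                         ) -> tuple[float, BroodOptimum]:
    """Brood cost alpha at which the constant-world optimal growth hits a target.

    The optimal growth is continuous and strictly decreasing in alpha on the
    interior branch, from its alpha = 0 maximum down to the zero-brood floor
    1 - muA0, so the match is a bracketed root.  Raises when the target lies
    outside that achievable range.
    """

    def opt_growth(alpha: float) -> float:
        return optimal_constant_brood(_base_lh(muA0, muJ, L0, alpha),
                                      r=r_const).growth_rate

    g0 = opt_growth(0.0)
    floor = 1.0 - muA0
    if target_growth > g0 + 1e-12:
        raise ValueError(f"target growth {target_growth:.6g} exceeds the "
                         f"alpha=0 optimum {g0:.6g}: infeasible")
    if target_growth <= floor:
        raise ValueError(f"target growth {target_growth:.6g} is at or below "
                         f"the no-reproduction floor {floor:.6g}: infeasible")
    if math.isclose(target_growth, g0, rel_tol=0, abs_tol=1e-12):
        return 0.0, optimal_constant_brood(_base_lh(muA0, muJ, L0, 0.0),
                                           r=r_const)
    alpha = brentq(lambda a: opt_growth(a) - target_growth, 0.0, alpha_max,
                   xtol=_ALPHA_XTOL)
    return float(alpha), optimal_constant_brood(
        _base_lh(muA0, muJ, L0, float(alpha)), r=r_const)


def translocate_masting_to_constant(env: TwoStateEnvironment,
                                    matched_alpha: float, r_const: float,
                                    muA0: float, muJ: float, L0: float,
                                    baseline_growth: float
                                    ) -> tuple[float, float]:
    """Masting species moved to the constant world, cue-switching blindly.

    It keeps alternating its evolved good/bad-year broods with the same
    probabilities, but every year now delivers the constant world's resource
    level and brood cost.  Returns (growth, % change vs baseline).
    """
    good, bad, _ = masting_species_strategy(env, muA0, muJ, L0)
    lh = _base_lh(muA0, muJ, L0, matched_alpha)
    R_good = annual_growth_rate(good.brood_size, lh, r_const)
    R_bad = annual_growth_rate(bad.brood_size, lh, r_const)
    growth = geometric_mean_growth([(env.p_good, R_good),
                                    (1.0 - env.p_good, R_bad)])
    return growth, 100.0 * (growth / baseline_growth - 1.0)


def translocate_constant_to_masting(env: TwoStateEnvironment,
                                    constant_brood: float, muA0: float,
                                    muJ: float, L0: float,
                                    baseline_growth: float
                                    ) -> tuple[float, float]:
    """Constant-world species moved to the masting world, cue-blind.

    It keeps its single evolved brood size every year while experiencing the
    masting world's fluctuating growth rates and brood costs.  Returns
    (growth, % change vs baseline).
    """
    R_good = annual_growth_rate(constant_brood,
                                _base_lh(muA0, muJ, L0, env.alpha_good),
                                env.r_good)
    R_bad = annual_growth_rate(constant_brood,
                               _base_lh(muA0, muJ, L0, env.alpha_bad),
                               env.r_bad)
    growth = geometric_mean_growth([(env.p_good, R_good),
                                    (1.0 - env.p_good, R_bad)])
    return growth, 100.0 * (growth / baseline_growth - 1.0)


def run_case_study(env: TwoStateEnvironment, muA0: float = 0.1,
                   muJ: float = 0.1, L0: float = 0.01) -> CaseStudyResult:
    """Full pipeline: per-state optima, alpha matching, both translocations."""
    good, bad, baseline = masting_species_strategy(env, muA0, muJ, L0)
    r_const = env.p_good * env.r_good + (1.0 - env.p_good) * env.r_bad
    alpha, const_opt = match_alpha_constant(baseline, r_const, muA0, muJ, L0)
    m2c_growth, m2c_pct = translocate_masting_to_constant(
        env, alpha, r_const, muA0, muJ, L0, baseline)
    c2m_growth, c2m_pct = translocate_constant_to_masting(
        env, const_opt.brood_size, muA0, muJ, L0, baseline)
    return CaseStudyResult(
        good_optimum=good,
        bad_optimum=bad,
        masting_baseline_growth=baseline,
        matched_alpha=alpha,
        constant_optimum=const_opt,
        constant_baseline_growth=const_opt.growth_rate,
        r_const=r_const,
        masting_to_constant_growth=m2c_growth,
        masting_to_constant_pct=m2c_pct,
        constant_to_masting_growth=c2m_growth,
        constant_to_masting_pct=c2m_pct,
    )


def sweep_translocation_grid(r_ratios, p_goods, r_bad: float = 0.05,
                             alpha_good: float = 0.0, alpha_bad: float = 0.5,
                             muA0: float = 0.1, muJ: float = 0.1,
                             L0: float = 0.01
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage-change surfaces for both translocation directions.

    Rows are r_good/r_bad ratios, columns masting frequencies p_good.  Cells
    where the growth-matching alpha is infeasible (the masting baseline
    growth at or below the no-reproduction floor) are NaN, never fabricated.
    Returns (constant->masting, masting->constant) DataFrames.
    """
    r_ratios = np.asarray(r_ratios, dtype=float)
    p_goods = np.asarray(p_goods, dtype=float)
    if np.any(r_ratios < 1):
        raise ValueError("r_good/r_bad ratios must be >= 1")
    c2m = np.full((r_ratios.size, p_goods.size), np.nan)
    m2c = np.full_like(c2m, np.nan)
    for i, ratio in enumerate(r_ratios):
        for jj, p in enumerate(p_goods):
            env = TwoStateEnvironment(p_good=float(p),
                                      r_good=float(ratio * r_bad),
                                      r_bad=r_bad, alpha_good=alpha_good,
                                      alpha_bad=alpha_bad)
            try:
                res = run_case_study(env, muA0, muJ, L0)
            except ValueError:
                continue
            c2m[i, jj] = res.constant_to_masting_pct
            m2c[i, jj] = res.masting_to_constant_pct
    index = pd.Index(r_ratios, name="r_good_over_r_bad")
    cols = pd.Index(p_goods, name="p_good")
    return (pd.DataFrame(c2m, index=index, columns=cols),
            pd.DataFrame(m2c, index=index, columns=cols))
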