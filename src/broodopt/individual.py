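"""Individual (demographic) stochasticity: Poisson brood-size variation.

Three routes to the population growth rate when each adult's brood is a
Poisson draw with mean B0:

* ``lyapunov_poisson`` — the analytic Lyapunov exponent of the approximating
  stochastic linear map: exp of the Poisson-weighted mean of the log annual
  growth kernel.  By Jensen's inequality this never exceeds the arithmetic
  mean growth, so individual variation always costs the population.
* ``simulate_annual_draw_map`` — Monte-Carlo of that map: one shared Poisson
  brood per year multiplies the whole population.
* ``simulate_branching`` — the exact individual-based branching process:
  per-adult Poisson broods, per-adult survival, per-juvenile survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._optim import find_brood_optimum
from .deterministic import annual_growth_rate, default_search_max
from .params import BroodOptimum, LifeHistory


@dataclass(frozen=True)
class StochasticRunConfig:
    """Replication control for the stochastic simulators."""

    n_individuals: int = 100
    n_years: int = 200
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_years <= 0 or self.n_replicates <= 0:
            raise ValueError("n_individuals, n_years and n_replicates must be positive")


@dataclass
class SimulationResult:
    """Growth-rate estimate and trajectories from a stochastic simulator.

    ``growth_rate`` is the Lyapunov-style geometric estimate
    exp(mean log(N_{G+1}/N_G)); ``arithmetic_growth`` is the plain mean of
    annual ratios, reported for diagnostics.  ``log_growth_se`` is the
    standard error of the mean log annual growth.
    """

    growth_rate: float
    log_growth_mean: float
    log_growth_se: float
    arithmetic_growth: float
    population: np.ndarray  # shape (n_replicates, n_years + 1)
    extinct_fraction: float = 0.0
    seed: int = 0
    replicate_seeds: list[int] = field(default_factory=list)


def poisson_truncation(mean_brood: float, tail_tol: float = 1e-12) -> int:
    """Smallest j_max whose Poisson upper-tail mass is below tail_tol."""
    if mean_brood == 0:
        return 0
    j = int(stats.poisson.isf(tail_tol, mean_brood))
    while stats.poisson.sf(j, mean_brood) >= tail_tol:
        j += 1
    return j


def lyapunov_poisson(mean_brood: float, lh: LifeHistory,
                     tail_tol: float = 1e-12) -> float:
    """Lyapunov growth rate under IID Poisson annual brood draws.

    exp( sum_j log R0(j) f(j) ) with f the Poisson(mean_brood) pmf and R0
    the deterministic annual-growth kernel; the sum is truncated where the
    upper tail mass drops below ``tail_tol``.  The kernel at j = 0 is
    1 - muA0 > 0, so the log is always finite.
    """
    if mean_brood < 0:
        raise ValueError("mean brood size must be non-negative")
    if mean_brood == 0:
        return 1.0 - lh.adult.muA0
    j_max = poisson_truncation(mean_brood, tail_tol)
    j = np.arange(j_max + 1)
    weights = stats.poisson.pmf(j, mean_brood)
    log_growth = np.log(annual_growth_rate(j.astype(float), lh))
    return float(np.exp(np.sum(weights * log_growth)))


def arithmetic_mean_growth_poisson(mean_brood: float, lh: LifeHistory,
                                   tail_tol: float = 1e-12) -> float:
    """Poisson-weighted arithmetic mean of the annual growth kernel.

    This is the expected one-step growth of the branching process at large
    population size; it upper-bounds the Lyapunov rate (Jensen).
    """
    if mean_brood == 0:
        return 1.0 - lh.adult.muA0
    j_max = poisson_truncation(mean_brood, tail_tol)
    j = np.arange(j_max + 1)
    weights = stats.poisson.pmf(j, mean_brood)
    return float(np.sum(weights * annual_growth_rate(j.astype(float), lh)))


def _summarize(log_states: np.ndarray, seed: int,
               replicate_seeds: list[int], valid: np.ndarray | None = None,
               extinct_fraction: float = 0.0) -> SimulationResult:
    """Build a SimulationResult from per-replicate log-population paths."""
    with np.errstate(invalid="ignore"):  # -inf rows from extinct replicates
        log_steps = np.diff(log_states, axis=1)
    if valid is None:
        steps = log_steps.ravel()
    else:
        steps = log_steps[valid]
    mean = float(np.mean(steps))
    se = float(np.std(steps, ddof=1) / np.sqrt(steps.size)) if steps.size > 1 else np.nan
    with np.errstate(over="ignore"):
        population = np.exp(log_states)
    return SimulationResult(
        growth_rate=float(np.exp(mean)),
        log_growth_mean=mean,
        log_growth_se=se,
        arithmetic_growth=float(np.mean(np.exp(steps))),
        population=population,
        extinct_fraction=extinct_fraction,
        seed=seed,
        replicate_seeds=replicate_seeds,
    )


def simulate_annual_draw_map(mean_brood: float, lh: LifeHistory,
                             cfg: StochasticRunConfig) -> SimulationResult:
    """Monte-Carlo of the approximating stochastic linear map.

    Each year one Poisson brood size j is drawn for the whole population and
    the population is multiplied by the annual growth kernel at B0 = j.
    Internally evolved in log space, so arbitrarily long declines do not
    underflow; the time-average log growth converges to ``lyapunov_poisson``.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_replicates)
    replicate_seeds = [int(c.generate_state(1)[0] % 2**31) for c in children]

    log_states = np.empty((cfg.n_replicates, cfg.n_years + 1))
    log_states[:, 0] = np.log(cfg.n_individuals)
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        j = rng.poisson(mean_brood, size=cfg.n_years).astype(float)
        log_r = np.log(annual_growth_rate(j, lh))
        log_states[rep, 1:] = log_states[rep, 0] + np.cumsum(log_r)
    return _summarize(log_states, cfg.seed, replicate_seeds)


def simulate_branching(mean_brood: float, lh: LifeHistory,
                       cfg: StochasticRunConfig) -> SimulationResult:
    """Exact individual-based branching process.

    Per adult: brood j ~ Poisson(mean_brood); the adult survives the interval
    with probability (1 - muA0) exp(-alpha j); each of its j offspring
    independently reaches maturity with probability
    exp(-muJ j (1 - L0) / r0).  Next year's adults are the surviving adults
    plus matured offspring.  Replicates that go extinct contribute their
    pre-extinction years only.
    """
    ju, ad = lh.juvenile, lh.adult
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_replicates)
    replicate_seeds = [int(c.generate_state(1)[0] % 2**31) for c in children]

    counts = np.zeros((cfg.n_replicates, cfg.n_years + 1), dtype=np.int64)
    counts[:, 0] = cfg.n_individuals
    n_extinct = 0
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        n = cfg.n_individuals
        for year in range(cfg.n_years):
            if n == 0:
                n_extinct += 1
                break
            j = rng.poisson(mean_brood, size=n)
            p_adult = (1.0 - ad.muA0) * np.exp(-ad.alpha * j)
            survivors = int(np.sum(rng.random(n) < p_adult))
            p_juv = np.exp(-ju.muJ * j * (1.0 - ju.L0) / ju.r0)
            matured = int(np.sum(rng.binomial(j, p_juv)))
            n = survivors + matured
            counts[rep, year + 1] = n

    with np.errstate(divide="ignore"):
        log_states = np.log(counts.astype(float))
    valid = (counts[:, 1:] > 0) & (counts[:, :-1] > 0)
    result = _summarize(log_states, cfg.seed, replicate_seeds, valid=valid,
                        extinct_fraction=n_extinct / cfg.n_replicates)
    result.population = counts.astype(float)
    return result


def optimal_mean_brood_individual(lh: LifeHistory,
                                  search_max: float | None = None,
                                  tail_tol: float = 1e-12) -> BroodOptimum:
    """Mean brood size maximizing the Poisson Lyapunov growth rate."""
    if search_max is None:
        search_max = default_search_max(lh)
    return find_brood_optimum(
        lambda b: lyapunov_poisson(b, lh, tail_tol), search_max)
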