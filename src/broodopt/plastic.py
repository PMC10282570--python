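"""Plastic (resource-synchronized) brood strategies.

A plastic breeder observes each year's resource level X and uses the brood
size that maximizes that year's growth kernel; in sufficiently poor years
(with any brood cost) the optimum is zero and the adult sits the year out.
Because the per-year-optimized kernel dominates the kernel at any fixed
brood pointwise in X, the plastic Lyapunov growth rate is at least the best
constant-strategy rate at every (alpha, CV).  When brood cost is high
enough, a variable world plus plasticity can even beat the best constant
world — the good-year reproduction boom outweighs slightly worse bad years
(Jensen's inequality on a convex response).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._optim import _refine, maximize_scalar
from .deterministic import annual_growth_rate, optimal_constant_brood
from .environment import (ResourceModel, expect_log_over_resources,
                          optimal_constant_brood_env)
from .params import LifeHistory


@dataclass
class Trajectory:
    """A simulated population path under one brood strategy.

    Populations are stored on the log scale so century-spanning growth or
    decline never overflows; ``population`` converts back (and may saturate
    at inf/0 for extreme paths).
    """

    years: np.ndarray
    resource: np.ndarray
    brood: np.ndarray
    log_population: np.ndarray
    strategy: str  # "plastic" | "constant"
    seed: int

    @property
    def population(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.log_population)

    @property
    def annual_log_growth(self) -> np.ndarray:
        return np.diff(self.log_population)

    @property
    def mean_log_growth(self) -> float:
        return float(np.mean(self.annual_log_growth))


#: relative positions of the coarse brood grid, in units of the juvenile-term
#: peak 1/c; the per-year optimum always lies in [0, 1/c]
_T_GRID = np.linspace(0.0, 2.0, 33)


def _optimal_brood_scalar(A: float, alpha: float, c: float,
                          xatol: float = 1e-10) -> tuple[float, float]:
    """Argmax and max of g(B) = A exp(-alpha B) + B exp(-c B) over B >= 0."""
    if alpha == 0:
        b = 1.0 / c
        return b, A + b * math.exp(-1.0)

    def g(B: float) -> float:
        return A * math.exp(-alpha * B) + B * math.exp(-c * B)

    vals = A * np.exp(-alpha * _T_GRID / c) + (_T_GRID / c) * np.exp(-_T_GRID)
    i = int(np.argmax(vals))
    lo = _T_GRID[max(i - 1, 0)] / c
    hi = _T_GRID[min(i + 1, _T_GRID.size - 1)] / c
    b, fb = _refine(g, lo, hi, xatol)
    if fb <= A + 1e-12:
        return 0.0, A
    return b, fb


def per_year_optimal_brood(X: float, lh: LifeHistory,
                           xatol: float = 1e-10) -> float:
    """Brood size maximizing the annual growth kernel at resource level X.

    With no brood cost (alpha = 0) the optimum has the closed form
    X / (muJ (1 - L0)).  With a brood cost the optimum shrinks in poor
    years, reaching exactly zero when the marginal adult cost of the first
    offspring outweighs its survival prospects (alpha (1 - muA0) >= 1).
    """
    if X <= 0:
        raise ValueError(f"resource value must be positive, got {X}")
    ju, ad = lh.juvenile, lh.adult
    c = ju.muJ * (1.0 - ju.L0) / X
    b, _ = _optimal_brood_scalar(1.0 - ad.muA0, ad.alpha, c, xatol)
    return b


def _log_plastic_kernel(x: np.ndarray, lh: LifeHistory) -> np.ndarray:
    """log of the per-year-optimized kernel, vectorized over resource values.

    The coarse grid stage runs as one (brood, resource) matrix; only the
    Brent refinement of each column's bracket is per-node.
    """
    ju, ad = lh.juvenile, lh.adult
    A = 1.0 - ad.muA0
    c = ju.muJ * (1.0 - ju.L0) / np.asarray(x, dtype=float)
    if ad.alpha == 0:
        return np.log(A + np.exp(-1.0) / c)
    t = _T_GRID[:, None]
    vals = A * np.exp(-ad.alpha * t / c) + (t / c) * np.exp(-t)
    best = np.argmax(vals, axis=0)
    out = np.empty(c.shape)
    for k, ck in enumerate(c):
        i = int(best[k])
        lo = _T_GRID[max(i - 1, 0)] / ck
        hi = _T_GRID[min(i + 1, _T_GRID.size - 1)] / ck
        _, fb = _refine(lambda B, _c=ck: A * math.exp(-ad.alpha * B)
                        + B * math.exp(-_c * B), lo, hi, 1e-10)
        out[k] = math.log(max(fb, A))
    return out


def lyapunov_env_plastic(lh: LifeHistory, env: ResourceModel,
                         n_nodes: int = 128) -> float:
    """Lyapunov growth rate when brood size tracks the yearly resource.

    exp E[ log R0(B0*(r_Y); r_Y) ]; the per-year optimum is evaluated at the
    fixed quadrature nodes, so the result is deterministic and repeatable.
    At cv = 0 it equals the deterministic optimum growth exactly.
    """
    if env.is_degenerate:
        return optimal_constant_brood(lh, env.mean_r).growth_rate
    return math.exp(expect_log_over_resources(
        lambda x: _log_plastic_kernel(x, lh), env, n_nodes))


def optimal_cv(lh: LifeHistory, cv_range: tuple[float, float] = (0.0, 3.0),
               mean_r: float | None = None, coarse_step: float = 0.05,
               n_nodes: int = 128) -> tuple[float, float]:
    """Level of environmental variation maximizing plastic population growth.

    Coarse scan over ``cv_range`` followed by golden-section refinement;
    returns (best CV, growth there).  A boundary optimum at CV = 0 means a
    constant world is best (the low-brood-cost regime); for high brood cost
    the best CV is strictly positive.
    """
    if mean_r is None:
        mean_r = lh.juvenile.r0
    lo, hi = cv_range
    if not (0 <= lo < hi):
        raise ValueError("cv_range must be a closed interval starting at >= 0")

    def growth(cv: float) -> float:
        return lyapunov_env_plastic(lh, ResourceModel(mean_r, cv), n_nodes)

    grid = np.arange(lo, hi + 0.5 * coarse_step, coarse_step)
    vals = np.array([growth(c) for c in grid])
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    cv_best, g_best = maximize_scalar(growth, float(a), float(b),
                                      n_grid=8, xatol=1e-4)
    # allow an exact boundary optimum at cv = lo
    if vals[0] >= g_best:
        return float(grid[0]), float(vals[0])
    return cv_best, g_best


def simulate_strategy_trajectories(lh: LifeHistory, env: ResourceModel,
                                   n_years: int, seed: int,
                                   n0: float = 100.0
                                   ) -> tuple[Trajectory, Trajectory]:
    """Paired plastic and constant trajectories on the same resource draws.

    The constant strategy uses the CV-aware optimal constant brood; the
    plastic strategy re-optimizes each year at the realized resource.
    Populations evolve in log space by the annual growth kernel, so long
    declines do not underflow.
    """
    if n_years < 1:
        raise ValueError("n_years must be at least 1")
    rng = np.random.default_rng(seed)
    resource = np.atleast_1d(env.draw(rng, n_years))
    years = np.arange(n_years + 1)

    b_const = optimal_constant_brood_env(lh, env).brood_size
    b_plastic = np.array([per_year_optimal_brood(float(x), lh) for x in resource])

    def log_path(broods: np.ndarray) -> np.ndarray:
        log_r = np.log([annual_growth_rate(float(b), lh, float(x))
                        for b, x in zip(broods, resource)])
        return np.concatenate(([math.log(n0)],
                               math.log(n0) + np.cumsum(log_r)))

    plastic = Trajectory(years, resource, b_plastic, log_path(b_plastic),
                         "plastic", seed)
    const_broods = np.full(n_years, b_const)
    constant = Trajectory(years, resource, const_broods,
                          log_path(const_broods), "constant", seed)
    return plastic, constant
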