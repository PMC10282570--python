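"""Deterministic discrete-time population map and optimal constant brood size.

Each breeding interval the adult population is multiplied by
R0(B0) = (1 - muA0) exp(-alpha B0) + B0 exp(-muJ B0 (1 - L0) / r):
surviving adults plus offspring that reached maturity.  There is no density
dependence; the map is linear and the long-run behaviour is governed entirely
by R0.  The same kernel is reused with per-year growth rates r by the
stochastic modules.
"""

from __future__ import annotations

import numpy as np

from ._optim import find_brood_optimum
from .params import BroodOptimum, LifeHistory


def annual_growth_rate(B0, lh: LifeHistory, r: float | None = None):
    """Multiplicative population growth per breeding interval at brood size B0.

    ``r`` is the effective juvenile growth rate for the interval; defaults to
    the baseline r0.  Accepts scalar or array B0.
    """
    if r is None:
        r = lh.juvenile.r0
    if r <= 0:
        raise ValueError(f"juvenile growth rate r must be positive, got {r}")
    B0 = np.asarray(B0, dtype=float)
    if np.any(B0 < 0):
        raise ValueError("brood size must be non-negative")
    adult = (1.0 - lh.adult.muA0) * np.exp(-lh.adult.alpha * B0)
    juvenile = B0 * np.exp(-lh.juvenile.muJ * B0 * (1.0 - lh.juvenile.L0) / r)
    out = adult + juvenile
    return out if out.ndim else float(out)


def iterate_population(N0: float, B0: float, lh: LifeHistory,
                       r: float | None = None, n_years: int = 10) -> np.ndarray:
    """Population sizes N_0, ..., N_{n_years} under the linear map.

    Exactly N_G = N0 * R0^G.
    """
    if N0 <= 0:
        raise ValueError("initial population must be positive")
    if n_years < 0:
        raise ValueError("n_years must be non-negative")
    R0 = annual_growth_rate(B0, lh, r)
    return N0 * R0 ** np.arange(n_years + 1, dtype=float)


def default_search_max(lh: LifeHistory, r: float | None = None) -> float:
    """Ten times the zero-cost optimal brood: brackets all realistic optima."""
    if r is None:
        r = lh.juvenile.r0
    return 10.0 * r / (lh.juvenile.muJ * (1.0 - lh.juvenile.L0))


def optimal_constant_brood(lh: LifeHistory, r: float | None = None,
                           search_max: float | None = None) -> BroodOptimum:
    """Brood size maximizing the deterministic annual growth rate.

    Global argmax over B0 in [0, search_max], with the boundary tie-break:
    an interior optimum that merely matches the no-reproduction growth
    (1 - muA0) would never evolve, so B0 = 0 is returned in that case while
    the interior candidate is still reported.
    """
    if search_max is None:
        search_max = default_search_max(lh, r)
    if search_max <= 0:
        raise ValueError("search_max must be positive")
    return find_brood_optimum(lambda b: annual_growth_rate(b, lh, r), search_max)
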