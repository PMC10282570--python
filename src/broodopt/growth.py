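"""Juvenile von Bertalanffy growth, size-dependent survival, and the
offspring-optimal brood size.

A juvenile born at size ``L0`` (as a fraction of the asymptotic size) grows as
dL/dt = r (1 - L) and dies at instantaneous rate ``muJ (1 - L(t))``, so the
mortality hazard fades as the juvenile approaches full size.  Parents of
smaller broods confer a faster effective growth rate r = r0 / B0 on each
offspring (parental care / per-offspring provisioning), which creates the
offspring-side trade-off: large broods grow slowly and spend longer in the
vulnerable small-size window.
"""

from __future__ import annotations

import math

import numpy as np

from .params import JuvenileParams


def length_at_time(t, r: float, L0: float):
    """Juvenile size L(t) = 1 - (1 - L0) exp(-r t), fraction of asymptotic size.

    Accepts scalar or array ``t``; strictly increasing in t with asymptote 1.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time t must be non-negative")
    if r <= 0:
        raise ValueError(f"growth rate r must be positive, got {r}")
    if not 0 < L0 < 1:
        raise ValueError(f"L0 must lie in (0, 1), got {L0}")
    out = 1.0 - (1.0 - L0) * np.exp(-r * t)
    return out if out.ndim else float(out)


def survivors_at_time(t, B0: float, params: JuvenileParams, r: float):
    """Expected juveniles alive at time t from an initial brood of B0.

    B(t) = B0 exp(-muJ (1 - L0) (1 - exp(-r t)) / r); non-increasing in t,
    converging to the survivors-to-maturity limit as t -> inf.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time t must be non-negative")
    if r <= 0:
        raise ValueError(f"growth rate r must be positive, got {r}")
    if B0 < 0:
        raise ValueError("brood size must be non-negative")
    out = B0 * np.exp(-params.muJ * (1.0 - params.L0) * (1.0 - np.exp(-r * t)) / r)
    return out if out.ndim else float(out)


def survivors_to_maturity_fixed_r(B0: float, params: JuvenileParams, r: float) -> float:
    """Limit of ``survivors_at_time`` as t -> inf at a fixed growth rate r."""
    if r <= 0:
        raise ValueError(f"growth rate r must be positive, got {r}")
    return B0 * math.exp(-params.muJ * (1.0 - params.L0) / r)


def expected_survivors(B0, params: JuvenileParams):
    """Expected offspring reaching maturity when growth rate is shared, r = r0/B0.

    B_inf = B0 exp(-muJ B0 (1 - L0) / r0); defined as 0 at B0 = 0 by
    continuity.  Unimodal in B0 for muJ > 0.  Accepts scalar or array B0.
    """
    B0 = np.asarray(B0, dtype=float)
    if np.any(B0 < 0):
        raise ValueError("brood size must be non-negative")
    out = B0 * np.exp(-params.muJ * B0 * (1.0 - params.L0) / params.r0)
    return out if out.ndim else float(out)


def offspring_optimal_brood(params: JuvenileParams) -> tuple[float, float]:
    """Brood size maximizing expected survivors, and the maximum itself.

    Closed form: B0* = r0 / (muJ (1 - L0)), at which the survivor count is
    B0* / e.  Raises if muJ = 0 (survivors grow without bound: no finite
    optimum).
    """
    if params.muJ == 0:
        raise ValueError("no finite optimum: with muJ = 0 expected survivors "
                         "increase without bound in brood size")
    b_star = params.r0 / (params.muJ * (1.0 - params.L0))
    return b_star, b_star * math.exp(-1.0)
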