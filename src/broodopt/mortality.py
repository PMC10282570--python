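"""Brood-cost adult mortality and expected lifespan.

Having offspring trades adult maintenance for reproduction: annual adult
mortality rises exponentially toward 1 with brood size,
mu_A = 1 - (1 - muA0) exp(-alpha B0).  The marginal cost of one more
offspring is largest at small broods — going from 0 to 1 offspring is always
the most expensive step.
"""

from __future__ import annotations

import math

import numpy as np

from .params import AdultParams


def annual_mortality(B0, params: AdultParams):
    """Probability an adult with brood B0 dies before the next breeding interval.

    Equals muA0 at B0 = 0 or alpha = 0; monotone non-decreasing in both B0
    and alpha; bounded above by 1.  Accepts scalar or array B0.
    """
    B0 = np.asarray(B0, dtype=float)
    if np.any(B0 < 0):
        raise ValueError("brood size must be non-negative")
    out = 1.0 - (1.0 - params.muA0) * np.exp(-params.alpha * B0)
    return out if out.ndim else float(out)


def expected_lifespan(B0: float, params: AdultParams) -> float:
    """Expected number of breeding intervals survived, 1 / mu_A(B0).

    Geometric-survival expectation; infinite when mortality is zero.
    """
    mu = annual_mortality(B0, params)
    if mu == 0:
        return math.inf
    return 1.0 / mu
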