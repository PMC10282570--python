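import numpy as np
import pytest

from broodopt import JuvenileParams, LifeHistory, TwoStateEnvironment


def grid_refine_argmax(f, lo, hi, step=1e-3):
    """Dense-grid brute force + local bounded refinement (independent oracle)."""
    from scipy.optimize import minimize_scalar
    grid = np.arange(lo, hi + step, step)
    vals = np.array([f(x) for x in grid])
    i = int(np.argmax(vals))
    if i in (0, len(grid) - 1):
        return float(grid[i]), float(vals[i])
    res = minimize_scalar(lambda x: -f(x), bounds=(grid[i - 1], grid[i + 1]),
                          method="bounded", options={"xatol": 1e-10})
    return float(res.x), float(-res.fun)


@pytest.fixture
def grid_argmax_oracle():
    return grid_refine_argmax


@pytest.fixture
def baseline_juvenile() -> JuvenileParams:
    """Baseline illustration parameters: r0=0.5, muJ=0.2, L0=0.01."""
    return JuvenileParams(r0=0.5, muJ=0.2, L0=0.01)


@pytest.fixture
def baseline_lh() -> LifeHistory:
    """Baseline life history with muA0=0.07 and no brood cost."""
    return LifeHistory.from_values()


@pytest.fixture
def masting_env() -> TwoStateEnvironment:
    """The kakapo-style masting world of the translocation case study."""
    return TwoStateEnvironment(p_good=0.25, r_good=0.2, r_bad=0.05,
                               alpha_good=0.0, alpha_bad=0.5)
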