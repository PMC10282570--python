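"""Parameter containers for the brood-size life-history model.

Sizes are measured as fractions of the asymptotic juvenile size (L_inf = 1),
time in unitless "days" within a breeding interval, and mortality rates per
day (juvenile) or per breeding interval (adult).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class JuvenileParams:
    """Juvenile growth and mortality parameters.

    Attributes
    ----------
    r0 : float
        Baseline juvenile von Bertalanffy growth rate (time^-1).  The
        effective per-brood growth rate is ``r0 / B0``: parents of smaller
        broods confer faster growth on each offspring.
    muJ : float
        Size-dependent juvenile mortality coefficient (time^-1); the
        instantaneous hazard is ``muJ * (1 - L(t))``.
    L0 : float
        Birth size as a fraction of the asymptotic size (0 < L0 < 1).
    """

    r0: float = 0.5
    muJ: float = 0.2
    L0: float = 0.01

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError(f"r0 must be positive, got {self.r0}")
        if self.muJ < 0:
            raise ValueError(f"muJ must be non-negative, got {self.muJ}")
        if not 0 < self.L0 < 1:
            raise ValueError(f"L0 must lie in (0, 1), got {self.L0}")


@dataclass(frozen=True)
class AdultParams:
    """Adult survival parameters.

    Attributes
    ----------
    muA0 : float
        Intrinsic annual adult mortality probability — the chance an adult
        with no offspring dies before the next breeding interval.
    alpha : float
        Brood cost mortality: per-offspring exponential increase in annual
        adult mortality (mu_A = 1 - (1 - muA0) exp(-alpha * B0)).
    """

    muA0: float = 0.07
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.muA0 < 1:
            raise ValueError(f"muA0 must lie in [0, 1), got {self.muA0}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")


@dataclass(frozen=True)
class LifeHistory:
    """A full parameter set: juvenile growth/mortality plus adult survival."""

    juvenile: JuvenileParams = field(default_factory=JuvenileParams)
    adult: AdultParams = field(default_factory=AdultParams)

    @classmethod
    def from_values(
        cls,
        r0: float = 0.5,
        muJ: float = 0.2,
        L0: float = 0.01,
        muA0: float = 0.07,
        alpha: float = 0.0,
    ) -> "LifeHistory":
        return cls(JuvenileParams(r0, muJ, L0), AdultParams(muA0, alpha))

    def with_alpha(self, alpha: float) -> "LifeHistory":
        return LifeHistory(self.juvenile, AdultParams(self.adult.muA0, alpha))


@dataclass(frozen=True)
class BroodOptimum:
    """An optimal brood size together with its growth rate.

    ``is_interior`` is False when the boundary strategy of no reproduction
    (B0 = 0) is optimal.  ``interior_candidate`` records the interior local
    maximum (brood, growth) when one exists even if it is dominated by the
    zero-brood boundary — the "dashed branch" regime at very high brood cost,
    where a non-zero brood matches but cannot beat simple adult survival.
    """

    brood_size: float
    growth_rate: float
    is_interior: bool
    interior_candidate: tuple[float, float] | None = None
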