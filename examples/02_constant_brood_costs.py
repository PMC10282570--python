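"""Optimal constant brood size when reproduction costs the parent.

Adult mortality rises exponentially with brood size (brood cost alpha).
The population-optimal brood trades this year's recruits against the
parent's future breeding attempts, producing a characteristic non-monotone
response: the optimum falls with alpha, rebounds once adult death is nearly
certain anyway, then collapses to zero.
"""

from broodopt import LifeHistory, optimal_constant_brood

lh = LifeHistory.from_values()  # r0=0.5, muJ=0.2, L0=0.01, muA0=0.07

print(f"{'alpha':>6} {'optimal brood':>14} {'growth R0':>10}  regime")
for alpha in (0.0, 0.25, 0.5, 0.9, 1.2, 2.0, 3.0):
    opt = optimal_constant_brood(lh.with_alpha(alpha))
    regime = "interior" if opt.is_interior else "no reproduction"
    print(f"{alpha:6.2f} {opt.brood_size:14.3f} {opt.growth_rate:10.4f}  {regime}")

print("\nR0 < 1 means decline; the zero-brood floor is 1 - muA0 = 0.93. "
      "At very high cost the interior strategy cannot beat simply surviving.")
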