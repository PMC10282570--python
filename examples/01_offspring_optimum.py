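"""How many offspring maximize the number that reach maturity?

Juveniles grow along a von Bertalanffy curve and die at a rate that fades
with size; parents of smaller broods confer faster growth (r = r0/B0), so
there is an interior optimum brood size from the offspring's point of view.
"""

from broodopt import JuvenileParams, expected_survivors, offspring_optimal_brood

ju = JuvenileParams(r0=0.5, muJ=0.2, L0=0.01)

for brood in (1, 3, 10):
    print(f"brood of {brood:2d}: {expected_survivors(brood, ju):.2f} "
          "offspring expected to reach maturity")

b_star, survivors = offspring_optimal_brood(ju)
print(f"\noffspring-optimal brood size: {b_star:.4f} "
      f"(closed form r0 / (muJ (1 - L0)))")
print(f"survivors at the optimum:     {survivors:.4f} (= optimum / e)")
print("\nSmall broods grow fast but are few; large broods swamp parental "
      "care and die young. The optimum balances the two.")
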