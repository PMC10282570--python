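"""Two species, two environments: the cost of moving.

A masting-adapted species (kakapo-like: distinct optimal broods for good
and bad years) and a constant-world species (blackbird-like: one brood
size) are matched to the same long-run growth rate, then each is moved to
the other's environment while keeping its evolved strategy.
"""

from broodopt import TwoStateEnvironment, run_case_study

env = TwoStateEnvironment(p_good=0.25, r_good=0.2, r_bad=0.05,
                          alpha_good=0.0, alpha_bad=0.5)
res = run_case_study(env, muA0=0.1, muJ=0.1, L0=0.01)

print("masting species (perceives good/bad year cues):")
print(f"  good year: brood {res.good_optimum.brood_size:.2f}, "
      f"growth {res.good_optimum.growth_rate:.2f}")
print(f"  bad year:  brood {res.bad_optimum.brood_size:.2f}, "
      f"growth {res.bad_optimum.growth_rate:.2f}")
print(f"  overall geometric-mean growth: {res.masting_baseline_growth:.2f}")

print(f"\nconstant-world species (matched growth via alpha = "
      f"{res.matched_alpha:.3f}):")
print(f"  brood {res.constant_optimum.brood_size:.2f}, "
      f"growth {res.constant_baseline_growth:.2f} at r = {res.r_const:.4f}")

print("\nafter swapping environments (strategies unchanged):")
print(f"  masting -> constant: growth {res.masting_to_constant_growth:.2f} "
      f"({res.masting_to_constant_pct:+.1f}%)")
print(f"  constant -> masting: growth {res.constant_to_masting_growth:.2f} "
      f"({res.constant_to_masting_pct:+.1f}%)")
print("Both moves cost growth; the cue-driven species loses slightly less "
      "than the fixed-strategy one.")
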