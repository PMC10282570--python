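# Methods

## Model structure and assumptions

The package is organized around one scalar kernel, the annual multiplicative
growth rate of a non-overlapping-generations population with discrete
breeding intervals and no density dependence:

    R0(B0; r) = (1 − muA0) exp(−alpha·B0) + B0 exp(−muJ·B0·(1 − L0)/r).

The first term is adult survival with an exponential brood cost; the second
is the expected number of offspring reaching maturity, derived by solving
the juvenile system dL/dt = r(1 − L), dB/dt = −muJ(1 − L)B in closed form
and letting t → ∞, with the parental-care assumption that the effective
juvenile growth rate is r₀/B₀ (each extra offspring dilutes care). Sizes
are fractions of the asymptotic size; time within a breeding interval is
unitless "days"; "year" means one breeding interval throughout.

Brood size B0 is treated as a continuous non-negative real everywhere
except the branching-process simulator, where broods are integer Poisson
draws. The B0 = 0 limit of the offspring term is defined as 0 by
continuity, so all population-level formulas are well defined at zero
brood, whose growth is the floor 1 − muA0.

## Default parameters

| parameter | meaning | default |
|---|---|---|
| r0 | baseline juvenile growth rate (time⁻¹) | 0.5 |
| muJ | juvenile mortality coefficient (time⁻¹) | 0.2 |
| L0 | birth size, fraction of asymptotic size | 0.01 |
| muA0 | intrinsic annual adult mortality | 0.07 |
| alpha | brood cost mortality (per offspring) | varied |
| CV | resource-year coefficient of variation | varied |

The case-study environment uses muA0 = 0.1, muJ = 0.1, L0 = 0.01, good
years (probability p_mast) with r = 0.2 and alpha = 0, bad years with
r = 0.05 and alpha = 0.5.

## Stochastic growth rates

Long-run growth under IID year-to-year stochasticity is the Lyapunov
exponent of the linear map, exp E[log R0] — geometric-mean fitness. Jensen's
inequality places it at or below the arithmetic-mean growth, which is why
both individual and environmental variation depress a constant strategy.

**Poisson individual variation.** The analytic rate sums log R0(j) against
the Poisson pmf, truncated at the smallest j with upper-tail mass below
1e-12 (halving the tolerance moves results by < 1e-9). The kernel at j = 0
is 1 − muA0 > 0, so the log never diverges. Two simulators complement the
sum: an annual-draw map (one shared Poisson brood per year) whose time
average converges to the analytic rate, and an exact per-adult branching
process. For large populations the branching process's one-step expectation
is the *arithmetic* Poisson-weighted growth; replicate-averaged
trajectories of the two simulators therefore agree (both have expectation
N0·(arithmetic mean)^t), while their pathwise log growth rates differ. Both
averages are reported. Simulations evolve log populations (the annual-draw
map) or integer counts (branching); replicates that hit zero contribute
pre-extinction years only, with the extinction fraction reported.

**Lognormal environment.** Resource years r_Y are lognormal with exact
moment matching: scale² = ln(1 + CV²), location = ln(mean) − scale²/2, so
the mean stays fixed while CV varies. The expectation of log R0 is computed
by Gauss–Hermite quadrature in the log-resource variable (default 128
nodes) with a node-doubling check at 1e-8 relative tolerance. For large
broods the log kernel has a steep transition that Hermite nodes
under-resolve; in that case the integral is recomputed adaptively in the
Gaussian variable on |z| ≤ 8.5 (omitted tail mass < 1e-15) and accepted on
quad's own error estimate, raising with diagnostics if that too fails.
CV = 0 bypasses quadrature entirely, making the degenerate case exact.
Adult mortality is held resource-independent here; resource-dependent brood
cost appears only in the two-state case study.

**Plastic strategies.** The per-year optimal brood maximizes R0(B0; X) at
the realized resource X. With alpha = 0 it is exactly X/(muJ(1 − L0)).
With a cost, the kernel's slope at B0 = 0 is 1 − alpha(1 − muA0): for
alpha(1 − muA0) < 1 the optimum is interior in every year (shrinking like
O(X) in poor years), and only for alpha(1 − muA0) ≥ 1 do poor years shut
reproduction off exactly. The same slope argument means a *constant*
strategy's optimum can only be exactly zero — and hence the zero-brood CV
threshold can only exist — above that same cost level. The plastic
Lyapunov integral evaluates the per-year optimum at the fixed quadrature
nodes, so it is deterministic and repeatable; its cv = 0 limit equals the
deterministic optimal growth to 1e-10.

## Optimization

All brood optimizations share one routine: a 64-interval coarse grid on
[0, search_max] with bounded Brent refinement (xatol 1e-8) of every grid
local maximum, plus the first cell and the cell around the global grid
argmax — a sharp interior peak just above B0 = 0 (high cost, poor resource)
otherwise hides between grid points. Default search_max is ten times the
zero-cost optimum r/(muJ(1 − L0)), which brackets every optimum in the
parameter ranges of interest; an objective still rising at search_max is
logged and reported as unbracketed. Tie-break at the boundary: an interior
optimum must beat the zero-brood growth by more than 1e-9, otherwise
no-reproduction is returned (a strategy that only matches doing nothing
would never evolve) with the interior candidate still reported. The
optimal-CV search scans [0, 3] in 0.05 steps and refines by bounded Brent,
keeping boundary optima at CV = 0 representable.

## Case study and alpha matching

"Overall growth" across the two year types is the probability-weighted
geometric mean exp(p·ln R_good + (1−p)·ln R_bad), the Lyapunov-consistent
combination (the arithmetic mean would overstate it — 1.12 instead of 1.09
at the reference parameters). The constant-world species' brood cost is
always *solved* (Brent root of optimal-growth(alpha) = target, xtol 1e-10;
the optimal growth is continuous and strictly decreasing in alpha between
the alpha = 0 optimum and the floor 1 − muA0) rather than taken from any
rounded value, so every downstream translocation number is internally
consistent. The solver gives alpha = 0.230, optimal brood 0.576 at the
reference parameters, and reproduces translocation growths 0.95 (−12.7 %)
and 0.96 (−11.9 %). Grid cells where the target growth is infeasible are
flagged NaN, never fabricated. Display rounding (2 dp for broods and
growths, whole percent for changes) happens only in reports.

## Synthetic data

The package generates all stochastic inputs itself: Poisson brood draws,
lognormal resource years, and two-state masting sequences, from seeded
numpy Generators (one root SeedSequence spawning per-replicate streams,
all seeds recorded in outputs). These emulate IID year-to-year variation
only — no temporal autocorrelation of masting, no resource-driven adult
mortality outside the two-state case study, no observation error, and
perfect cue perception for plastic breeders. Passing tests therefore
demonstrate the internal consistency of the model under its own stated
assumptions, not the fit of any real time series.

## Problem sizes

Monte-Carlo checks use 2×10⁵-year annual-draw runs, 10⁵-adult
one-generation branching checks, 10⁶ lognormal draws, and 3×10⁴-year
plastic trajectories; every stochastic assertion is a 3-standard-error
band, so these sizes set the tightness of the check rather than its
outcome. Sweep tables default to alpha ∈ [0, 3] step 0.05, CV ∈ [0, 2]
step 0.05, and the translocation surfaces to r_good/r_bad ∈ [1, 10] step
0.25 with p_mast ∈ [0, 1] step 0.02.

## Known limitations

* Exponential brood-cost mortality only; threshold (logistic) costs are a
  stated extension point, not implemented.
* Lognormal resource years only; other positive distributions (e.g. Gamma)
  would slot into the same quadrature but are not provided.
* No density dependence, age structure, or within-year heterogeneity beyond
  the Poisson brood draw; no evolutionary dynamics within runs.
* Plastic breeders perceive the year's resource level perfectly; imperfect
  cues and false alarms are out of scope.
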