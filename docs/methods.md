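# Methods

## Model and power approximation

The design model is four independent normal cells `X_ijk ~ N(μ_ij, σ_ij²)`,
`k = 1..N_ij`, with no homogeneity assumption on the variances. The target of
inference is a linear combination of cell means `ψ = Σ L_ij μ_ij`; the three
standard contrasts (interaction `{1,−1,−1,1}`, main effect A `{1,1,−1,−1}`,
main effect B `{1,−1,1,−1}`) are available as presets, and arbitrary
coefficients are accepted. Power is invariant to jointly rescaling the
coefficients and the effect (L, ψ−ψ0) → (cL, c(ψ−ψ0)); the package does not
normalize coefficient conventions — callers using ½-weighted main-effect
parameterizations must scale ψ0 accordingly.

The data-level test refers `T* = (ψ̂ − ψ0)/ω̂`, with
`ω̂² = Σ L² S² / N`, to a central t distribution whose degrees of freedom ν̂
plug the sample variances into the Satterthwaite formula; H0 is rejected when
`|T*| > t_{ν̂,α/2}`. The reported two-sided p-value `2 P{t(ν̂) > |T*|}` is a
convenience consistent with that rule. For planning, the nonnull distribution
of T* is approximated by a noncentral t with *population*-variance degrees of
freedom ν and noncentrality `δ = (ψ − ψ0)/ω`, giving

    π(δ) = P{ t(ν,δ) > t_{ν,α/2} } + P{ t(ν,δ) < −t_{ν,α/2} }.

At δ = 0 this equals α exactly (verified to 1e−10 in the suite). The
approximation is an approximation: the suite and the acceptance script check
it against the test's simulated rejection rate and find agreement within
0.01 at the design points shipped with the package.

Numerical notes: ν is evaluated with fractional N (the optimizer needs it);
it requires N_ij > 1, and the package enforces a floor of N_ij ≥ 2 everywhere
so every cell variance has at least one degree of freedom. scipy's noncentral
t CDF loses its footing at very large ν (NaN); the power function substitutes
the exact large-ν limit t(ν,δ) → N(δ,1) wherever scipy returns a non-finite
value. This path is only reachable for allocations in the thousands of
subjects.

## Cost-optimal allocation

The design problem is `min C_O + Σ C_ij N_ij` subject to `π(δ(N)) ≥ 1 − β`,
`N_ij ≥ 2`, over integer N. The solver has three stages:

1. **Continuous relaxation.** The N_ij are treated as reals and the smooth
   program is solved with SLSQP (exact linear cost gradient,
   finite-difference constraint gradient, ftol 1e−12). The constraint surface
   is smooth but not convex, so the solver is multistarted: each start is a
   positive direction vector scaled onto the power boundary by Brent root
   finding in the scale factor (monotonicity of power in a common scale makes
   this bracket cleanly). Directions: the comparator's t-stage sizes, the
   σ/√C allocation-ratio rule, equal sizes, σ-proportional, inverse-cost, and
   12 seeded log-normal perturbations of the ratio rule. Solutions ending
   marginally below the target (solver tolerance) are repaired by scaling
   back onto the boundary along their ray, so the returned continuous
   allocation is always feasible. The cheapest feasible endpoint wins.

2. **Floor/ceiling screen.** All 2⁴ = 16 combinations of `[N_P]` and
   `[N_P]+1` (floors clamped to the cell floor, duplicates removed) are
   evaluated; feasible means power ≥ target − 1e−10, the slack guarding
   against knife-edge exclusion at rounding precision. The winner is the
   least-cost feasible candidate, ties broken by largest power, then smallest
   total size, then lexicographic order (the last two rules exist only to
   make results deterministic). The all-ceiling candidate dominates the
   feasible continuous solution, so the screen never comes up empty. All 16
   candidates are recorded in the result's audit trail.

3. **Local integer polish.** The screen inspects only the box around the
   continuous optimum, and that box can miss the true integer optimum: in the
   asthma interaction scenario with unequal costs the global continuous
   optimum is {11.44, 15.74, 12.90, 17.61} (cost 18534.17) while the cheapest
   feasible integer allocation is {11, 16, 13, 19} (18604.08), whose fourth
   cell lies outside the floor/ceiling box. The constraint surface folds near
   the optimum, and rounding each coordinate independently is not guaranteed
   to land on the integer solution. The polish therefore repeats a search of
   the ±2 integer box around the incumbent, accepting a candidate only when
   it is *strictly* cheaper and feasible, until a fixed point. Strict-cost
   acceptance preserves the screen's tie-break semantics. In all twelve
   shipped scenarios the fixed point coincides with an exhaustive ±5-box
   search around the continuous optimum (asserted in the suite); the radius
   and the screen-only behaviour (`refine_radius=0`) are configurable.

Degenerate inputs: ψ = ψ0 makes power ≡ α and raises an infeasibility error
before any optimization; a start that cannot bracket the boundary is skipped;
if every start fails, a convergence error is raised rather than returning an
infeasible allocation.

## The two-step comparator

The comparator fixes allocation ratios at the known normal-theory optimum
`r_ij = (σ_ij/σ_11)√(C_11/C_ij)`, sizes the anchor cell with standard-normal
quantiles (`N_Z11 = (z_{α/2}+z_β)² w²/(ψ−ψ0)²`, `w² = Σ L²σ²/r`), recomputes
approximate degrees of freedom υ at the fractional normal-stage sizes, resizes
with t(υ) quantiles, and rounds every cell up via `floor(N_T)+1`. The
formulas compose with no intermediate rounding and a single Z-then-t pass.
The literal `floor+1` rule is the default because it is what the method
specifies (it yields N+1 when N_T is an exact integer); a true-ceiling
variant is available behind a flag. The comparator never evaluates the
noncentral-t power function and rounds cells independently, which is why the
optimizer's cost is never higher and usually lower; the suite asserts
dominance in all twelve scenarios, with equality exactly once (main effect B
under equal unit costs).

## Monte Carlo engine

Each replication draws N_ij normal variates per cell from the design's means
and variances and applies the level-α Welch–Satterthwaite test; the rejection
proportion estimates the true power, reported with its binomial standard
error √(p(1−p)/R) and the difference from the noncentral-t approximation.
The engine is vectorized across replications (cell streams drawn in flat cell
order from one numpy `default_rng(seed)`) but formula-identical to the
data-level test; a parity test asserts bitwise-equal rejection decisions
against looping the scalar test over the same variate streams. Same seed,
same result, bitwise. Defaults: 10,000 replications, matching the shipped
scenarios' validation scale (MC standard error ≈ 0.004 at p = 0.8).

The generator emulates exactly the model the power function assumes —
independent normal cells with known variances. It does not probe
non-normality, dependence, or variance misspecification, so passing
validation shows the *approximation* is accurate under the model, not that
the test is robust to model violations on real data.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `alpha` | 0.05 | — | conventional two-sided level |
| `target_power` | 0.80 | — | conventional planning target |
| `null_value` | 0 | response units | tests existence of the effect |
| cell floor | 2 | subjects | sample variance needs N−1 ≥ 1 |
| `refine_radius` | 2 | cells | smallest radius that recovers the true optimum in every shipped scenario; validated against ±5 brute force |
| `multistart_count` | 12 | starts | diminishing returns beyond ~10 in the scenarios examined |
| feasibility slack | 1e−10 | power | floating-point guard, far below any decision-relevant scale |
| `replications` | 10,000 | data sets | SE ≈ 0.004 near p = 0.8 |

## Known limitations

- 2×2 designs and a single linear combination only; no multiplicity control
  for several simultaneous contrasts, no larger factorials.
- One-sided tests are not implemented.
- The power function is the noncentral-t *approximation* to the
  Welch–Satterthwaite test's power, not an exact computation; its observed
  accuracy (|error| ≲ 0.01 at n per cell ≥ 6) is an empirical finding at the
  shipped design points.
- The integer stage guarantees a ±`refine_radius` local optimum, not a global
  integer optimum; the suite's ±5 exhaustive cross-check covers the shipped
  scenarios, not every conceivable configuration.
- Budget-constrained power *maximization* (the dual problem) is out of scope.
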