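# welchplan

Power analysis and cost-optimal sample-size allocation for heteroscedastic
2×2 factorial designs tested with the Welch–Satterthwaite statistic.

## The problem

A 2×2 factorial study observes independent normal responses
`X_ijk ~ N(μ_ij, σ_ij²)` in four treatment cells (factor A level *i*, factor
B level *j*) whose error variances may differ. Main effects and the
interaction are expressed as a linear combination of the cell means,
`ψ = Σ_ij L_ij μ_ij` (e.g. the interaction contrast
`ψ_I = μ11 − μ12 − μ21 + μ22`), and `H0: ψ = ψ0` is tested with the
Welch–Satterthwaite statistic `T* = (ψ̂ − ψ0)/ω̂`, which is approximately
t-distributed with Satterthwaite degrees of freedom. Its nonnull distribution
is approximately noncentral t, giving the power approximation

```
ν  = (Σ L² σ² / N)² / Σ L⁴ σ⁴ / [N² (N − 1)]
δ  = (ψ − ψ0) / ω,        ω² = Σ L² σ² / N
π(δ) = P{ |t(ν, δ)| > t_{ν, α/2} }
```

When the cost of recruiting a subject differs across cells
(`C_T = C_O + Σ C_ij N_ij`), the design question becomes: **what integer
allocation {N11, N12, N21, N22} meets the power target at least cost?**
`welchplan` solves this with a continuous constrained minimization (SLSQP
with multistart), an exhaustive screen of the 2⁴ floor/ceiling roundings,
and a local integer polish that guarantees a ±2-box optimum. The widely used
two-step allocation rule (cell sizes proportional to σ_ij/√C_ij, sized with
normal then t quantiles — Luh and Guo's method) is included as a comparator;
it is generally more expensive. A Monte Carlo engine validates the
noncentral-t power approximation against the test's actual rejection rate.

The package is for biostatisticians and trialists planning two-factor studies
under budget constraints when the homogeneous-variance assumption is not
credible.

## Worked example

An asthma study crosses attack context (recent/stable) with panic fear
(low/high). Planning values: means {1.23, 0.42, 0.13, 0.38}, variances
{0.6889, 0.5184, 0.1156, 0.5929}, per-subject costs
{784.74, 267.96, 82.94, 242.44}; target power 0.8 for the interaction at
α = 0.05.

```sh
welchplan optimize \
  --means 1.23 0.42 0.13 0.38 \
  --variances 0.6889 0.5184 0.1156 0.5929 \
  --contrast interaction \
  --unit-costs 784.74 267.96 82.94 242.44
```

prints

```
continuous solution   {11.439, 15.74, 12.901, 17.611}
optimal allocation    {11, 16, 13, 19}
total cost            18604.08
total sample size     59
attained power        0.8005
```

The continuous relaxation would cost 18534.17 with fractional cell sizes;
the cheapest *integer* allocation meeting the 0.8 target recruits 11, 16, 13
and 19 subjects per cell for a total budget of 18604.08 and attains power
0.8005. The comparator rule (`welchplan luh-guo` with the same flags) yields
{12, 17, 14, 19} at 19739.72 — 6% more expensive for the same goal. A Monte
Carlo check of the returned design:

```sh
welchplan simulate --means 1.23 0.42 0.13 0.38 \
  --variances 0.6889 0.5184 0.1156 0.5929 --sizes 11 16 13 19 --seed 1
```

```
approximate power     0.8005
simulated power       0.8011
error (sim - approx)  +0.0006
MC standard error     0.0040
```

so the noncentral-t approximation agrees with the test's simulated rejection
rate well within Monte Carlo error.

Other subcommands: `power` (allocation → approximate power), `test`
(Welch–Satterthwaite test on a long-format CSV with columns
factorA, factorB, response), and `reproduce-tables` (see below). Designs can
also be given as a YAML config file (`--config`); the same functionality is
available from Python via `welchplan.DesignSpec`, `optimize_allocation`,
`luh_guo_sizes`, `simulate_power`, and friends.

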