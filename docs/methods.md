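# Methods

## Model

A discrete-time, stochastic, individual-based model of a group-structured
population of asexual organisms. Individuals carry two state variables: a
heritable cooperation degree φ ∈ {0.0, 0.1, …, 1.0} and an integer age.
The population lives on `n_groups` group slots; a slot is an address, not
an organism — it can be empty and can be recolonized. There is no explicit
space and no natal-patch bias: offspring join a uniformly random slot.

Each step applies, in order: resource production and equal sharing within
groups; reproduction; offspring mutation; offspring dispersal; survival of
everyone (newborns included); ageing of survivors. The model's biology is
carried by four deterministic kernels (module `model_core`):

* group resources: `R_group = R0 * (1 + I*bK*Σφ / (I*R0/2 + bK*Σφ))`,
  a Monod saturating return on the group's summed cooperation degree.
  A group with zero cooperative benefit receives exactly `R0`; the
  increment saturates strictly below `I`.
* equal sharing: `s = R_group / N_group`. Resources are produced and
  consumed within the step; nothing carries over.
* reproduction: `F = alpha*(1 - beta*phi)*(s - M)/(Ks + (s - M))` for
  `s > M`, else 0. The cost of cooperating falls only on the cooperator
  (the `1 - beta*phi` factor), while the benefit (a larger `R_group`) is
  shared by everyone in the group — a public-goods game.
* survival: `r = c*exp(-age/age_standard)`, purely age-dependent.
  Starvation (`s <= M`) halts reproduction but does not directly kill;
  populations starve to extinction through mortality outpacing a halted
  birth process, which is what makes low `R0` an absorbing hazard for
  free-rider-only populations.

Environmental forcing is constant or sinusoidal,
`R0(t) = R00 + A*sin(2*pi*t/P)`, evaluated at integer steps modulo `P` so
periodicity is exact in floating point. The amplitude must satisfy
`A < R00`: the resource kernels presume positive resources.

## Parameters, defaults and calibration

| name | meaning | unit | default |
|---|---|---|---|
| `R00` | environmental resource availability | resources | 4 |
| `I` | maximum resource increment rate | – | 5 |
| `bK` | cooperation efficiency | resources/degree | 5 |
| `alpha` | maximum reproductive rate | offspring/step | 2 |
| `beta` | reproduction cost per unit degree | – | 0.5 |
| `M` | metabolic consumption | resources/step | 1 |
| `Ks` | reproduction half-saturation | resources | 1 |
| `c` | newborn survival probability | – | 0.9 |
| `age_standard` | survival e-folding age | steps | 5 |
| `m` | per-offspring mutation probability | – | 0.001 |
| `n_groups` | group slots | – | 90 |
| `N_init` | initial population size | – | 300 |
| `T` | steps per run | – | 10,000 |

The structural constants (N = 300 individuals in 90 groups, m = 0.001,
11 trait levels, T = 10,000) are the model's reference design. The rate
constants (α, β, M, K_s, I, c, age_standard) are package calibration
choices, fixed once by the criteria implemented in
`coopdyn.experiments.calibrate` and kept thereafter:

* non-social populations persist at benign resource levels (R₀⁰ = 8) —
  measured 100 % of replicates;
* non-social populations go extinct at harsh levels (R₀⁰ = 1) — with
  M = 1, any occupied group at R₀ = 1 has s ≤ M, so extinction there is
  deterministic;
* social populations with b_K = 5 persist at harsh levels — measured
  100 % of replicates.

Every default is overridable through `SimulationParams`, the YAML config,
or CLI flags.

**Forcing defaults.** The sinusoidal experiments use R₀⁰ = 4, A = 2,
P = 500. The amplitude was calibrated jointly with the rate constants: the
forcing should span harsh to benign, but a trough at or below M (i.e.
A ≥ 3 with these defaults) shuts down reproduction entirely for ~90
consecutive steps each period and exterminates every non-social replicate,
leaving no non-social dynamics to compare against. A = 2 places the trough
(R₀ = 2) near the non-social persistence boundary while all replicates of
both scenarios survive.

## Stochastic choices

* **Offspring integerization.** The reproduction kernel yields a
  continuous rate; realized counts are Poisson(F), the standard
  demographic reading of a per-capita rate in discrete time. It preserves
  the mean exactly, which the Monte-Carlo tests verify.
* **Mutation kernel.** With probability m the offspring's level is
  redrawn uniformly from all 11 levels (it may equal the parent's). A
  uniform redraw — rather than a ±0.1 stepwise walk — lets cooperation
  arise de novo from an all-free-rider population, which the harsh-
  environment dynamics require.
* **Initial traits (social scenario).** Uniform over the 11 levels: the
  least-informative choice. Non-social populations start and stay at
  φ = 0 (the trait is locked, mutation disabled).
* **Survival of newborns.** Newborns face survival probability exactly
  `c` in their birth step; survivors of any age then age by one step.
* **RNG.** numpy PCG64 behind a three-primitive interface (uniform /
  integers / Poisson) with a documented per-step draw order, so unit
  tests can drive the engine with fully scripted draws
  (`coopdyn.rng.ScriptedRng`) and reproduce hand-computed lifecycle
  chains bit-exactly. Replicate i of an experiment runs with seed
  `master_seed + i`; results are independent of execution order.

## Analysis choices

* **Stable window.** Summary statistics, cross-correlations and spectra
  drop the first half of each run (fraction 0.5, configurable) to
  exclude the transient.
* **TLCC.** For each integer lag k in [−max_lag, +max_lag], the Pearson
  correlation of `x_t` with `y_{t+k}` over the overlapping window. Each
  window is standardized by its own mean and sd, so slow amplitude drift
  does not masquerade as synchrony. Zero-variance windows yield NaN
  (flagged, never silently 0). At desk scale the window (1,000 steps)
  supports max_lag = 250 = P/2, which covers every distinct phase
  relation of a period-500 forcing.
* **Spectrum.** The population size on the stable window is standardized
  by its mean, `z_t = (N_t − mean)/mean`, and transformed with a real
  FFT; amplitudes are scaled so a pure sinusoid of relative amplitude a
  peaks at height a, and satisfy Parseval's identity against var(z)
  (tested to 1e−6). Replicate spectra are averaged pointwise on the
  common frequency grid; extinct replicates (whose standardization is
  undefined) are excluded and their count reported.
* **Extinction.** Extinction is absorbing; after it a run's series
  continues with N = 0 so all replicates share one length. A replicate
  counts as extinct when its final N is 0.

## Problem sizes

Desk scale — the package default and what `scripts/acceptance.py` and the
test suite use — is T = 2,000 steps and 20 replicates per condition
(about a minute for the full battery on one CPU); the published-design
scale (T = 10,000, 500 replicates) is available behind `--scale paper`.
Population sizes at the defaults range from ~70 (harsh, b_K = 1) to
~1,500 (benign, b_K = 5) individuals.

## What the simulations do and do not emulate

The generator produces demographically realistic discrete-generation
dynamics: overlapping generations with age-structured mortality,
demographic stochasticity at realistic population sizes, mutation-limited
trait evolution, and extinction as an absorbing state. It does not
emulate: spatial structure or limited dispersal (which would further
favor cooperation), density-dependent mortality, environmental
stochasticity beyond deterministic sinusoidal forcing, sexual
reproduction, or continuous trait variation. Conclusions drawn from it
concern this model world; passing tests demonstrate internal correctness
and the model's qualitative mechanisms, not quantitative predictions for
any real species.

## Findings worth flagging, and limitations

Two behaviors of the calibrated model deserve explicit mention because
they differ from what one might expect:

* **A cooperation ceiling under extreme scarcity.** At R₀⁰ = 1,
  free-riders cannot persist at all, so any surviving population is
  essentially all-cooperator regardless of b_K ∈ {1, 3, 5}: the
  stable-window cooperator fraction is pinned at ≈ 0.9998 for every
  efficiency, and the tiny residual free-rider load *increases* with b_K
  (richer groups can transiently host free-riding mutants). The
  cooperator fraction therefore is not monotonically increasing in b_K at
  this harshness; the efficiency gradient is visible only below the
  ceiling (at intermediate R₀⁰).
* **Buffering shows in amplitude, not in phase.** Under sinusoidal
  forcing, social populations fluctuate with markedly smaller relative
  amplitude than non-social ones (desk-scale mean spectrum peak ≈ 0.52
  vs ≈ 0.64), because cooperation rises in the harsh phase and cushions
  the trough. But with these defaults the social equilibrium population
  size still increases steeply with R₀, so both scenarios remain
  phase-locked to the forcing and the peak |TLCC| is ≈ 0.99 for both
  (in fact slightly *higher* for social populations, whose smoother
  series correlate more cleanly). A correlation-based synchrony measure
  is blind to the amplitude buffering that the spectrum captures; full
  desynchronization of social populations would require a parameter
  regime in which extra free-riders cancel the benefit of extra
  resources strongly enough to flatten the N-versus-R₀ response, which
  the shipped calibration does not produce.

Other known limitations: the 11-level trait grid makes selection
coefficients between adjacent levels small in benign environments, so
trait distributions there equilibrate slowly; and at paper scale the
benign-environment runs are the cost driver (population ~1,500), so a
full 500-replicate sweep is minutes-to-hours, not seconds.
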