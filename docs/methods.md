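# Methods

## Models and assumptions

All model variants are logistic-growth ODEs with an environmental death
rate δ and a strong Allee effect. The state is a fixed set of
(species, genotype) compartments — ancestors and mutants per species —
and mutants differ from ancestors only in a higher exponential growth
rate (r_A < r_M). The Allee response multiplies a genotype's growth rate
by (1 − ρ) when its *reference density* is below the critical size N_c:

| variant                     | Allee reference        | logistic term          |
|-----------------------------|------------------------|------------------------|
| baseline                    | — (ρ = 0 enforced)     | own total / K          |
| cooperation                 | own species total      | own total / K          |
| mutualism                   | partner species total  | grand total / K        |
| mutualism_no_competition    | partner species total  | own species total / K  |
| cheater                     | cooperator total       | grand total / K        |

In the cheater model the cheater genotypes additionally carry a factor
(1 + b) above N_c (they skip the cost of cooperation) and (1 − a) below
it (cooperators get preferential access to the public goods they make).

Assumptions worth stating explicitly: no demographic (birth–death) noise —
the only stochastic element is mutant arrival; no spatial structure; the
positive interaction raises the exponential growth rate but not the
carrying capacity; the two mutualists share one K.

The step response is the default because it permits clean first-passage
analysis. A smooth alternative (`allee_form="smooth"`) replaces the step
by a Hill-type sigmoid `r·(1 − ρ·N_c^h/(N_c^h + N^h))` with steepness
h (default 4): continuous, equal to r(1 − ρ/2) at N_c, converging to the
step as h → ∞. For the cheater model both branch values are blended with
the same Hill weight. The boundary case of the step form, N = N_c
exactly, takes the reduced branch (the high branch applies strictly above
N_c); the event has measure zero and the choice is only a tie-break.

## Stress protocol and initial conditions

Pre-stress growth at δ = 0 is deterministic and identical across
replicates, so simulations start at stress onset (t = 0) with the
ancestor at its pre-stress equilibrium — the carrying capacity. Mutualists
with competition split the shared equilibrium K by `initial_fraction`
(default ½ each); without competition each species has its own
equilibrium at K.

The cheater model is the exception: its pre-stress state is an
oscillation, not a fixed point, so a deterministic burn-in is run first
(default 300 time units) starting from cooperators at N_c and cheaters at
N_c/10. Oscillations around N_c require a pre-stress mortality — at δ = 0
the system freezes at carrying capacity because the logistic term
vanishes — so the burn-in applies a small dilution rate `burn_in_delta`
(default 0.1, chosen below r_A(1 − ρ) so cooperators can recover below
N_c; the experimental systems this model descends from are serially
diluted in just this way). The burn-in is mutation-free: pre-stress
mutants would confer no advantage relevant to the coming stress. Being
deterministic, the burn-in is computed once per parameter set and shared
by all replicates, and is integrated with dense events rather than fixed
intervals.

## Simulation engine

Each replicate advances in reporting intervals of Δt = 0.01 time units:

1. deterministic ODE advance by Δt (embedded Dormand–Prince 5(4) pair,
   adaptive step control at rtol 10⁻⁷/atol 10⁻¹⁰, vectorized across the
   replicates of a batch; integrator failure raises, never a silent NaN);
2. mutant injection: per species, a Poisson draw with mean μ·A·Δt where A
   is the ancestor abundance at the interval start. Mutants are added
   without decrementing ancestors; at the μ ≤ 10⁻³ rates of interest the
   non-conservation bias is far below one individual per run. A zero mean
   consumes no random numbers;
3. extinction clamping: any species whose total falls below
   `extinction_threshold` (default 1 individual) is zeroed.

Clamping acts on species totals, not on individual compartments, by
design: right after stress onset the population sits near K, the logistic
term makes *every* per-capita growth rate negative, and a freshly arisen
single mutant transiently dips below one individual before the decline
frees resources. Zeroing that compartment would make early arrivals
unrescuable and, in the baseline model, would contradict the defining
property that the rescue window spans the whole ancestor extinction time.
A lineage below one individual is only tolerated while its species as a
whole remains viable; `clamp_mode="compartment"` restores the stricter
per-compartment rule for comparison.

Verdicts, checked at interval boundaries: *extinct* when every
compartment is zero; *rescued* when the mutant compartment reaches
max(N_c, extinction_threshold) — for mutualism both species' mutants,
and for the cheater model the cooperator mutant with the cheater species
simultaneously extinct (an adapted cheater lineage can still crash an
established cooperator mutant, so the mutant's rise alone is not
absorbing there); *undecided_at_t_max* otherwise, counted as non-rescue.
The default horizon t_max is ten times the deterministic extinction time
of the mutant-free system (a fixed 200-unit horizon when that time is
unbounded), so verdicts are essentially always reached.

Randomness: replicate i of grid point g under master seed s uses
`SeedSequence([s, g, i])`. Identical (params, seed) gives bit-identical
outcomes; batched and one-at-a-time execution share the draw order and
the integrator, so they agree replicate by replicate.

## Theory

First-passage times are computed on the deterministic flow by dense
integration plus event root-finding (scipy RK45 at rtol 10⁻⁹), robust to
the branch switch at N_c; the exponential and logistic-with-death closed
forms serve as independent oracles in the tests (agreement ≤ 10⁻⁶
relative in the K → ∞ limits). `t_decline` is the ancestor decline time
to N_c; `t_grow` the time a mutant starting at the extinction threshold
at stress onset needs to reach N_c, integrated against the declining
background (the logistic term includes the background, not a bare
exponential); the rescue window is max(0, t_decline − t_grow), and for
the baseline it is the whole ancestor extinction time.

The rescue probability approximation is P = 1 − exp(−μ·E) with E the
ancestor exposure ∫A(t)dt (computed by augmenting the background ODE with
a quadrature state) over the *viable arrival span*: the set of arrival
times from which a threshold-sized mutant deterministically reaches N_c.
The span is found by scanning the decline and bisecting both edges
(48-point scan, edge tolerance 10⁻³ of the decline time). This is the
default `method="arrival"`; `method="window"` integrates over [0, window]
instead, which ignores that the earliest arrivals are not viable while
the population is still saturated and that arrivals later than `window`
can still succeed (the growth time shrinks as the background thins), and
therefore systematically underestimates.

For mutualists the two arrival events are rare and independent, so their
probabilities multiply. The second species' span is evaluated on a
conditioned background in which the first species' mutant is injected at
the exposure-weighted mean arrival time of its own span — a one-level
conditioning that captures the competition-accelerated decline of the
partner once the first mutant expands. Without interspecies competition
the joint probability reduces to the square of a single cooperating
population's probability. No analytic treatment of the cheater model is
offered.

## Default parameters

| parameter | default | units | why |
|-----------|---------|-------|-----|
| r_A       | 0.5     | 1/time | ancestral growth; sets the time scale |
| r_M       | 3.0     | 1/time | r_M > δ so mutants can outgrow the stress |
| δ         | 1.0     | 1/time | stress: δ > r_A forces decline; δ/r_A = 2 |
| ρ         | 0.7     | —      | strong Allee: r_M(1 − ρ) = 0.9 < δ, so mutants below N_c cannot establish |
| K         | 1000    | indiv. | large enough that N_c ≪ K is meaningful |
| N_c       | 50      | indiv. | mid-range critical size; swept in studies |
| μ         | 3·10⁻⁴  | 1/(indiv.·time) | puts expected arrivals per window near one, so rescue probabilities are mid-range |
| Δt        | 0.01    | time   | reporting/mutation interval |
| a, b      | 0.3, 0.5 | —     | cheater coexistence with oscillations; rescue studies sweep a |

The inequalities r_A < δ < r_M and r_M(1 − ρ) < δ define the
rescue-relevant regime (`classify_regime` reports deviations). The ratio
δ/r_A = 2 bounds the growth-rate multiplier in the ratio-matching study
when N_c ≪ K: once the handicapped family's scaled growth rate
c·r_A(1 − N_c/K) reaches δ its decline stalls above the critical size
and its rescue probability saturates, so equalizing multipliers cannot
exceed c_max ≈ δ/(r_A(1 − N_c/K)) — the twofold ceiling is the N_c ≪ K
limit of this expression. For N_c at an appreciable fraction of K the
logistic factor inflates the ceiling (measured: c ≈ 2.5 at N_c = 0.4K);
the ratio-matching studies therefore sweep N_c up to 0.25K, where the
twofold ceiling governs.

## What the generator emulates — and what it does not

The parameter defaults emulate a microbial-scale stress experiment:
abrupt lethal stress, rare beneficial mutation, carrying capacity of 10³.
Real populations add demographic noise (important exactly near the
1-individual boundary that is deterministic here), standing variation
(rescue can start from pre-existing mutants, not only new arrivals),
density-dependent mutation, and spatial refugia. Passing tests therefore
validate the *model's* internal logic and its analytic approximation, not
quantitative predictions for any particular organism.

## Monte Carlo sizes and numerical tie-breaks

Production estimates use 1000 replicates per parameter set (binomial SE
≤ 0.016). The test-suite and the acceptance script scale down to 200–500
replicates per estimate (and 1000 where a zero count is the assertion),
with tolerances widened to the matching binomial error; the growth-ratio
bisection stops when the two estimates differ by at most `tol`, their
95% Wilson CIs overlap, or the bracket is narrower than 10⁻².
Wilson score intervals are used throughout because the probabilities of
interest concentrate near 0 and 1. Degenerate inputs are resolved as:
μ = 0 or A = 0 draw no randomness; N_c = 0 makes the reduced branch
unreachable (reference > 0); K = ∞ sets the logistic term to one;
N_c below the extinction threshold uses the threshold as the rescue
criterion so "rescued" still means an established lineage.

## Known limitations

- Near the window-closing transition at high μ, repeated arrivals
  accumulate in the mutant compartment and can rescue where no *single*
  mutant could; every single-arrival approximation (either method)
  underestimates there. The agreement tests run at arrival intensities
  where this effect is within the Monte Carlo noise.
- At large N_c the adaptation of one non-competing mutualist keeps its
  partner's Allee reference high and lengthens the partner's window, so
  the squared-probability decomposition drifts optimistic-side; the
  decomposition checks run at small-to-moderate N_c where the coupling
  is weak.
- The mutualism conditioning uses a single representative arrival time
  for the first species; it is validated only through the
  theory-vs-simulation agreement property, not derived.
- The cheater burn-in is deterministic and shared, so every replicate
  experiences the stress at the same oscillation phase; rescue
  probabilities for that model are conditional on that phase.
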