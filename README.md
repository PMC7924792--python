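# evorescue

Evolutionary rescue in populations engaged in positive interactions:
hybrid deterministic–stochastic simulations and an analytic
rescue-time-window theory.

## The problem

When an environment abruptly deteriorates — a death rate δ larger than the
growth rate r_A — a population declines toward extinction and can survive
only if adapted mutants (growth rate r_M > δ) arise and spread in time:
*evolutionary rescue*. Positive interactions complicate this picture.
Cooperative populations suffer a strong Allee effect: below a critical
population size N_c the per-capita growth rate drops by a factor (1 − ρ),
so a mutant must not only arise but also climb above N_c before the whole
population falls below it. Obligate mutualists additionally need *both*
partner species to adapt while competing for shared resources, and
cooperator populations invaded by cheaters hover around N_c even before
the stress hits.

`evorescue` is for theoretical ecologists and evolutionary biologists who
want to quantify these effects: it estimates rescue probabilities by Monte
Carlo simulation, computes the analytic rescue-window approximation, and
compares interaction types under matched conditions.

## The models

All variants extend logistic growth with an environmental death rate.
For a single cooperative population with ancestors A and mutants M
(N_T = A + M):

    dA/dt = r_A(N_T) · A · (1 − N_T/K) − δA
    dM/dt = r_M(N_T) · M · (1 − N_T/K) − δM

    r(N_T) = r        if N_T > N_c        (step Allee response;
             r(1 − ρ) otherwise            a smooth Hill form is optional)

Obligate mutualists use the *partner's* total as the Allee reference and
(by default) a shared logistic term — interspecies competition; a
no-competition form gives each species its own logistic term. The
cooperator–cheater model references the cooperator total, with cheaters
growing faster by (1 + b) above N_c and slower by (1 − ρ)(1 − a) below.

Dynamics are integrated deterministically over intervals Δt = 0.01; the
only stochasticity is mutation: new mutants arrive as Poisson draws with
mean μ·A·Δt. A species whose total drops below one individual is extinct.
A replicate counts as *rescued* when the mutant compartment reaches N_c
(both species for mutualism; for the cheater model the cooperator mutant
must hold above N_c with cheaters purged).

The theory computes the rescue window — the time the ancestors take to
decline to N_c minus the time a single mutant needs to grow to N_c — and
approximates the rescue probability as P = 1 − exp(−μ ∫ A(t) dt) over the
span of arrival times from which a mutant deterministically reaches N_c.

## Worked example

```python
from evorescue import (ModelParams, classify_regime, rescue_window,
                       rescue_probability_theory, estimate_rescue_probability)

p = ModelParams(model_variant="cooperation", N_c=30.0, mu=3e-4)
print("regime:", classify_regime(p))
w = rescue_window(p)
print(f"t_decline={w.t_decline:.3f}  t_grow={w.t_grow:.3f}  window={w.window:.3f}")
print(f"P_theory={rescue_probability_theory(p):.3f}")
row = estimate_rescue_probability(p, n_replicates=500, master_seed=1)
print(f"P_sim={row['p_hat']:.3f}  95% CI=({row['ci_low']:.3f}, {row['ci_high']:.3f})")
```

prints

```
regime: rescue_relevant
t_decline=5.686  t_grow=3.541  window=2.145
P_theory=0.325
P_sim=0.332  95% CI=(0.292, 0.374)
```

The defaults (r_A = 0.5, r_M = 3, δ = 1, ρ = 0.7, K = 1000) put the
population in the rescue-relevant regime r_A < δ and r_M > δ > r_M(1 − ρ):
ancestors decline from K to the critical size N_c = 30 in 5.7 time units,
a mutant arising at stress onset needs 3.5 time units to climb to N_c,
and the resulting 2.1-unit rescue window gives a ≈33% rescue chance at
μ = 3·10⁻⁴ — theory and a 500-replicate Monte Carlo estimate agree within
the binomial error. Raising N_c to 300 closes the window: the rescue
probability is zero for every mutation rate.

The same machinery is scriptable from the shell:

```sh
evorescue sweep -c config.yaml          # rescue-probability grids -> CSV
evorescue theory -c config.yaml         # window / probability surfaces
evorescue compare -c config.yaml        # interaction types side by side
evorescue match-ratio -c config.yaml    # growth-rate handicap of cooperation
evorescue simulate -c config.yaml       # one replicate, full trajectory
```

where `config.yaml` holds the parameters, e.g.

```yaml
params: {model_variant: cooperation, mu: 3.0e-4}
grid:   {N_c: [10, 30, 100, 300]}
n_replicates: 1000
seed: 1
out_dir: results
```

Each command writes a resolved-config sidecar; re-running from the sidecar
reproduces the outputs exactly.

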