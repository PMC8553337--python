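# evoplast

Evolutionary search for interpretable synaptic plasticity rules in
spiking neuronal networks.

Phenomenological models of synaptic plasticity are compact symbolic
expressions: a function *f* of locally available quantities that sets
the weight change, Δw = η·f(…).  Instead of deriving such rules by
hand, `evoplast` treats their discovery as an optimization problem
("evolving to learn"): candidate expressions are encoded as Cartesian
genetic programming (CGP) genotypes, mutated and selected by a μ+λ
evolution strategy, and scored by how well a spiking network actually
*learns* when the rule is in charge of its synapses.  Because the
phenotype is a readable formula, the winners can be analyzed, compared
and generalized — in contrast to black-box learned optimizers.

The package is for computational neuroscientists who want to run or
extend such searches at desk scale, and it ships the discovered rules
of each task family as built-in, testable references.

## Task families and fitness functions

- **Reward-driven** — N Poisson inputs project to one stochastic
  escape-noise readout (φ(u) = ρ·e^{(u−u_th)/Δu}); frozen-noise
  patterns must be classified with a spike/no-spike code, reward
  R = ±1.  Rules take the form Δw_j = η·f(R, E_j(T), R̄) or
  η·f(R, E_j(T), R̄⁺, R̄⁻), where E_j is the policy-gradient
  eligibility trace τ_M Ė_j = −E_j + (1/Δu)[Σ_s δ(t−s) − φ(u)]·ε_j(t)
  and the baselines are moving averages of (positive/negative) rewards.
  Fitness: mean reward per trial, averaged over experiments (or times
  the trial count n on the accumulated-reward scale).  Built-in
  references LR0–LR5, e.g. LR0: (R−1)E, LR2: (R−R̄_abs)E.
- **Error-driven** — a student neuron matches a teacher's membrane
  potential from shared Poisson input; Δw_j = η·f(v, u, s̄_j).
  Fitness: negative RMSE between v and u (initial 10% excluded).
  References: the gradient rule (v−u)s̄ and two discovered variants
  that reduce to c₁(v−u)s̄ + c₂ with c₁ ≈ 2.
- **Correlation-driven** — a LIF neuron must detect a frozen-noise
  pattern replayed among rate-balanced background spikes, using
  nearest-spike STDP with weight dependence (branches f_dep/f_fac of
  w and E^c = e^{−|Δt|/τ}) plus per-spike homeostatic terms.  Fitness:
  minimal signal-to-noise ratio of the free membrane potential across
  experiments.  References: a homeostatic STDP baseline and two
  discovered rules (LR1, LR2).

See `docs/methods.md` for the full model description, parameter
defaults and their rationale, and known limitations.

## Worked example

Score the fixed reward-driven rule Δw = η(R−1)E — written as an infix
expression over x0=R, x1=E — on three seeded experiments of the
spike/no-spike classification task:

```
$ evoplast eval-rule --task reward --expression "(x0 - 1)*x1" --seeds 0,1,2
{
 "task": "reward",
 "rule": "(x0 - 1)*x1",
 "per_experiment": [
  192.0,
  266.0,
  258.0
 ],
 "mean": 238.66666666666666,
 "std": 33.15954697452237,
 "aggregate": 238.66666666666666
}
```

Each per-experiment number is the accumulated reward over 300 learning
trials (ceiling 300 = every trial classified correctly; 0 = chance).
Here the rule learns the task in all three experiments, collecting on
average ~80% of the attainable reward including the early trials spent
learning.

A full evolutionary search is driven by a TOML config:

```
$ evoplast evolve --config run.toml        # writes evolution_log.jsonl,
                                           # best_expression.txt, ...
$ evoplast kernels --rule LR2 --out k.csv  # STDP kernel dump for plotting
$ evoplast make-fixtures --seed 0 --out fixtures/
```

with `run.toml` like:

```toml
task = "reward"
seed = 1
out_dir = "runs/reward-1"

[evolution]
mu = 4
lam = 4
n_generations = 100

[task_config]
n_experiments = 10
```

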