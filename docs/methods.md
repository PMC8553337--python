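# Methods

`evoplast` searches for synaptic plasticity rules as compact symbolic
expressions.  A candidate rule is a function f from local synaptic
quantities to a weight change, Δw = η·f(·), encoded as a Cartesian
graph, evolved by a μ+λ strategy, and scored by running it inside a
spiking-network simulation of one of three task families.  This note
records the model choices, the default parameters and why they were
chosen, and what the synthetic tasks do and do not probe.

## Cartesian genetic programming

The genotype is a fixed-size two-dimensional graph: input nodes, a grid
of internal nodes (default 1 row × 12 columns, full `levels_back`) and
one or more output nodes.  Each internal node carries one operator gene
and `max_arity` input genes; only the first `arity` of them are coding.
The default primitive set is {+, −, ×, ÷} plus constant nodes {1.0,
0.5}; a binary power operator is opt-in (the correlation-task search
uses it, since rules of the form (wE)^w are otherwise unreachable).
Division is deliberately unprotected: any non-finite intermediate raises
an invalid-evaluation flag which the evolution loop converts to fitness
−∞.  Silently substituting a value would hide genuinely pathological
expressions from selection.

Decoding collects the active subgraph by backward reachability from the
output genes and renders a canonical, fully parenthesized infix
expression.  That string is the cache key: two genotypes with the same
phenotype share one fitness evaluation.  We do not canonicalize
algebraically (`x0*x2` and `x2*x0` are distinct keys); this is a cheap,
conservative choice — it can only cause extra evaluations, never wrong
cache hits.

Mutation resamples each mutable gene independently with probability
`p_mutate`, always to a *different* legal value.  The default
`p_mutate = 0.3` is high by genetic-algorithm standards but appropriate
for CGP, where most genes are non-coding at any time and the effective
phenotypic mutation rate is far lower; with the default graph sizes it
makes the desk-scale smoke searches (e.g. recovering `x0*x2` with μ=2,
λ=4 in 50 generations) succeed in the large majority of seeds.

## Evolution strategy

A variant of μ+λ evolution strategies with tournament selection
(default tournament size 1, i.e. uniform parent choice), mutation-only
offspring (no crossover, which is disruptive for CGP graphs), and
neutral search: at equal fitness an offspring replaces a parent, so
silent mutations can accumulate and carry the search across plateaus.
Defaults μ=4, λ=4 keep desk-scale runs fast.  Per-evaluation task
samples are drawn once from the run seed and reused in every
generation, making fitness values comparable across generations; the
fitness cache is keyed on (expression, task-sample seeds) so changing
the sample invalidates it.  Fitness aggregation over task samples is
the mean for the reward and error families and the minimum for the
correlation family.

Tournament subsets are drawn without replacement ("choose a random
subset"); with size = population size this returns the global best, and
with size 2 over three distinct fitnesses the best wins with
probability 2/3.

## Neuron and input models

Times are in ms, rates in Hz, potentials in mV.  Default membrane
parameters u_rest = −70, τ_m = 10, τ_syn = 5.  The stochastic neurons
(reward and error tasks) emit spikes as an inhomogeneous Poisson
process with escape rate φ(u) = ρ·exp((u − u_th)/Δu), saturating at
`max_rate` (default 1000 Hz; 200 Hz in the reward task, where the
saturation doubles as a refractory-like ceiling that keeps
trial-end eligibility values bounded).  Spike emission per step uses
the exact probability 1 − exp(−φ dt); the linear membrane/current
subsystem is integrated exactly per step (dt = 0.1 ms), so refining dt
changes trajectories only through spike-time discretization.  The
correlation task uses a deterministic hard-threshold LIF with
delta-shaped PSCs, simulated event-driven (with delta PSCs the
potential can only cross threshold at a spike arrival).  One dt of
synaptic delay separates a presynaptic spike from its postsynaptic
effect.

None of the neuron constants (τ_m, ρ, Δu, u_th, input rates, weight
scales) are fixed by the task definitions alone; they live in the
regime where the respective reference rule learns reliably, and were
chosen once, as follows, then frozen: the error and correlation tasks
use values for which the reference rules (potential-error gradient
rule; homeostatic STDP) succeed robustly, and the reward task uses the
configuration found by a coarse parameter search maximizing learning
performance of the (R−1)E rule — mirroring the practice of tuning the
learning setup on the known reference rule before any search.

## Reward-driven task

N = 100 inputs project to one escape-noise readout (u_th = −62,
Δu = 1.5, ρ = 50, max_rate = 200).  M = 2 frozen-Poisson patterns
(6 Hz per input, 500 ms), one per class; classification is spike vs.
no spike over the whole trial, reward R = ±1.  Initial weights are
N(0, σ_w) with σ_w = 0.35, which puts the initial spike probability
per trial near one half.  Baselines are moving averages with window
m_r = 100 trials, held across trials within an experiment and reset
between experiments; the baseline available in trial i uses rewards up
to trial i−1.

The per-synapse eligibility follows the stochastic policy-gradient
score: τ_M Ė_j = −E_j + (1/Δu)[Σ_s δ(t−s) − φ(u(t))]·ε_j(t), with
τ_M = 500 ms and ε_j the *PSP-filtered* presynaptic trace, i.e. the
sensitivity ∂u/∂w_j of the reset-free membrane to synapse j.  Using the
bare synaptic-current trace here instead would bias the score (we
verified empirically that E then acquires a strong nonzero mean under
fixed weights, breaking all reward rules); with the PSP trace the
trial-end E is zero-mean under fixed weights and O(1–10), commensurate
with the reward and baseline terms that the discovered rules add to it.
The trace is normalized per second, so its clamped-potential fixed
point is −φ(u)·ε/Δu with φ in Hz and trial-end values are O(1–10),
commensurate with the O(1) reward and baseline terms the reference
rules combine it with.  Weight updates Δw = η·f(R, E(T), baselines)
are applied once per trial; η = 0.05 (tuned on the (R−1)E rule).

Fitness is the mean reward per trial averaged over experiments; the
"paper" scale multiplies by the trial count n so the ceiling equals n.
n = 300 trials per experiment and n_exp = 10 experiments are the
defaults.  The task geometry (M = 2 patterns, N = 100 inputs) was
chosen because it is the scale at which the eligibility-only reference
rules learn reliably; with more patterns per class the failure mode
below dominates at desk scale.

Two known limitations of this family.  First, when the weights drive
the neuron to spike with probability ≈ 1 for every pattern (or ≈ 0),
the policy-gradient score — and hence every rule built on it — carries
almost no information; the weights then random-walk on a plateau and an
experiment can fail outright.  Second, rules whose weight update is
dominated by a reward-gated term that acts identically on *every*
synapse (the homeostatic terms of two of the six reference rules)
shift the membrane potential coherently by N × PSP × Δw per trial; at
this network scale (PSP ≈ 2.5 mV per unit weight against an 8 mV
threshold gap) that drives the readout onto the saturation plateau
before the per-synapse eligibility term can correct errors, and the
effect is independent of η because both terms scale with it.  Those
two rules therefore do not reach high fitness here; their viability
depends on a network scale (many small-amplitude synapses) that this
desk-scale configuration does not reproduce.  The relative ranking of
the six reference rules is correspondingly sensitive to the operating
point.

## Error-driven task

N = 10 Poisson inputs with per-input constant rates U[10, 50] Hz drive
a teacher and a student (no reset after spikes, so spiking is
irrelevant to the dynamics and is omitted).  Teacher weights
U[2, 10] plus a global shift U[−2, 2] per experiment; student starts at
w_0 = 6.  The student reads the teacher potential every δt = dt and
updates continuously, Δw_j = η·f(v, u, s̄_j), with the raw updates
exponentially smoothed (τ_I = 10 ms) before application.  Potentials
are passed to rules relative to rest, which makes the large-potential
limit of the discovered expressions well defined.  η = 10⁻³ was chosen
by grid search (decades 10⁻⁵…3·10⁻³) on a single example task with the
gradient rule (v−u)s̄ — the largest rate that converges cleanly; it
recovers the teacher weights to well under 10 % of the weight spread in
10/10 test seeds over T = 10 s.  Fitness is the negative RMSE between v
and u excluding the initial 10 % of the trace, so that maximizing
fitness is literal.

The asymptotic reduction of a rule to c₁(v−u)s̄ + c₂ is computed by
least squares over sampled points with u ~ U[20, 100] mV above rest,
v − u ~ U[−1, 1] and s̄ ~ U[0, 1]; the residual is the RMS misfit
relative to the RMS rule output.

## Correlation-driven task

N = 500 inputs, base rate ν = 5 Hz, frozen pattern of 100 ms replayed
every 400 ms.  The frozen pattern is drawn from a Poisson process and
thinned to the first spike per neuron, which makes the printed balance
factor α = 1 − ν_pattern/ν_inter exact: pattern neurons then have the
same average rate as background neurons, removing rate as a detection
cue.  The output is a hard-threshold LIF (u_th = −60, τ_m = 10) with
delta PSCs of J = 2 mV per unit weight; initial weights U[0.3, 0.7].

Pairing is nearest-spike: at each presynaptic spike, the anticausal
branch f_dep(w, E) fires against the most recent postsynaptic spike
plus the presynaptic homeostatic term; at each postsynaptic spike, the
causal branch f_fac(w, E) fires for every synapse against its most
recent presynaptic spike plus the postsynaptic homeostatic term.
E = exp(−|Δt|/τ) with τ = 20 ms.  Weights are clipped to [0, 1] after
every update; rules that divide by w (the discovered rule with the
−E/w anticausal branch) get a weight floor of 10⁻³.  η = 0.01.
Synaptic transmission at a spike uses the weight before that spike's
plasticity update.

Evaluation freezes the weights, replays the pattern with fresh
background (20 cycles), disables spiking, and computes
SNR = (⟨max u per pattern window⟩ − ⟨u inter⟩)/Std(u inter); the first
50 ms after each pattern are excluded from the inter statistics so the
pattern's own decaying tail does not inflate them.  Training length
(200 cycles = 100 s) and J were calibrated once so that the baseline
homeostatic STDP rule trains the detector reliably; the same settings
are used for all rules.  Fitness is the minimum SNR over n_exp = 3
experiments.

For searches over this family one genome carries four outputs
(f_dep, f_fac, f_pre_hom, f_post_hom) over inputs (w, E); the
homeostatic outputs are evaluated with E masked to zero so they depend
on the weight only.

## What the synthetic tasks do and do not show

All inputs are synthetic and fully seeded: frozen-Poisson patterns,
i.i.d. Poisson background, uniformly drawn rates and teacher weights.
They emulate the statistical structure the learning problems need
(spatio-temporal pattern identity, a noisy regression target, a
repeating correlation structure) but none of the things real neural
data would add: correlated inputs, nonstationary rates, dale-law sign
constraints, conductance effects, or trial-to-trial gain changes.
Passing tests therefore shows that the implementation realizes the
specified dynamics and that the reference rules behave as described
under the stated conditions — not that any rule would perform
equivalently in vivo.

## Numerical choices and degenerate inputs

- Exact exponential propagators everywhere; no Euler integration.
- Escape-rate exponent clamped (arg ≤ 30) and rate saturated at
  `max_rate`; both documented fields, not hidden constants.
- Invalid expressions (division by zero, overflow, 0^negative) raise a
  flag that becomes fitness −∞; they are cached like any value and can
  never crash a run.
- SNR with zero inter-pattern variance reports +∞ with a warning.
- Ties in tournament selection resolve to the first maximum in subset
  order; selection ties between parent and offspring resolve to the
  offspring (neutral search).
- The balance factor α is rejected (configuration error) if the
  pattern rate exceeds what balancing can absorb (ν_pattern > ν_inter).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the tasks at the default
sizes above (reward: 300-trial experiments, up to 50 of them in the
acceptance script; error: 10-second trials; correlation: 100-second
training runs, 3 experiments), which a single CPU core completes in
minutes.  Full evolutionary searches over
thousands of candidate rules are supported by the same code paths
(`evoplast evolve`) but are not exercised at full scale by the checks.
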