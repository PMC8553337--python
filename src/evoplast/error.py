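"""Error-driven learning: teacher-student regression on membrane
potentials.

N Poisson inputs with constant (per-input) rates project with identical
connectivity to a teacher and a student neuron, both leaky integrators
with exponential postsynaptic currents and no reset after spike emission
(their spiking does not feed back onto the potential, so the potential
dynamics are deterministic given the inputs).  The teacher's fixed
weights define target potentials v(t), read out every ``delta_t`` and
provided instantaneously to the student; the student's weights adapt
under dw_j = eta * f(v, u, sbar_j), with updates low-pass filtered
(tau_I) before application.  The reference rule is the potential-error
gradient rule dw_j = eta * (v - u) * sbar_j.

Fitness is the negative RMSE between v and u over the simulation,
excluding the initial 10% (so maximizing fitness minimizes the error).
Potentials are passed to rules relative to rest, which makes the
large-potential asymptotics of the discovered rules well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .cgp import CompiledRule, InvalidEvaluation
from .neurosim import NeuronParams, filter_spikes, poisson_times, propagators, subthreshold_potential

__all__ = [
    "ErrorTaskConfig",
    "ErrorTrialResult",
    "run_error_trial",
    "rmse",
    "rmse_in_windows",
    "fitness_error",
    "asymptotic_reduce",
    "reference_rules",
    "reference_rule_expressions",
    "wrap_compiled_rule",
]


@dataclass
class ErrorTaskConfig:
    n_inputs: int = 10
    r_min: float = 10.0  # Hz
    r_max: float = 50.0
    w_min: float = 2.0  # teacher weight range
    w_max: float = 10.0
    w0: float = 6.0  # student initial weight
    w_shift: float = 2.0  # global teacher shift ~ U[-w_shift, +w_shift]
    delta_t: float = 0.1  # readout interval (ms); default = dt
    eta: float = 1e-03  # grid-searched on a single example task with the gradient rule
    tau_I: float = 10.0  # update low-pass filter (ms)
    T: float = 10000.0  # ms
    n_experiments: int = 5
    dt: float = 0.1
    neuron: NeuronParams = field(
        default_factory=lambda: NeuronParams(
            tau_m=10.0, u_rest=-70.0, u_th=-55.0, delta_u=2.0, rho=20.0,
            reset_mode="none", tau_syn=5.0,
        )
    )

    def __post_init__(self) -> None:
        if self.r_min > self.r_max or self.w_min > self.w_max:
            raise ValueError("require r_min <= r_max and w_min <= w_max")
        if self.delta_t < self.dt:
            raise ValueError("delta_t must be >= dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.dt))


#: error rule contract: f(v_rel, u_rel, sbar_j) -> per-synapse value, with
#: potentials measured relative to rest
ErrorRuleFn = Callable[[float, float, np.ndarray], np.ndarray]


def wrap_compiled_rule(rule: CompiledRule) -> ErrorRuleFn:
    if rule.arity != 3:
        raise ValueError("error-driven rules take 3 inputs (v, u, sbar_j)")
    return lambda v, u, s: rule(v, u, s)


@dataclass
class ErrorTrialResult:
    v: np.ndarray  # teacher potential trace (mV)
    u: np.ndarray  # student potential trace (mV)
    weights: np.ndarray  # final student weights
    teacher_weights: np.ndarray
    weight_history: np.ndarray | None  # (n_records, N), optional


def run_error_trial(
    rule: ErrorRuleFn,
    config: ErrorTaskConfig,
    seed: int,
    record_weights_every: int = 0,
) -> ErrorTrialResult:
    """One experiment: fresh input rates, spike trains and teacher
    weights; continuous weight adaptation of the student over T."""
    rng = np.random.default_rng(seed)
    N, dt, n_steps = config.n_inputs, config.dt, config.n_steps
    rates = rng.uniform(config.r_min, config.r_max, size=N)
    sbar = np.empty((N, n_steps))
    for j in range(N):
        times = poisson_times(rates[j], config.T, rng) + dt  # one-step synaptic delay
        sbar[j] = filter_spikes(times, config.neuron.tau_syn, dt, n_steps)

    w_teacher = rng.uniform(config.w_min, config.w_max, size=N) + rng.uniform(
        -config.w_shift, config.w_shift
    )
    v = subthreshold_potential(w_teacher @ sbar, config.neuron, dt)

    k_read = int(round(config.delta_t / dt))
    u_rest = config.neuron.u_rest
    em, _, p21 = propagators(config.neuron.tau_m, config.neuron.tau_syn, dt)
    a = math.exp(-config.delta_t / config.tau_I)
    w = np.full(N, float(config.w0))
    X = np.zeros(N)  # low-pass-filtered update
    u = np.empty(n_steps)
    u_rel = 0.0
    v_held_rel = v[0] - u_rest
    history = [] if record_weights_every else None
    for k in range(n_steps):
        u_rel = u_rel * em + p21 * float(w @ sbar[:, k])
        u[k] = u_rest + u_rel
        if k % k_read == 0:
            v_held_rel = v[k] - u_rest
            raw = np.asarray(rule(v_held_rel, u_rel, sbar[:, k]), dtype=np.float64)
            if not np.all(np.isfinite(raw)):
                raise InvalidEvaluation("error rule produced a non-finite weight change")
            X = a * X + (1.0 - a) * raw
            w = w + config.eta * X
        if record_weights_every and k % record_weights_every == 0:
            history.append(w.copy())
    return ErrorTrialResult(
        v=v,
        u=u,
        weights=w,
        teacher_weights=w_teacher,
        weight_history=np.asarray(history) if history else None,
    )


def rmse(v: np.ndarray, u: np.ndarray, skip_fraction: float = 0.1) -> float:
    """Root mean-squared potential error, excluding the initial
    ``skip_fraction`` of the trace."""
    k0 = int(len(v) * skip_fraction)
    d = v[k0:] - u[k0:]
    return float(np.sqrt(np.mean(d * d)))


def rmse_in_windows(v: np.ndarray, u: np.ndarray, n_windows: int = 10) -> np.ndarray:
    """RMSE per consecutive time window (learning-curve view)."""
    edges = np.linspace(0, len(v), n_windows + 1, dtype=int)
    return np.array(
        [rmse(v[a:b], u[a:b], skip_fraction=0.0) for a, b in zip(edges[:-1], edges[1:])]
    )


def fitness_error(
    rule: ErrorRuleFn, config: ErrorTaskConfig, seeds: Sequence[int]
) -> float:
    """Negative mean RMSE across experiments (maximal fitness = 0)."""
    if len(seeds) < 1:
        raise ValueError("need at least one experiment seed")
    errors = []
    try:
        for s in seeds:
            r = run_error_trial(rule, config, int(s))
            errors.append(rmse(r.v, r.u))
    except InvalidEvaluation:
        return float("-inf")
    return -float(np.mean(errors))


def asymptotic_reduce(
    rule: ErrorRuleFn,
    u_range: tuple[float, float] = (20.0, 100.0),
    delta_range: tuple[float, float] = (-1.0, 1.0),
    sbar_range: tuple[float, float] = (0.0, 1.0),
    n_samples: int = 4000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Least-squares reduction of a rule to c1*(v-u)*sbar + c2 in the
    regime v ~ u with both far above rest.

    Returns (c1, c2, residual) with residual the RMS misfit relative to
    the RMS rule output.  Degenerate sampling (no variance in
    (v-u)*sbar) is a usage error.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    u = rng.uniform(*u_range, size=n_samples)
    v = u + rng.uniform(*delta_range, size=n_samples)
    s = rng.uniform(*sbar_range, size=n_samples)
    x = (v - u) * s
    if np.std(x) == 0:
        raise ValueError("degenerate sampling: (v-u)*sbar has zero variance")
    y = np.asarray(rule(v, u, s), dtype=np.float64)
    y = np.broadcast_to(y, x.shape)
    A = np.column_stack([x, np.ones_like(x)])
    (c1, c2), *_ = np.linalg.lstsq(A, y, rcond=None)
    fit = A @ np.array([c1, c2])
    rms_y = float(np.sqrt(np.mean(y * y)))
    residual = float(np.sqrt(np.mean((y - fit) ** 2))) / rms_y if rms_y > 0 else 0.0
    return float(c1), float(c2), residual


def reference_rules() -> dict[str, ErrorRuleFn]:
    """Error-driven reference rules over (v, u, sbar), potentials
    relative to rest.

    ``gradient``  : (v - u) * sbar           (stochastic gradient descent)
    ``evolved_a`` : (v - u) * sbar * (2u - 1)/v
    ``evolved_b`` : sbar * ((v + u) v (v - u) - sbar) / v^2
    The latter two reduce to c1*(v-u)*sbar + c2 with c1 ~ 2 for v ~ u >> 1.
    """
    return {
        "gradient": lambda v, u, s: (v - u) * s,
        "evolved_a": lambda v, u, s: (v - u) * s * (2.0 * u - 1.0) / v,
        "evolved_b": lambda v, u, s: s * ((v + u) * v * (v - u) - s) / v**2,
    }


def reference_rule_expressions() -> dict[str, str]:
    """Same rules as infix text over x0=v, x1=u, x2=sbar."""
    return {
        "gradient": "(x0 - x1) * x2",
        "evolved_a": "(x0 - x1) * x2 * (2*x1 - 1) / x0",
        "evolved_b": "x2 * ((x0 + x1) * x0 * (x0 - x1) - x2) / x0**2",
    }
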