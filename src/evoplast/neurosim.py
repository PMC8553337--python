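"""Fixed-step spiking dynamics: leaky integrators, escape noise, Poisson
and frozen-noise inputs, exponential spike-train filtering.

Conventions: times in ms, rates in Hz, potentials in mV.  The linear
subsystems (membrane, synaptic currents, filtered traces) are integrated
exactly per step via exponential propagators, so halving dt changes
subthreshold trajectories only through spike-time discretization.  Spike
emission of stochastic neurons uses the exact in-step probability
1 - exp(-phi*dt) rather than phi*dt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "NeuronParams",
    "SimConfig",
    "escape_rate",
    "spike_probability",
    "propagators",
    "exp_filter",
    "filter_spikes",
    "times_to_steps",
    "poisson_times",
    "frozen_pattern",
    "BalancedRates",
    "balanced_rate_factor",
    "subthreshold_potential",
    "simulate_escape_neuron",
]

#: clamp for the escape-rate exponent; far above any operating regime but
#: below float overflow
_MAX_EXP_ARG = 30.0


@dataclass
class NeuronParams:
    """Stochastic leaky-integrator neuron with escape noise.

    ``rho`` is the firing rate at threshold (Hz), ``u_th`` the threshold
    potential and ``delta_u`` the noise amplitude: the instantaneous
    firing rate is rho * exp((u - u_th)/delta_u).  ``reset_mode`` selects
    what happens after a spike: ``"reset"`` (instantaneous reset to rest),
    ``"none"`` (membrane keeps integrating) or ``"lif"`` (deterministic
    hard threshold with reset; escape noise disabled).
    """

    tau_m: float = 10.0
    u_rest: float = -70.0
    u_th: float = -55.0
    delta_u: float = 1.0
    rho: float = 20.0
    reset_mode: str = "reset"
    tau_syn: float = 5.0
    max_rate: float = 1000.0  # saturation of the escape rate (Hz)

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.delta_u <= 0 or self.rho < 0 or self.max_rate <= 0:
            raise ValueError("require tau_m > 0, delta_u > 0, rho >= 0, max_rate > 0")
        if self.reset_mode not in ("reset", "none", "lif"):
            raise ValueError(f"unknown reset_mode {self.reset_mode!r}")


@dataclass
class SimConfig:
    dt: float = 0.1  # ms
    T: float = 500.0  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.dt))


def escape_rate(u, params: NeuronParams):
    """Instantaneous firing rate phi(u) = rho * exp((u - u_th)/delta_u) in
    Hz, saturating at ``max_rate`` (a refractory-like ceiling far above
    the operating regime that also keeps the exponential bounded)."""
    x = np.minimum((np.asarray(u, dtype=np.float64) - params.u_th) / params.delta_u, _MAX_EXP_ARG)
    return np.minimum(params.rho * np.exp(x), params.max_rate)


def spike_probability(rate_hz, dt_ms: float):
    """Probability of at least one spike of an inhomogeneous Poisson
    process with the given rate within one step."""
    return -np.expm1(-np.asarray(rate_hz) * dt_ms * 1e-3)


class Propagators(NamedTuple):
    em: float  # membrane decay exp(-dt/tau_m)
    es: float  # synaptic decay exp(-dt/tau_syn)
    p21: float  # current->membrane coupling over one step


def propagators(tau_m: float, tau_syn: float, dt: float) -> Propagators:
    """Exact one-step propagators of the membrane/current subsystem
    du/dt = -(u - u_rest)/tau_m + I,  dI/dt = -I/tau_syn."""
    em = math.exp(-dt / tau_m)
    es = math.exp(-dt / tau_syn)
    if abs(tau_m - tau_syn) < 1e-12:
        p21 = dt * em
    else:
        p21 = (es - em) / (1.0 / tau_m - 1.0 / tau_syn)
    return Propagators(em, es, p21)


def exp_filter(x: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Causal exponential filtering y[k] = decay * y[k-1] + x[k]."""
    decay = math.exp(-dt / tau)
    return lfilter([1.0], [1.0, -decay], np.asarray(x, dtype=np.float64), axis=-1)


def times_to_steps(times: Sequence[float], dt: float) -> np.ndarray:
    return np.floor(np.asarray(times, dtype=np.float64) / dt).astype(np.int64)


def filter_spikes(times: Sequence[float], tau: float, dt: float, n_steps: int) -> np.ndarray:
    """Spike train filtered by a causal exponential kernel with unit jump
    per spike, evaluated on the simulation grid."""
    x = np.zeros(n_steps)
    steps = times_to_steps(times, dt)
    steps = steps[(steps >= 0) & (steps < n_steps)]
    np.add.at(x, steps, 1.0)
    return exp_filter(x, tau, dt)


def poisson_times(rate_hz: float, T_ms: float, rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson spike times on [0, T), sorted and strictly
    increasing."""
    if rate_hz <= 0 or T_ms <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * T_ms * 1e-3)
    return np.unique(rng.uniform(0.0, T_ms, size=n))


def frozen_pattern(
    n_neurons: int, T_pattern: float, rate_hz: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Draw a frozen-noise spatio-temporal pattern: one homogeneous
    Poisson train per neuron, fixed once and replayed identically.
    Neurons with at least one spike are the 'pattern neurons'."""
    return [poisson_times(rate_hz, T_pattern, rng) for _ in range(n_neurons)]


class BalancedRates(NamedTuple):
    alpha: float
    nu_inter: float
    nu_pattern: float


def balanced_rate_factor(T_pattern: float, T_inter: float, nu: float) -> BalancedRates:
    """Rate-balance factor for pattern neurons between pattern replays.

    Background neurons spike at ``nu`` during inter segments only, giving
    an average rate nu_inter = nu * T_inter/(T_inter + T_pattern).  A
    pattern neuron spikes once per replay (nu_pattern = 1/(T_inter +
    T_pattern)); scaling its inter-segment rate by alpha = 1 -
    nu_pattern/nu_inter equalizes the average rates, removing rate as a
    cue for pattern detection.
    """
    if T_inter <= 0:
        raise ValueError("T_inter must be positive")
    cycle = T_inter + T_pattern
    nu_inter = nu * T_inter / cycle
    nu_pattern = 1000.0 / cycle  # one spike per cycle, in Hz (cycle in ms)
    if nu_inter <= 0 or nu_pattern > nu_inter:
        raise ValueError("pattern rate exceeds achievable balance; increase nu or T_inter")
    alpha = 1.0 - nu_pattern / nu_inter
    assert 0.0 <= alpha <= 1.0
    return BalancedRates(alpha, nu_inter, nu_pattern)


def subthreshold_potential(
    current: np.ndarray, params: NeuronParams, dt: float
) -> np.ndarray:
    """Membrane potential of a non-spiking (free) leaky integrator driven
    by a per-step synaptic current trace, integrated exactly."""
    em, _, p21 = propagators(params.tau_m, params.tau_syn, dt)
    drive = lfilter([p21], [1.0, -em], np.asarray(current, dtype=np.float64))
    return params.u_rest + drive


def simulate_escape_neuron(
    current: np.ndarray,
    params: NeuronParams,
    dt: float,
    rng: np.random.Generator,
    record_u: bool = True,
) -> tuple[np.ndarray | None, np.ndarray]:
    """Step an escape-noise neuron driven by a per-step current trace.

    ``current[k]`` is the synaptic current at step k (already filtered by
    tau_syn).  Returns (u_trace, spike_steps).  With ``reset_mode ==
    "reset"`` the membrane jumps back to rest right after a spike; with
    ``"none"`` spikes are emitted without affecting the dynamics.
    """
    n = len(current)
    em, _, p21 = propagators(params.tau_m, params.tau_syn, dt)
    u_rest, u_th, delta_u = params.u_rest, params.u_th, params.delta_u
    rho, max_rate = params.rho, params.max_rate
    dt_s = 1e-3 * dt
    do_reset = params.reset_mode == "reset"
    if params.reset_mode == "lif":
        raise ValueError("use the event-driven LIF path for hard-threshold neurons")
    draws = rng.random(n)
    u_trace = np.empty(n) if record_u else None
    spikes = []
    exp = math.exp
    v = 0.0  # u - u_rest
    for k in range(n):
        v = v * em + p21 * current[k]
        if record_u:
            u_trace[k] = u_rest + v
        x = (v + u_rest - u_th) / delta_u
        rate = max_rate if x > _MAX_EXP_ARG else rho * exp(x)
        if rate > max_rate:
            rate = max_rate
        if draws[k] < -math.expm1(-rate * dt_s):
            spikes.append(k)
            if do_reset:
                v = 0.0
    return u_trace, np.asarray(spikes, dtype=np.int64)
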