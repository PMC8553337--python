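"""Correlation-driven learning: detecting a frozen-noise pattern with
STDP and homeostasis.

N inputs drive a single hard-threshold LIF neuron with delta-shaped
postsynaptic currents.  A frozen-noise spike pattern of duration
T_pattern is replayed every T_inter, with Poisson background spiking in
between.  Pattern neurons (those that spike inside the pattern) have
their inter-pattern rate scaled by the balance factor alpha so that
average rates carry no information — only the spatio-temporal structure
does.

Plasticity is pairing-based STDP with weight dependence plus
weight-dependent homeostasis:

    dw_STDP = eta * { f_dep(w, E)  if dt < 0  (anticausal)
                      f_fac(w, E)  if dt >= 0 (causal) }
    dw_hom  = eta * { f_pre_hom(w)  on a presynaptic spike
                      f_post_hom(w) on a postsynaptic spike }

with E = exp(-|dt|/tau), dt = t_post - t_pre, nearest-spike pairing, and
weights clipped to [0, 1] after every update.

Fitness is the minimal signal-to-noise ratio across experiments, where
the SNR compares the free membrane potential (spiking disabled, frozen
weights) during pattern windows against the inter-pattern statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.signal import lfilter

from .cgp import InvalidEvaluation
from .neurosim import balanced_rate_factor, frozen_pattern, poisson_times

__all__ = [
    "CorrTaskConfig",
    "STDPRule",
    "PairingEvent",
    "stdp_update",
    "clip_weight",
    "Experiment",
    "make_experiment",
    "generate_cycles",
    "train",
    "free_membrane_trace",
    "run_spiking",
    "snr",
    "snr_of_weights",
    "detection_stats",
    "fitness_corr",
    "reference_stdp_rules",
    "kernel_table",
]


@dataclass
class CorrTaskConfig:
    n_inputs: int = 500
    nu: float = 5.0  # Hz, pattern-draw and background rate
    T_pattern: float = 100.0  # ms
    T_inter: float = 400.0  # ms
    tau: float = 20.0  # eligibility decay (ms)
    eta: float = 0.01
    w_hom: float = -0.3  # constant post-triggered homeostatic term (baseline rule)
    n_experiments: int = 3
    n_train_cycles: int = 200
    n_eval_cycles: int = 20
    dt: float = 0.1
    w_init_low: float = 0.3
    w_init_high: float = 0.7
    J: float = 2.0  # PSP jump (mV) per unit weight
    tau_m: float = 10.0
    u_rest: float = -70.0
    u_th: float = -60.0
    inter_margin: float = 50.0  # ms excluded from inter stats after each pattern

    @property
    def cycle(self) -> float:
        return self.T_pattern + self.T_inter


@dataclass
class STDPRule:
    """The four branches of a correlation-driven rule.  ``f_dep`` and
    ``f_fac`` take (w, E); the homeostatic branches take w only.  All
    must accept numpy arrays.  ``w_floor`` lifts the lower weight bound
    for rules that divide by w."""

    f_dep: Callable  # anticausal pairing, dt < 0
    f_fac: Callable  # causal pairing, dt >= 0
    f_pre_hom: Callable
    f_post_hom: Callable
    w_floor: float = 0.0
    name: str = ""


@dataclass(frozen=True)
class PairingEvent:
    """A nearest-spike pre/post pairing with dt = t_post - t_pre."""

    delta_t: float  # ms
    tau: float

    @property
    def eligibility(self) -> float:
        return math.exp(-abs(self.delta_t) / self.tau)


def clip_weight(w, floor: float = 0.0):
    return np.clip(w, floor, 1.0)


def stdp_update(rule: STDPRule, w: float, event: PairingEvent, eta: float) -> float:
    """Weight change for one pairing event including the homeostatic term
    of the triggering spike (presynaptic for anticausal pairings,
    postsynaptic for causal ones).  The caller clips after application."""
    E = event.eligibility
    try:
        if event.delta_t < 0:
            val = rule.f_dep(w, E) + rule.f_pre_hom(w)
        else:
            val = rule.f_fac(w, E) + rule.f_post_hom(w)
        dw = eta * float(val)
    except ZeroDivisionError as exc:
        raise InvalidEvaluation("STDP rule divided by zero") from exc
    if not math.isfinite(dw):
        raise InvalidEvaluation("STDP rule produced a non-finite weight change")
    return dw


# ---------------------------------------------------------------------------
# experiment construction


@dataclass
class Experiment:
    config: CorrTaskConfig
    pattern_steps: np.ndarray  # spike time (ms) per pattern spike
    pattern_syn: np.ndarray  # synapse index per pattern spike
    is_pattern_neuron: np.ndarray  # bool mask, length N
    alpha: float


def make_experiment(config: CorrTaskConfig, seed: int) -> Experiment:
    """Draw the frozen-noise pattern.  The raw Poisson draw is thinned to
    the first spike per neuron, which makes the alpha rate balance exact
    (pattern neurons contribute exactly one spike per replay)."""
    rng = np.random.default_rng(seed)
    raw = frozen_pattern(config.n_inputs, config.T_pattern, config.nu, rng)
    times, syn = [], []
    for j, tr in enumerate(raw):
        if tr.size:
            times.append(tr[0])
            syn.append(j)
    order = np.argsort(times)
    times = np.asarray(times)[order]
    syn = np.asarray(syn, dtype=np.int64)[order]
    mask = np.zeros(config.n_inputs, dtype=bool)
    mask[syn] = True
    alpha = balanced_rate_factor(config.T_pattern, config.T_inter, config.nu).alpha
    return Experiment(config, times, syn, mask, alpha)


def generate_cycles(
    exp: Experiment, n_cycles: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Input spikes for ``n_cycles`` pattern/inter alternations, as
    time-sorted (times, synapse) arrays.  Background neurons spike at nu
    during inter segments; pattern neurons at alpha*nu."""
    cfg = exp.config
    all_t, all_s = [], []
    for c in range(n_cycles):
        t0 = c * cfg.cycle
        all_t.append(t0 + exp.pattern_steps)
        all_s.append(exp.pattern_syn)
        for j in range(cfg.n_inputs):
            rate = cfg.nu * (exp.alpha if exp.is_pattern_neuron[j] else 1.0)
            tr = poisson_times(rate, cfg.T_inter, rng)
            if tr.size:
                all_t.append(t0 + cfg.T_pattern + tr)
                all_s.append(np.full(tr.size, j, dtype=np.int64))
    times = np.concatenate(all_t)
    syn = np.concatenate(all_s)
    order = np.argsort(times, kind="stable")
    return times[order], syn[order]


# ---------------------------------------------------------------------------
# training (event-driven LIF with plasticity)


def train(
    rule: STDPRule,
    exp: Experiment,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
    n_cycles: int | None = None,
) -> np.ndarray:
    """Train the plastic synapses on fresh input for ``n_cycles`` and
    return the final weights.

    Event-driven: between input spikes the membrane only decays (delta
    PSCs), so threshold crossings can only occur at spike arrivals.  The
    PSP jump uses the weight as it was when the spike arrived; plasticity
    then updates it for later spikes.
    """
    cfg = exp.config
    n_cycles = cfg.n_train_cycles if n_cycles is None else n_cycles
    times, syn = generate_cycles(exp, n_cycles, rng)
    if weights is None:
        weights = rng.uniform(cfg.w_init_low, cfg.w_init_high, size=cfg.n_inputs)
    w = clip_weight(np.asarray(weights, dtype=np.float64).copy(), rule.w_floor)
    floor = rule.w_floor
    eta, tau, J = cfg.eta, cfg.tau, cfg.J
    tau_m, theta_rel = cfg.tau_m, cfg.u_th - cfg.u_rest
    last_pre = np.full(cfg.n_inputs, -1e9)
    last_post = -1e9
    u = 0.0  # relative to rest
    t_prev = 0.0
    exp_f, isfinite = math.exp, math.isfinite
    for t, j in zip(times.tolist(), syn.tolist()):
        u *= exp_f(-(t - t_prev) / tau_m)
        t_prev = t
        wj = w[j]
        u += J * wj  # transmission with the pre-update weight
        # anticausal pairing + presynaptic homeostasis
        E = exp_f(-(t - last_post) / tau) if t - last_post < 500.0 else 0.0
        try:
            val = rule.f_dep(wj, E) + rule.f_pre_hom(wj)
        except ZeroDivisionError as exc:
            raise InvalidEvaluation("STDP rule divided by zero") from exc
        dw = eta * float(val)
        if not isfinite(dw):
            raise InvalidEvaluation("STDP rule produced a non-finite weight change")
        wj += dw
        w[j] = 1.0 if wj > 1.0 else (floor if wj < floor else wj)
        last_pre[j] = t
        if u >= theta_rel:
            u = 0.0  # reset
            Evec = np.exp(np.maximum((last_pre - t) / tau, -700.0))
            dwv = eta * (rule.f_fac(w, Evec) + rule.f_post_hom(w))
            if not np.all(np.isfinite(dwv)):
                raise InvalidEvaluation("STDP rule produced a non-finite weight change")
            w = clip_weight(w + dwv, floor)
            last_post = t
    return w


# ---------------------------------------------------------------------------
# evaluation


def _jump_trace(
    weights: np.ndarray, times: np.ndarray, syn: np.ndarray, cfg: CorrTaskConfig, n_steps: int
) -> np.ndarray:
    h = np.zeros(n_steps)
    steps = np.floor(times / cfg.dt).astype(np.int64)
    ok = (steps >= 0) & (steps < n_steps)
    np.add.at(h, steps[ok], cfg.J * weights[syn[ok]])
    return h


def free_membrane_trace(
    weights: np.ndarray, times: np.ndarray, syn: np.ndarray, cfg: CorrTaskConfig, n_steps: int
) -> np.ndarray:
    """Subthreshold membrane potential with the spiking mechanism
    disabled (frozen weights): exact decay-and-jump integration on the
    simulation grid."""
    d = math.exp(-cfg.dt / cfg.tau_m)
    h = _jump_trace(weights, times, syn, cfg, n_steps)
    return cfg.u_rest + lfilter([1.0], [1.0, -d], h)


def run_spiking(
    weights: np.ndarray, times: np.ndarray, syn: np.ndarray, cfg: CorrTaskConfig, n_steps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Hard-threshold LIF with frozen weights: returns (u trace, spike
    steps)."""
    d = math.exp(-cfg.dt / cfg.tau_m)
    h = _jump_trace(weights, times, syn, cfg, n_steps)
    u = np.empty(n_steps)
    theta_rel = cfg.u_th - cfg.u_rest
    v = 0.0
    spikes = []
    for k in range(n_steps):
        v = v * d + h[k]
        if v >= theta_rel:
            spikes.append(k)
            v = 0.0
            u[k] = cfg.u_th  # clamp the sample at threshold for display
        else:
            u[k] = cfg.u_rest + v
    return u, np.asarray(spikes, dtype=np.int64)


def snr(u_max_per_pattern: Sequence[float], u_inter: Sequence[float]) -> float:
    """(mean pattern-window maximum - mean inter level) / Std(inter)."""
    u_max = np.asarray(u_max_per_pattern, dtype=np.float64)
    inter = np.asarray(u_inter, dtype=np.float64)
    if u_max.size < 2 or inter.size < 1:
        raise ValueError("need >= 2 pattern windows and >= 1 inter sample")
    std = float(np.std(inter))
    if std == 0.0:
        warnings.warn("zero inter-pattern variance; SNR undefined, reporting +inf")
        return float("inf")
    return float((np.mean(u_max) - np.mean(inter)) / std)


def _window_indices(cfg: CorrTaskConfig, n_cycles: int, n_steps: int):
    k_cycle = int(round(cfg.cycle / cfg.dt))
    k_pat = int(round(cfg.T_pattern / cfg.dt))
    k_margin = int(round(cfg.inter_margin / cfg.dt))
    pattern, inter = [], []
    for c in range(n_cycles):
        a = c * k_cycle
        pattern.append((a, min(a + k_pat, n_steps)))
        inter.append((min(a + k_pat + k_margin, n_steps), min(a + k_cycle, n_steps)))
    return pattern, inter


def snr_of_weights(
    weights: np.ndarray, exp: Experiment, rng: np.random.Generator
) -> float:
    """SNR of the free membrane potential on fresh evaluation input
    (same frozen pattern, new background)."""
    cfg = exp.config
    times, syn = generate_cycles(exp, cfg.n_eval_cycles, rng)
    n_steps = int(round(cfg.n_eval_cycles * cfg.cycle / cfg.dt))
    u = free_membrane_trace(weights, times, syn, cfg, n_steps)
    pat, inter = _window_indices(cfg, cfg.n_eval_cycles, n_steps)
    u_max = [u[a:b].max() for a, b in pat if b > a]
    u_inter = np.concatenate([u[a:b] for a, b in inter if b > a])
    return snr(u_max, u_inter)


def detection_stats(
    weights: np.ndarray, exp: Experiment, rng: np.random.Generator
) -> tuple[float, float]:
    """Fractions of (pattern windows with >= 1 output spike, inter
    windows of equal length with >= 1 spike), with spiking enabled."""
    cfg = exp.config
    times, syn = generate_cycles(exp, cfg.n_eval_cycles, rng)
    n_steps = int(round(cfg.n_eval_cycles * cfg.cycle / cfg.dt))
    _, spikes = run_spiking(weights, times, syn, cfg, n_steps)
    spiked = np.zeros(n_steps, dtype=bool)
    spiked[spikes] = True
    k_cycle = int(round(cfg.cycle / cfg.dt))
    k_pat = int(round(cfg.T_pattern / cfg.dt))
    n_sub = int(cfg.T_inter // cfg.T_pattern)
    pat_hits, inter_hits, n_inter = 0, 0, 0
    for c in range(cfg.n_eval_cycles):
        a = c * k_cycle
        if spiked[a : a + k_pat].any():
            pat_hits += 1
        for s in range(n_sub):
            b = a + k_pat + s * k_pat
            if b + k_pat <= n_steps:
                n_inter += 1
                if spiked[b : b + k_pat].any():
                    inter_hits += 1
    return pat_hits / cfg.n_eval_cycles, inter_hits / max(n_inter, 1)


def fitness_corr(
    rule: STDPRule, config: CorrTaskConfig, seeds: Sequence[int]
) -> float:
    """Minimal SNR across experiments; each experiment draws a fresh
    pattern and background, trains from random initial weights, and
    measures the SNR with the final weights frozen."""
    if len(seeds) < 1:
        raise ValueError("need at least one experiment seed")
    snrs = []
    try:
        for s in seeds:
            exp = make_experiment(config, int(s))
            rng = np.random.default_rng(int(s) + 1_000_003)
            w = train(rule, exp, rng)
            snrs.append(snr_of_weights(w, exp, rng))
    except InvalidEvaluation:
        return float("-inf")
    return float(np.min(snrs))


# ---------------------------------------------------------------------------
# reference rules


def reference_stdp_rules(w_hom: float = -0.3) -> dict[str, STDPRule]:
    """Baseline homeostatic STDP plus the two discovered rules.

    ``baseline``: no anticausal pairing; causal potentiation by E; a
    constant depressing homeostatic term (w_hom < 0) per postsynaptic
    spike.
    ``LR1``: potentiates both branches (-(w-1)E >= 0 on [0,1]); +w per
    presynaptic, -w per postsynaptic spike.
    ``LR2``: punishes anticausal pairings by -E/w (hence the weight
    floor), causal (wE)^w; +w per presynaptic spike, -1 per postsynaptic.
    """
    zero = lambda *a: 0.0
    return {
        "baseline": STDPRule(
            f_dep=lambda w, E: 0.0 * E,
            f_fac=lambda w, E: E,
            f_pre_hom=zero,
            f_post_hom=lambda w: w_hom * np.ones_like(np.asarray(w, dtype=np.float64)),
            name="baseline",
        ),
        "LR1": STDPRule(
            f_dep=lambda w, E: -(w - 1.0) * E,
            f_fac=lambda w, E: E,
            f_pre_hom=lambda w: w,
            f_post_hom=lambda w: -w,
            name="LR1",
        ),
        "LR2": STDPRule(
            f_dep=lambda w, E: -E / w,
            f_fac=lambda w, E: (w * E) ** w,
            f_pre_hom=lambda w: w,
            f_post_hom=lambda w: -np.ones_like(np.asarray(w, dtype=np.float64)),
            w_floor=1e-3,
            name="LR2",
        ),
    }


def kernel_table(
    rule: STDPRule, weights: Sequence[float], delta_ts: Sequence[float], tau: float
) -> np.ndarray:
    """STDP kernel samples for plotting: rows (w, delta_t, dw/eta) for the
    pairing branches (homeostatic terms excluded)."""
    rows = []
    for w in weights:
        for dt_ in delta_ts:
            E = math.exp(-abs(dt_) / tau)
            val = rule.f_dep(w, E) if dt_ < 0 else rule.f_fac(w, E)
            rows.append((w, dt_, float(val)))
    return np.asarray(rows)
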