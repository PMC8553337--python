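"""Glue between the CGP engine, the evolution loop and the task
environments: run configuration, per-task fitness adapters, rule
evaluation reports and deterministic test fixtures.

Configuration is TOML with strict schema checking (unknown keys are
rejected), logs are JSON-lines, spike/trace dumps are CSV — all
line-oriented and diffable.  Every stochastic component derives its seed
from the single run seed.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import correlation, error, reward
from .cgp import CompiledRule, ExpressionGraph, GraphDims, PrimitiveSet, default_primitives, evaluate
from .evolution import EvolutionParams, EvolutionState, evolve

__all__ = [
    "RunConfig",
    "load_run_config",
    "dump_run_config",
    "toy_regression_fitness",
    "task_setup",
    "run_evolution",
    "eval_rule",
    "make_fixtures",
    "stdp_rule_from_graph",
]

TASKS = ("toy", "reward", "error", "correlation")

_TASK_CONFIGS = {
    "toy": None,
    "reward": reward.RewardTaskConfig,
    "error": error.ErrorTaskConfig,
    "correlation": correlation.CorrTaskConfig,
}


@dataclass
class RunConfig:
    task: str = "toy"
    seed: int = 0
    out_dir: str = "runs"
    evolution: EvolutionParams = field(default_factory=EvolutionParams)
    task_config: object = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; choose from {TASKS}")
        if self.task_config is None and _TASK_CONFIGS[self.task] is not None:
            self.task_config = _TASK_CONFIGS[self.task]()


def _apply_section(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in [{where}]")
    return cls(**data)


def load_run_config(path) -> RunConfig:
    """Read a TOML run configuration.  Sections: top-level ``task``,
    ``seed``, ``out_dir``; ``[evolution]``; ``[task_config]`` (fields of
    the task's config dataclass); optional ``[task_config.neuron]``."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    top = {k: v for k, v in raw.items() if k not in ("evolution", "task_config")}
    unknown = set(top) - {"task", "seed", "out_dir"}
    if unknown:
        raise ValueError(f"unknown top-level key(s) {sorted(unknown)}")
    task = top.get("task", "toy")
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    evo = _apply_section(EvolutionParams, raw.get("evolution", {}), "evolution")
    tc_cls = _TASK_CONFIGS[task]
    tc_data = dict(raw.get("task_config", {}))
    task_config = None
    if tc_cls is not None:
        neuron_data = tc_data.pop("neuron", None)
        task_config = _apply_section(tc_cls, tc_data, "task_config")
        if neuron_data is not None:
            from .neurosim import NeuronParams

            task_config.neuron = _apply_section(NeuronParams, neuron_data, "task_config.neuron")
    elif tc_data:
        raise ValueError("the toy task takes no [task_config]")
    return RunConfig(
        task=task,
        seed=int(top.get("seed", 0)),
        out_dir=str(top.get("out_dir", "runs")),
        evolution=evo,
        task_config=task_config,
    )


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return json.dumps(str(v))


def dump_run_config(cfg: RunConfig, path) -> None:
    """Serialize a RunConfig back to TOML (lossless round-trip)."""
    lines = [f"task = {_toml_value(cfg.task)}", f"seed = {_toml_value(cfg.seed)}",
             f"out_dir = {_toml_value(cfg.out_dir)}", "", "[evolution]"]
    for f in dataclasses.fields(EvolutionParams):
        lines.append(f"{f.name} = {_toml_value(getattr(cfg.evolution, f.name))}")
    if cfg.task_config is not None:
        lines.append("")
        lines.append("[task_config]")
        neuron = None
        for f in dataclasses.fields(type(cfg.task_config)):
            val = getattr(cfg.task_config, f.name)
            if f.name == "neuron":
                neuron = val
                continue
            lines.append(f"{f.name} = {_toml_value(val)}")
        if neuron is not None:
            lines.append("")
            lines.append("[task_config.neuron]")
            for f in dataclasses.fields(type(neuron)):
                lines.append(f"{f.name} = {_toml_value(getattr(neuron, f.name))}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# fitness adapters


def toy_regression_fitness(graph: ExpressionGraph, sample_seeds: tuple[int, ...]) -> float:
    """Symbolic-regression smoke task: fit f(x) = x0*x2 on random probe
    points; fitness is the negative sum of squared errors."""
    total = 0.0
    for s in sample_seeds:
        rng = np.random.default_rng(s)
        x = rng.uniform(-2.0, 2.0, size=(3, 20))
        y = evaluate(graph, list(x))[0]
        total += float(np.sum((y - x[0] * x[2]) ** 2))
    return -total


def stdp_rule_from_graph(graph: ExpressionGraph) -> correlation.STDPRule:
    """Build the four branches of a correlation-driven rule from a single
    two-input (w, E), four-output phenotype.

    Outputs are (f_dep, f_fac, f_pre_hom, f_post_hom); the homeostatic
    branches see E masked to zero, so they depend on the weight only.
    """
    if graph.n_inputs != 2 or graph.n_outputs != 4:
        raise ValueError("correlation rules need 2 inputs (w, E) and 4 outputs")

    def branch(i: int, mask_E: bool):
        def f(w, E=None):
            e = 0.0 if mask_E else E
            return evaluate(graph, [w, e])[i]

        return f

    return correlation.STDPRule(
        f_dep=branch(0, False),
        f_fac=branch(1, False),
        f_pre_hom=branch(2, True),
        f_post_hom=branch(3, True),
        w_floor=1e-3,
        name=graph.key,
    )


def task_setup(cfg: RunConfig):
    """Return (fitness_fn, dims, primitives) for a run configuration.

    Fitness conventions per task family: accumulated ("paper"-scale)
    reward, mean-aggregated; negative RMSE, mean-aggregated; minimal SNR.
    """
    task = cfg.task
    if task == "toy":
        prims = default_primitives()
        return toy_regression_fitness, GraphDims(n_inputs=3, n_outputs=1, n_columns=6), prims

    if task == "reward":
        tc = cfg.task_config
        n_in = 3 if tc.baseline_mode == "joint" else 4
        prims = default_primitives()
        dims = GraphDims(n_inputs=n_in, n_outputs=1, n_columns=12)

        def fitness_fn(graph, sample_seeds):
            rule = reward.wrap_compiled_rule(CompiledRule.from_graph(graph), tc.baseline_mode)
            return reward.fitness_reward(rule, tc, sample_seeds, scale="paper")

        return fitness_fn, dims, prims

    if task == "error":
        tc = cfg.task_config
        prims = default_primitives()
        dims = GraphDims(n_inputs=3, n_outputs=1, n_columns=12)

        def fitness_fn(graph, sample_seeds):
            rule = error.wrap_compiled_rule(CompiledRule.from_graph(graph))
            return error.fitness_error(rule, tc, sample_seeds)

        return fitness_fn, dims, prims

    if task == "correlation":
        tc = cfg.task_config
        prims = default_primitives(with_power=True)
        dims = GraphDims(n_inputs=2, n_outputs=4, n_columns=12)

        def fitness_fn(graph, sample_seeds):
            rule = stdp_rule_from_graph(graph)
            return correlation.fitness_corr(rule, tc, sample_seeds)

        return fitness_fn, dims, prims

    raise ValueError(f"unknown task {task!r}")


def run_evolution(cfg: RunConfig) -> EvolutionState:
    """Drive a full evolutionary run; writes the per-generation JSON-lines
    log, the best expression and a config snapshot into ``out_dir``."""
    fitness_fn, dims, prims = task_setup(cfg)
    params = dataclasses.replace(cfg.evolution, seed=cfg.seed)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state = evolve(fitness_fn, dims, prims, params, log_path=out / "evolution_log.jsonl")
    best = state.best
    (out / "best_expression.txt").write_text(best.key + "\n")
    (out / "best_genome.json").write_text(best.genome.to_json(prims) + "\n")
    dump_run_config(cfg, out / "config_snapshot.toml")
    return state


# ---------------------------------------------------------------------------
# rule evaluation reports


def eval_rule(
    task: str,
    expression: str,
    task_config=None,
    seeds=(0, 1, 2, 3, 4),
    baseline_mode: str = "split",
) -> dict:
    """Evaluate a plasticity rule (infix expression, or a named reference
    rule) and report per-experiment and aggregate fitness.

    Reward-task expressions are read as f(x0=R, x1=E, x2=Rbar+, x3=Rbar-)
    in ``split`` baseline mode, or f(x0=R, x1=E, x2=Rbar) in ``joint``
    mode; unused trailing inputs are permitted (e.g. "(x0 - 1)*x1")."""
    seeds = [int(s) for s in seeds]
    if task == "reward":
        tc = task_config or reward.RewardTaskConfig()
        if expression in reward.reference_rules():
            fn = reward.reference_rules()[expression]
        else:
            n_in = 3 if baseline_mode == "joint" else 4
            rule = CompiledRule.from_expression(
                expression, [f"x{i}" for i in range(n_in)]
            )
            fn = reward.wrap_compiled_rule(rule, baseline_mode)
        per = [float(np.mean(reward.run_experiment(fn, tc, s))) * tc.n_trials for s in seeds]
        agg = float(np.mean(per))
    elif task == "error":
        tc = task_config or error.ErrorTaskConfig()
        if expression in error.reference_rules():
            fn = error.reference_rules()[expression]
        else:
            fn = error.wrap_compiled_rule(CompiledRule.from_expression(expression))
        per = [-error.rmse(*(lambda r: (r.v, r.u))(error.run_error_trial(fn, tc, s))) for s in seeds]
        agg = float(np.mean(per))
    elif task == "correlation":
        tc = task_config or correlation.CorrTaskConfig()
        rules = correlation.reference_stdp_rules(tc.w_hom)
        if expression not in rules:
            raise ValueError(
                f"correlation rules are selected by name, one of {sorted(rules)}"
            )
        rule = rules[expression]
        per = []
        for s in seeds:
            exp = correlation.make_experiment(tc, s)
            rng = np.random.default_rng(s + 1_000_003)
            w = correlation.train(rule, exp, rng)
            per.append(correlation.snr_of_weights(w, exp, rng))
        agg = float(np.min(per))
    else:
        raise ValueError(f"eval-rule supports tasks reward/error/correlation, not {task!r}")
    return {
        "task": task,
        "rule": expression,
        "per_experiment": per,
        "mean": float(np.mean(per)),
        "std": float(np.std(per)),
        "aggregate": agg,
    }


# ---------------------------------------------------------------------------
# fixtures


def make_fixtures(seed: int, out_dir) -> dict[str, Path]:
    """Write deterministic miniature task instances (CSV/JSON) used by the
    unit-test suite and by examples."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}

    # miniature frozen-pattern set (reward task flavor)
    from .neurosim import frozen_pattern

    patterns = [frozen_pattern(10, 200.0, 10.0, rng) for _ in range(2)]
    lines = ["pattern,neuron_id,time_ms"]
    for p, trains in enumerate(patterns):
        for j, times in enumerate(trains):
            lines += [f"{p},{j},{t:.4f}" for t in times]
    paths["reward_patterns"] = out / "reward_patterns.csv"
    paths["reward_patterns"].write_text("\n".join(lines) + "\n")

    # miniature teacher configuration (error task flavor)
    teacher = {
        "rates_hz": rng.uniform(10.0, 50.0, size=5).round(4).tolist(),
        "teacher_weights": rng.uniform(2.0, 10.0, size=5).round(4).tolist(),
        "student_w0": 6.0,
    }
    paths["teacher_config"] = out / "teacher_config.json"
    paths["teacher_config"].write_text(json.dumps(teacher, indent=1) + "\n")

    # miniature correlation pattern
    cfg = correlation.CorrTaskConfig(n_inputs=30, n_train_cycles=5, n_eval_cycles=3)
    exp = correlation.make_experiment(cfg, seed)
    lines = ["neuron_id,time_ms"]
    lines += [f"{j},{t:.4f}" for t, j in zip(exp.pattern_steps, exp.pattern_syn)]
    paths["correlation_pattern"] = out / "correlation_pattern.csv"
    paths["correlation_pattern"].write_text("\n".join(lines) + "\n")
    return paths
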