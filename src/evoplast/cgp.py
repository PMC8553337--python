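"""Cartesian genetic programming over symbolic plasticity rules.

A candidate plasticity rule is encoded as a fixed-size two-dimensional
Cartesian graph (the genotype).  Each internal node carries one operator
gene and a fixed number of input genes (node indices); output nodes each
carry a single source-node index.  Decoding walks backwards from the
outputs and yields the active computational subgraph (the phenotype),
which defines a function f from named local synaptic quantities to a
weight change.  Genes of nodes outside the active subgraph can mutate
without changing the phenotype ("silent" mutations), which is what makes
phenotype-level fitness caching effective.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "InvalidEvaluation",
    "Operator",
    "PrimitiveSet",
    "default_primitives",
    "GraphDims",
    "Genome",
    "ExpressionGraph",
    "CompiledRule",
    "random_genome",
    "decode",
    "evaluate",
    "mutate",
    "expression_key",
]


class InvalidEvaluation(Exception):
    """A rule produced a non-finite value (e.g. division by zero).

    Consumers map this onto a fitness of -inf; it must never silently
    propagate NaN/inf into simulation state.
    """


@dataclass(frozen=True)
class Operator:
    """A computational primitive: a name, an arity, numpy semantics and
    an infix format string used to build canonical expressions."""

    name: str
    arity: int
    func: Callable[..., np.ndarray]
    fmt: str

    def format(self, *args: str) -> str:
        return self.fmt.format(*args)


def _const_op(value: float) -> Operator:
    v = float(value)
    text = repr(v)
    return Operator(name=f"const_{text}", arity=0, func=lambda v=v: np.float64(v), fmt=text)


@dataclass(frozen=True)
class PrimitiveSet:
    """Ordered collection of operators and constant-output nodes.

    Constants are represented internally as zero-arity operators appended
    after the proper operators, so a single operator gene indexes into
    ``all_ops``.
    """

    operators: tuple[Operator, ...]
    constants: tuple[float, ...] = ()

    @property
    def all_ops(self) -> tuple[Operator, ...]:
        return self.operators + tuple(_const_op(c) for c in self.constants)

    @property
    def max_arity(self) -> int:
        return max((op.arity for op in self.operators), default=1)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(op.name for op in self.all_ops)


_ADD = Operator("add", 2, np.add, "({} + {})")
_SUB = Operator("sub", 2, np.subtract, "({} - {})")
_MUL = Operator("mul", 2, np.multiply, "({} * {})")
_DIV = Operator("div", 2, np.true_divide, "({} / {})")  # unprotected on purpose
_POW = Operator("pow", 2, np.power, "({} ** {})")


def default_primitives(with_power: bool = False, constants: Sequence[float] = (1.0, 0.5)) -> PrimitiveSet:
    """Arithmetic set {+, -, *, /} plus constant nodes.

    Division is deliberately unprotected: non-finite intermediates raise
    :class:`InvalidEvaluation`, which evolution turns into fitness -inf.
    ``with_power`` opts in a binary power operator, needed e.g. for rules
    of the form (w*E)**w.
    """
    ops = (_ADD, _SUB, _MUL, _DIV) + ((_POW,) if with_power else ())
    return PrimitiveSet(operators=ops, constants=tuple(float(c) for c in constants))


@dataclass(frozen=True)
class GraphDims:
    """Dimensions of the Cartesian graph."""

    n_inputs: int
    n_outputs: int = 1
    n_rows: int = 1
    n_columns: int = 12
    levels_back: int | None = None  # None -> full column range

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_outputs < 1 or self.n_rows < 0 or self.n_columns < 0:
            raise ValueError("inconsistent graph dimensions")
        if self.n_rows * self.n_columns < 1 and self.n_outputs > 0 and self.n_inputs < 1:
            raise ValueError("graph needs at least one selectable node")

    @property
    def n_internal(self) -> int:
        return self.n_rows * self.n_columns

    @property
    def effective_levels_back(self) -> int:
        return self.n_columns if self.levels_back is None else self.levels_back


@dataclass
class Genome:
    """Cartesian genotype: per internal node one operator gene plus
    ``max_arity`` input genes, and one source gene per output.

    Node ids: inputs are 0..n_inputs-1, internal node i is n_inputs+i
    (column-major: column = i // n_rows).
    """

    dims: GraphDims
    internal_genes: np.ndarray  # shape (n_internal, 1 + max_arity), int
    output_genes: np.ndarray  # shape (n_outputs,), int

    def column_of(self, internal_index: int) -> int:
        return internal_index // self.dims.n_rows

    def allowed_sources(self, column: int) -> np.ndarray:
        """Node ids an internal node in ``column`` may read from."""
        d = self.dims
        first_col = max(0, column - d.effective_levels_back)
        lo = d.n_inputs + first_col * d.n_rows
        hi = d.n_inputs + column * d.n_rows
        return np.concatenate([np.arange(d.n_inputs), np.arange(lo, hi)])

    def validate(self, primitives: PrimitiveSet) -> None:
        d = self.dims
        n_ops = len(primitives.all_ops)
        for i in range(d.n_internal):
            op = self.internal_genes[i, 0]
            if not 0 <= op < n_ops:
                raise ValueError(f"node {d.n_inputs + i}: operator gene {op} out of range")
            allowed = set(self.allowed_sources(self.column_of(i)).tolist())
            for a in range(primitives.max_arity):
                if int(self.internal_genes[i, 1 + a]) not in allowed:
                    raise ValueError(f"node {d.n_inputs + i}: dangling input gene")
        n_nodes = d.n_inputs + d.n_internal
        for o in self.output_genes:
            if not 0 <= o < n_nodes:
                raise ValueError(f"output gene {o} references missing node")

    def copy(self) -> "Genome":
        return Genome(self.dims, self.internal_genes.copy(), self.output_genes.copy())

    # -- serialization -------------------------------------------------
    def to_json(self, primitives: PrimitiveSet | None = None) -> str:
        d = self.dims
        payload = {
            "dims": {
                "n_inputs": d.n_inputs,
                "n_outputs": d.n_outputs,
                "n_rows": d.n_rows,
                "n_columns": d.n_columns,
                "levels_back": d.levels_back,
            },
            "internal_genes": self.internal_genes.tolist(),
            "output_genes": self.output_genes.tolist(),
        }
        if primitives is not None:
            payload["primitives"] = list(primitives.names)
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "Genome":
        payload = json.loads(text)
        dims = GraphDims(**payload["dims"])
        return cls(
            dims=dims,
            internal_genes=np.asarray(payload["internal_genes"], dtype=np.int64).reshape(dims.n_internal, -1),
            output_genes=np.asarray(payload["output_genes"], dtype=np.int64),
        )


def random_genome(dims: GraphDims, primitives: PrimitiveSet, rng: np.random.Generator) -> Genome:
    """Draw a genome uniformly over legal gene values."""
    d = dims
    n_ops = len(primitives.all_ops)
    genes = np.zeros((d.n_internal, 1 + primitives.max_arity), dtype=np.int64)
    proto = Genome(d, genes, np.zeros(d.n_outputs, dtype=np.int64))
    for i in range(d.n_internal):
        genes[i, 0] = rng.integers(n_ops)
        allowed = proto.allowed_sources(proto.column_of(i))
        genes[i, 1:] = rng.choice(allowed, size=primitives.max_arity, replace=True)
    n_nodes = d.n_inputs + d.n_internal
    proto.output_genes = rng.integers(n_nodes, size=d.n_outputs)
    return proto


@dataclass
class ExpressionGraph:
    """Decoded phenotype: active nodes in topological order, plus the
    canonical fully parenthesized infix expression per output."""

    n_inputs: int
    n_outputs: int
    # (node_id, operator, source node ids) in evaluation order
    nodes: tuple[tuple[int, Operator, tuple[int, ...]], ...]
    output_ids: tuple[int, ...]
    expressions: tuple[str, ...]

    @property
    def active_nodes(self) -> tuple[int, ...]:
        return tuple(n[0] for n in self.nodes)

    @property
    def arity(self) -> int:
        return self.n_inputs

    @property
    def key(self) -> str:
        return ";".join(self.expressions)


def decode(genome: Genome, primitives: PrimitiveSet) -> ExpressionGraph:
    """Backward-reachability decoding of a genotype into its phenotype.

    Only the first ``arity`` input genes of each node are coding; the
    remainder are non-coding padding up to ``max_arity``.
    """
    genome.validate(primitives)
    d = genome.dims
    ops = primitives.all_ops

    def node_op(node_id: int) -> Operator:
        return ops[int(genome.internal_genes[node_id - d.n_inputs, 0])]

    def node_sources(node_id: int) -> tuple[int, ...]:
        i = node_id - d.n_inputs
        op = ops[int(genome.internal_genes[i, 0])]
        return tuple(int(g) for g in genome.internal_genes[i, 1 : 1 + op.arity])

    # collect active internal nodes
    active: set[int] = set()
    stack = [int(o) for o in genome.output_genes if int(o) >= d.n_inputs]
    while stack:
        nid = stack.pop()
        if nid in active:
            continue
        active.add(nid)
        stack.extend(s for s in node_sources(nid) if s >= d.n_inputs)

    order = sorted(active)  # node ids increase along columns -> topological
    nodes = tuple((nid, node_op(nid), node_sources(nid)) for nid in order)

    exprs: dict[int, str] = {i: f"x{i}" for i in range(d.n_inputs)}
    for nid, op, srcs in nodes:
        exprs[nid] = op.format(*(exprs[s] for s in srcs))
    output_ids = tuple(int(o) for o in genome.output_genes)
    return ExpressionGraph(
        n_inputs=d.n_inputs,
        n_outputs=d.n_outputs,
        nodes=nodes,
        output_ids=output_ids,
        expressions=tuple(exprs[o] for o in output_ids),
    )


def evaluate(graph: ExpressionGraph, inputs: Sequence) -> list[np.ndarray]:
    """Evaluate the active subgraph at the given input vector.

    Inputs may be scalars or broadcastable numpy arrays.  Any non-finite
    intermediate (division by zero, overflow, 0**-1, ...) raises
    :class:`InvalidEvaluation`.
    """
    if len(inputs) != graph.n_inputs:
        raise ValueError(f"expected {graph.n_inputs} inputs, got {len(inputs)}")
    vals: dict[int, np.ndarray] = {i: np.asarray(x, dtype=np.float64) for i, x in enumerate(inputs)}
    with np.errstate(all="ignore"):
        for nid, op, srcs in graph.nodes:
            v = op.func(*(vals[s] for s in srcs))
            v = np.asarray(v, dtype=np.float64)
            if not np.all(np.isfinite(v)):
                raise InvalidEvaluation(f"non-finite value at node {nid}")
            vals[nid] = v
    return [vals[o] for o in graph.output_ids]


def expression_key(graph: ExpressionGraph) -> str:
    """Canonical cache key: fully parenthesized infix, one segment per
    output.  No algebraic normalization — x0*x2 and x2*x0 differ."""
    return graph.key


def mutate(
    genome: Genome,
    p_mutate: float,
    rng: np.random.Generator,
    primitives: PrimitiveSet,
) -> tuple[Genome, bool]:
    """Point-mutate each mutable gene independently with probability
    ``p_mutate``, always to a *different* legal value.

    Returns ``(child, silent)`` where ``silent`` is true iff the decoded
    expression is unchanged (mutations only touched inactive or
    non-coding genes).
    """
    if not 0.0 <= p_mutate <= 1.0:
        raise ValueError("p_mutate must lie in [0, 1]")
    child = genome.copy()
    d = genome.dims
    n_ops = len(primitives.all_ops)
    for i in range(d.n_internal):
        if rng.random() < p_mutate and n_ops > 1:
            cur = int(child.internal_genes[i, 0])
            child.internal_genes[i, 0] = _resample(np.arange(n_ops), cur, rng)
        allowed = child.allowed_sources(child.column_of(i))
        for a in range(primitives.max_arity):
            if rng.random() < p_mutate and allowed.size > 1:
                cur = int(child.internal_genes[i, 1 + a])
                child.internal_genes[i, 1 + a] = _resample(allowed, cur, rng)
    n_nodes = d.n_inputs + d.n_internal
    for o in range(d.n_outputs):
        if rng.random() < p_mutate and n_nodes > 1:
            cur = int(child.output_genes[o])
            child.output_genes[o] = _resample(np.arange(n_nodes), cur, rng)
    silent = decode(child, primitives).key == decode(genome, primitives).key
    return child, silent


def _resample(choices: np.ndarray, current: int, rng: np.random.Generator) -> int:
    alternatives = choices[choices != current]
    return int(alternatives[rng.integers(alternatives.size)])


class CompiledRule:
    """An evaluable plasticity function f(...) -> weight change.

    Wraps either a decoded :class:`ExpressionGraph` (the evolution path)
    or a sympy-parsed infix expression (the user/CLI path).  Evaluation is
    pure and vectorized over numpy arrays; non-finite output raises
    :class:`InvalidEvaluation`.
    """

    def __init__(self, input_names: Sequence[str], evaluator, expression_key: str):
        self.input_names = tuple(input_names)
        self._evaluator = evaluator
        self.expression_key = expression_key

    @property
    def arity(self) -> int:
        return len(self.input_names)

    def __call__(self, *inputs):
        if len(inputs) != self.arity:
            raise ValueError(
                f"rule expects {self.arity} inputs {self.input_names}, got {len(inputs)}"
            )
        return self._evaluator(*inputs)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CompiledRule({self.expression_key!r})"

    @classmethod
    def from_graph(
        cls, graph: ExpressionGraph, input_names: Sequence[str] | None = None
    ) -> "CompiledRule":
        if graph.n_outputs != 1:
            raise ValueError("from_graph compiles single-output phenotypes")
        names = tuple(input_names) if input_names else tuple(f"x{i}" for i in range(graph.n_inputs))
        if len(names) != graph.n_inputs:
            raise ValueError("input_names length must match graph arity")

        def _eval(*inputs):
            return evaluate(graph, inputs)[0]

        return cls(names, _eval, graph.key)

    @classmethod
    def from_expression(
        cls, expression: str, input_names: Sequence[str] | None = None
    ) -> "CompiledRule":
        """Parse a plain infix expression over x0, x1, ... with sympy.

        The expression is lambdified to numpy; outputs are checked for
        finiteness so the -inf contract of the evolutionary loop holds
        for hand-written rules too.
        """
        import sympy

        expr = sympy.sympify(expression)
        symbols = sorted(expr.free_symbols, key=lambda s: s.name)
        for s in symbols:
            if not (s.name.startswith("x") and s.name[1:].isdigit()):
                raise ValueError(f"unknown symbol {s.name!r}; use x0, x1, ...")
        n = 1 + max((int(s.name[1:]) for s in symbols), default=-1)
        xs = sympy.symbols(f"x0:{n}") if n else ()
        fn = sympy.lambdify(xs, expr, modules="numpy")
        names = tuple(input_names) if input_names else tuple(f"x{i}" for i in range(n))
        if len(names) < n:
            raise ValueError(f"expression uses {n} inputs but only {len(names)} names given")

        def _eval(*inputs):
            arrs = [np.asarray(x, dtype=np.float64) for x in inputs[:n]]
            with np.errstate(all="ignore"):
                out = np.asarray(fn(*arrs) if n else fn(), dtype=np.float64)
            if not np.all(np.isfinite(out)):
                raise InvalidEvaluation(f"non-finite value from {expression!r}")
            return out

        return cls(names, _eval, str(expr))
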