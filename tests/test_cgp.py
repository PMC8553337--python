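"""Genotype representation, decoding, evaluation and mutation."""

import numpy as np
import pytest

from evoplast.cgp import (
    CompiledRule,
    Genome,
    GraphDims,
    InvalidEvaluation,
    decode,
    default_primitives,
    evaluate,
    expression_key,
    mutate,
    random_genome,
)

from conftest import recursive_genome_eval


def figure_style_genome():
    """Three inputs, a handful of internal nodes, output reading a
    multiplication of x0 and x2 — with unused (inactive) nodes."""
    prims = default_primitives()  # add=0 sub=1 mul=2 div=3 c1=4 c0.5=5
    dims = GraphDims(n_inputs=3, n_outputs=1, n_rows=1, n_columns=4)
    genes = np.array(
        [
            [2, 0, 2],  # node 3 = x0 * x2   (active)
            [0, 1, 3],  # node 4 = x1 + node3 (inactive)
            [1, 3, 3],  # node 5 = node3 - node3 (inactive)
            [3, 4, 5],  # node 6 = node4 / node5 (inactive)
        ],
        dtype=np.int64,
    )
    g = Genome(dims=dims, internal_genes=genes, output_genes=np.array([3], dtype=np.int64))
    return g, prims


class TestDecode:
    def test_multiplication_phenotype(self):
        g, prims = figure_style_genome()
        graph = decode(g, prims)
        assert graph.expressions == ("(x0 * x2)",)
        assert graph.active_nodes == (3,)
        out = evaluate(graph, [2.0, 9.0, 3.0])
        assert out[0] == pytest.approx(6.0)

    def test_output_wired_to_input_is_identity(self, prims):
        dims = GraphDims(n_inputs=3, n_outputs=1, n_rows=1, n_columns=2)
        g = Genome(
            dims,
            internal_genes=np.zeros((2, 3), dtype=np.int64),
            output_genes=np.array([1], dtype=np.int64),
        )
        graph = decode(g, prims)
        assert graph.expressions == ("x1",)
        assert graph.active_nodes == ()
        assert evaluate(graph, [5.0, 7.0, 9.0])[0] == pytest.approx(7.0)

    def test_constant_node_output(self, prims):
        dims = GraphDims(n_inputs=1, n_outputs=1, n_rows=1, n_columns=1)
        g = Genome(
            dims,
            internal_genes=np.array([[4, 0, 0]], dtype=np.int64),  # const 1.0
            output_genes=np.array([1], dtype=np.int64),
        )
        graph = decode(g, prims)
        for x in (-3.0, 0.0, 11.0):
            assert evaluate(graph, [x])[0] == pytest.approx(1.0)

    def test_dangling_reference_rejected(self, prims):
        dims = GraphDims(n_inputs=2, n_outputs=1, n_rows=1, n_columns=1)
        g = Genome(
            dims,
            internal_genes=np.array([[0, 0, 9]], dtype=np.int64),
            output_genes=np.array([2], dtype=np.int64),
        )
        with pytest.raises(ValueError):
            decode(g, prims)

    def test_redecoding_is_stable(self, prims, small_dims, rng):
        for _ in range(20):
            g = random_genome(small_dims, prims, rng)
            assert decode(g, prims).key == decode(g, prims).key


class TestEvaluate:
    def test_division_by_zero_flags_invalid(self, prims):
        dims = GraphDims(n_inputs=2, n_outputs=1, n_rows=1, n_columns=1)
        g = Genome(
            dims,
            internal_genes=np.array([[3, 0, 1]], dtype=np.int64),  # x0 / x1
            output_genes=np.array([2], dtype=np.int64),
        )
        graph = decode(g, prims)
        assert evaluate(graph, [6.0, 3.0])[0] == pytest.approx(2.0)
        with pytest.raises(InvalidEvaluation):
            evaluate(graph, [1.0, 0.0])

    def test_non_finite_intermediate_not_masked(self, prims):
        # 1/(x0/x1) at x1=0: the inner division is non-finite even though
        # the outer one would be finite again
        dims = GraphDims(n_inputs=2, n_outputs=1, n_rows=1, n_columns=2)
        g = Genome(
            dims,
            internal_genes=np.array([[3, 0, 1], [3, 1, 2]], dtype=np.int64),
            output_genes=np.array([3], dtype=np.int64),
        )
        graph = decode(g, prims)
        with pytest.raises(InvalidEvaluation):
            evaluate(graph, [1.0, 0.0])

    def test_oracle_equivalence_on_random_genomes(self, prims, small_dims, rng):
        """Decoded evaluation equals brute-force recursion over the raw
        genotype at random probe points."""
        n_checked = 0
        for _ in range(200):
            g = random_genome(small_dims, prims, rng)
            graph = decode(g, prims)
            for _ in range(10):
                x = rng.uniform(-3, 3, size=3)
                expected = recursive_genome_eval(g, prims, x)
                try:
                    got = evaluate(graph, list(x))
                except InvalidEvaluation:
                    assert not all(np.isfinite(v) for v in expected)
                    continue
                assert np.allclose(got, expected, rtol=1e-12, atol=0.0, equal_nan=False)
                n_checked += 1
        assert n_checked > 500  # plenty of finite probes actually compared


class TestRandomGenome:
    def test_determinism(self, prims, small_dims):
        a = random_genome(small_dims, prims, np.random.default_rng(7))
        b = random_genome(small_dims, prims, np.random.default_rng(7))
        assert np.array_equal(a.internal_genes, b.internal_genes)
        assert np.array_equal(a.output_genes, b.output_genes)

    def test_no_internal_nodes_output_selects_input(self, prims, rng):
        dims = GraphDims(n_inputs=2, n_outputs=1, n_rows=1, n_columns=0)
        g = random_genome(dims, prims, rng)
        assert g.output_genes[0] in (0, 1)

    def test_operator_gene_frequencies_uniform(self, prims, rng):
        """10^4 draws: per-operator counts within 3 sigma of the binomial
        expectation under uniform sampling."""
        dims = GraphDims(n_inputs=2, n_outputs=1, n_rows=1, n_columns=1)
        n_ops = len(prims.all_ops)
        n = 10_000
        counts = np.zeros(n_ops)
        for _ in range(n):
            g = random_genome(dims, prims, rng)
            counts[g.internal_genes[0, 0]] += 1
        p = 1.0 / n_ops
        sigma = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) < 3 * sigma)


class TestMutate:
    def test_zero_rate_is_identity_and_silent(self, prims, small_dims, rng):
        g = random_genome(small_dims, prims, rng)
        child, silent = mutate(g, 0.0, rng, prims)
        assert silent
        assert np.array_equal(child.internal_genes, g.internal_genes)
        assert np.array_equal(child.output_genes, g.output_genes)

    def test_rate_one_changes_every_mutable_gene(self, prims, small_dims):
        rng = np.random.default_rng(3)
        g = random_genome(small_dims, prims, rng)
        child, _ = mutate(g, 1.0, rng, prims)
        # every gene with more than one legal value must differ
        assert np.all(child.internal_genes[:, 0] != g.internal_genes[:, 0])
        for i in range(small_dims.n_internal):
            allowed = g.allowed_sources(g.column_of(i))
            for a in range(prims.max_arity):
                if allowed.size > 1:
                    assert child.internal_genes[i, 1 + a] != g.internal_genes[i, 1 + a]
        assert np.all(child.output_genes != g.output_genes)

    def test_inactive_node_mutation_is_silent(self):
        g, prims = figure_style_genome()
        h = g.copy()
        h.internal_genes[3, 0] = 0  # node 6 is inactive
        assert decode(h, prims).key == decode(g, prims).key

    def test_closure_under_mutation(self, prims, small_dims, rng):
        """Mutation never produces an out-of-range gene; decode always
        succeeds and evaluations agree with the recursion oracle."""
        g = random_genome(small_dims, prims, rng)
        for _ in range(100):
            g, _ = mutate(g, 0.3, rng, prims)
            graph = decode(g, prims)  # raises on any dangling reference
            x = rng.uniform(-2, 2, size=3)
            expected = recursive_genome_eval(g, prims, x)
            try:
                got = evaluate(graph, list(x))
            except InvalidEvaluation:
                assert not all(np.isfinite(v) for v in expected)
                continue
            assert np.allclose(got, expected, rtol=1e-12)


class TestExpressionKey:
    def test_distinct_inputs_distinct_keys(self, prims):
        dims = GraphDims(n_inputs=2, n_outputs=1, n_rows=1, n_columns=1)
        mk = lambda o: Genome(
            dims,
            internal_genes=np.zeros((1, 3), dtype=np.int64),
            output_genes=np.array([o], dtype=np.int64),
        )
        assert decode(mk(0), prims).key != decode(mk(1), prims).key

    def test_key_equality_iff_value_equality(self, prims, small_dims, rng):
        """Over random genome pairs, equal keys imply equal values on all
        probe points, and random probing never equates distinct keys
        (no collisions at this scale)."""
        genomes = [random_genome(small_dims, prims, rng) for _ in range(100)]
        graphs = [decode(g, prims) for g in genomes]
        probes = rng.uniform(-2, 2, size=(20, 3))

        def signature(graph):
            vals = []
            for x in probes:
                try:
                    vals.append(round(float(evaluate(graph, list(x))[0]), 9))
                except InvalidEvaluation:
                    vals.append(None)
            return tuple(vals)

        sigs = {}
        for graph in graphs:
            k = expression_key(graph)
            s = signature(graph)
            if k in sigs:
                assert sigs[k] == s
            sigs[k] = s

    def test_serialization_roundtrip(self, prims, small_dims, rng):
        g = random_genome(small_dims, prims, rng)
        h = Genome.from_json(g.to_json(prims))
        assert decode(h, prims).key == decode(g, prims).key


class TestCompiledRule:
    def test_from_expression_matches_graph(self):
        g, prims = figure_style_genome()
        graph = decode(g, prims)
        by_graph = CompiledRule.from_graph(graph)
        by_expr = CompiledRule.from_expression("x0 * x2")
        x = np.array([1.5, -2.0, 4.0])
        assert by_graph(*x) == pytest.approx(by_expr(*x))

    def test_from_expression_invalid_flagged(self):
        rule = CompiledRule.from_expression("x0 / x1")
        with pytest.raises(InvalidEvaluation):
            rule(1.0, 0.0)

    def test_arity_mismatch_rejected(self):
        rule = CompiledRule.from_expression("x0 + x1")
        with pytest.raises(ValueError):
            rule(1.0)
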