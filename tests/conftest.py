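import numpy as np
import pytest

from evoplast.cgp import GraphDims, default_primitives


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def prims():
    return default_primitives()


@pytest.fixture
def small_dims():
    return GraphDims(n_inputs=3, n_outputs=1, n_rows=1, n_columns=6)


def recursive_genome_eval(genome, primitives, inputs):
    """Independent oracle: evaluate a genotype by naive recursion over the
    gene arrays, without any decoding step.  Returns one value per output;
    non-finite intermediates surface as inf/nan (caller inspects)."""
    import numpy as _np

    ops = primitives.all_ops
    n_in = genome.dims.n_inputs

    def value(node):
        if node < n_in:
            return _np.float64(inputs[node])
        row = genome.internal_genes[node - n_in]
        op = ops[int(row[0])]
        args = [value(int(row[1 + a])) for a in range(op.arity)]
        with _np.errstate(all="ignore"):
            return _np.float64(op.func(*args))

    return [value(int(o)) for o in genome.output_genes]
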