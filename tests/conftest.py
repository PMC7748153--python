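import numpy as np
import pandas as pd
import pytest

from asdpipe import ExpressionMatrix, GeneSet, Shortlist, ThresholdRule


@pytest.fixture
def rng():
    return np.random.default_rng(20201218)


def make_shortlist(source_id, genes, n_input=None):
    genes = frozenset(genes)
    return Shortlist(
        source_id=source_id,
        genes=genes,
        rule_applied=ThresholdRule("membership"),
        n_input=n_input if n_input is not None else len(genes),
    )


def make_geneset(name, genes):
    return GeneSet.from_iterable(name, genes)


def make_matrix(values, genes=None, tissues=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    tissues = tissues or [f"T{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=tissues))


def random_sets(rng, n_sets, set_size, universe_size, prefix="G"):
    universe = [f"{prefix}{i:04d}" for i in range(universe_size)]
    return [
        set(rng.choice(universe, size=set_size, replace=False)) for _ in range(n_sets)
    ]
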