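import numpy as np
import pandas as pd
import pytest


def make_expr(values, genes=None, samples=None) -> pd.DataFrame:
    """Small expression frame builder for tests."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)


def make_groups(samples_ref, samples_test) -> pd.Series:
    return pd.Series(
        {**{s: "a_ref" for s in samples_ref}, **{s: "b_test" for s in samples_test}},
        name="condition",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160603)


@pytest.fixture
def small_two_groups():
    """6-sample, 5-gene frame with 3 + 3 group split."""
    rng = np.random.default_rng(7)
    expr = make_expr(rng.normal(size=(5, 6)))
    groups = make_groups(expr.columns[:3], expr.columns[3:])
    return expr, groups


def random_symmetric_adjacency(rng, n):
    """Random valid signed-style adjacency: symmetric, [0,1], unit diagonal."""
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a
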