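import numpy as np
import pandas as pd
import pytest

from refselect.data_io import ExpressionMatrix, ReplicateTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, scale="log_expression", gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    n, j = values.shape
    return ExpressionMatrix(
        values,
        gene_ids=gene_ids or [f"g{i+1}" for i in range(j)],
        sample_ids=sample_ids or [f"s{i+1}" for i in range(n)],
        scale=scale,
    )


@pytest.fixture
def small_log_matrix():
    return make_matrix([[0.0, 2.0], [2.0, 0.0], [1.0, 1.0]])


@pytest.fixture
def random_log_matrix(rng):
    return make_matrix(rng.normal(size=(30, 5)))


@pytest.fixture
def replicate_table():
    records = pd.DataFrame(
        {
            "sample": ["s1", "s1", "s1", "s2", "s2", "s1", "s2"],
            "gene": ["g1", "g1", "g1", "g1", "g1", "g2", "g2"],
            "replicate": [1, 2, 3, 1, 2, 1, 1],
            "value": [20.0, 21.0, 25.0, 18.0, 20.0, 30.0, 31.0],
        }
    )
    return ReplicateTable(records, scale="ct")
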