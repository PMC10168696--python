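import numpy as np
import pandas as pd
import pytest

import driftrescue as dr


@pytest.fixture(scope="session")
def small_params():
    return dr.GeneratorParams(n_genes=2000, seed=1)


@pytest.fixture(scope="session")
def small_study(small_params):
    """A 2000-gene synthetic study shared across read-only tests."""
    matrix, samples, truth = dr.generate_study(small_params)
    return matrix, samples, truth


@pytest.fixture(scope="session")
def adjusted_study(small_study, small_params):
    matrix, samples, truth = small_study
    adj = dr.eb_batch_adjust(matrix, samples["batch"].to_numpy(), mode="parametric")
    return adj, samples, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, scale="log10", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return dr.ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale=scale
    )


@pytest.fixture()
def matrix_factory():
    return make_matrix
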