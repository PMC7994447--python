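import numpy as np
import pytest

from scgnn import ExpressionMatrix, SyntheticSpec, generate_zinb


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_matrix(rng):
    """20 cells x 8 genes non-negative matrix with ~40% zeros."""
    values = rng.gamma(2.0, 2.0, size=(20, 8))
    values[rng.random(values.shape) < 0.4] = 0.0
    return ExpressionMatrix(
        values,
        [f"c{i}" for i in range(20)],
        [f"g{j}" for j in range(8)],
        layer_tag="raw",
    )


@pytest.fixture(scope="session")
def tiny_zinb():
    """Small planted-cluster ZINB matrix shared by fast pipeline tests."""
    spec = SyntheticSpec(
        cells_per_cluster=(40, 40, 40), n_genes=60, n_marker_genes=10, seed=7
    )
    return generate_zinb(spec)


def two_blob_embedding(n_per_blob=10, dim=3, gap=50.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per_blob, dim))
    b = rng.normal(gap, 1.0, size=(n_per_blob, dim))
    return np.vstack([a, b]), np.repeat([0, 1], n_per_blob)
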