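import numpy as np
import pytest

from fanoise import BilateralMatrix, SimulationConfig, simulate_bilateral_expression


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """A 5-gene x 6-individual bilateral matrix with mild structure."""
    G, N = 5, 6
    b = rng.normal(10, 2, G)
    s = rng.normal(0, 0.3, (G, N))
    u = b[:, None] + s + rng.normal(0, 0.2, (G, N))
    v = b[:, None] + s + rng.normal(0, 0.2, (G, N))
    return BilateralMatrix(
        gene_ids=[f"g{i}" for i in range(G)],
        left=u,
        right=v,
        log_base="2",
        group_labels=np.array(["A", "A", "A", "B", "B", "B"]),
    )


@pytest.fixture
def cohort():
    """Default three-group qPCR-scale cohort with its generative truth."""
    return simulate_bilateral_expression(SimulationConfig(seed=7))


def exact_cov_matrix(C, rng=None):
    """Return a 4 x 2 data matrix whose sample covariance equals C exactly.

    Built from an orthogonal zero-mean design with unit sample variance,
    linearly mapped through the Cholesky factor of C.
    """
    C = np.asarray(C, dtype=float)
    z1 = np.array([1.0, 1.0, -1.0, -1.0]) * np.sqrt(3.0) / 2.0
    z2 = np.array([1.0, -1.0, 1.0, -1.0]) * np.sqrt(3.0) / 2.0
    Z = np.column_stack([z1, z2])  # sample cov = identity, ddof=1
    L = np.linalg.cholesky(C)
    return Z @ L.T
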