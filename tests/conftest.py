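import numpy as np
import pytest

from comra import CMRParams, generate_synthetic_space


@pytest.fixture(scope="session")
def desk_space():
    """Clustered 20-item space used throughout the reduced-scale tests."""
    return generate_synthetic_space(20, 16, n_clusters=4, cluster_spread=0.1, seed=0)


@pytest.fixture(scope="session")
def flat_space():
    """Unstructured 20-item space (one cluster per item)."""
    return generate_synthetic_space(20, 16, seed=3)


@pytest.fixture
def params():
    return CMRParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def orthogonal_space(n: int, extra_dim: int = 0):
    """Space whose item vectors are standard basis vectors (all cosines 0)."""
    from comra.semantic import SemanticSpace

    vectors = np.eye(n, n + extra_dim)
    return SemanticSpace(items=tuple(f"w{i:03d}" for i in range(n)), vectors=vectors)
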