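import numpy as np
import pytest

from braintce.connectome_io import Connectome, normalize_adjacency
from braintce.synth_fixtures import default_spec, synth_connectome, synth_recording


def random_symmetric(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random nonnegative symmetric weight matrix with zero diagonal."""
    W = rng.random((n, n))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return W


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_system():
    """Stabilized 4-region system from a fixed random connectome."""
    W = random_symmetric(4, np.random.default_rng(7))
    return normalize_adjacency(Connectome(weights=W, region_ids=[f"r{i}" for i in range(4)]))


@pytest.fixture(scope="session")
def synth_dataset():
    """One default-scale synthetic dataset shared across tests."""
    spec = default_spec(seed=11)
    conn = synth_connectome(spec)
    raw, ledger = synth_recording(spec)
    return spec, conn, raw, ledger
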