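import numpy as np
import pytest

from stscsr import ExpressionData, SimulationConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng) -> ExpressionData:
    """A random 30-spot × 40-gene raw count matrix on a 6×5 grid."""
    counts = rng.poisson(2.0, size=(30, 40)).astype(float)
    counts[:, 0] += 1  # avoid empty spots
    coords = np.array([[r, c] for r in range(6) for c in range(5)], dtype=float)
    return ExpressionData(counts,
                          [f"g{j}" for j in range(40)],
                          [f"s{i}" for i in range(30)],
                          coords, "raw")


@pytest.fixture
def bands_dataset():
    """Default 3-band 20×20 synthetic dataset (seed 7)."""
    return simulate(SimulationConfig(seed=7))


def tiny_tri_instance(seed: int, m: int = 6, n: int = 5, k: int = 3):
    """Random small matrices for block-update oracle checks."""
    rng = np.random.default_rng(seed)
    X = rng.random((m, n)) * 2.0
    W = rng.random((n, n))
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    L = np.diag(W.sum(axis=1)) - W
    B_e = rng.random((m, k))
    B_e /= np.maximum(np.linalg.norm(B_e, axis=0), 1.0)
    B_s = rng.random((n, k))
    B_s /= np.maximum(np.linalg.norm(B_s, axis=0), 1.0)
    C = rng.random((k, k))
    C = 0.5 * (C + C.T)
    nrm = np.linalg.norm(C)
    if nrm > np.sqrt(k):
        C *= np.sqrt(k) / nrm
    F_e = rng.random((k, n)) * 2.0
    F_s = rng.random((k, n))
    return X, W, L, B_e, B_s, C, F_e, F_s
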