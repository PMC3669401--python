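import numpy as np
import pytest

from pandanet import (
    NoiseSpec,
    SeedNetworks,
    make_noisy_seeds,
    simulate_truth,
)
from pandanet.netio import LabeledBipartiteNetwork, LabeledSymmetricNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def tiny_seeds():
    """A small deterministic raw seed triple (3 TFs x 5 genes)."""
    rng = np.random.default_rng(42)
    W = (rng.random((3, 5)) < 0.4).astype(float)
    W[0, 0] = 1.0  # ensure at least one edge
    P = np.eye(3)
    P[0, 1] = P[1, 0] = 1.0
    C = np.eye(5)
    C[1, 2] = C[2, 1] = 0.8
    tfs = ["TF1", "TF2", "TF3"]
    genes = [f"g{i}" for i in range(1, 6)]
    return SeedNetworks(
        LabeledBipartiteNetwork(tfs, genes, W),
        LabeledSymmetricNetwork(tfs, P),
        LabeledSymmetricNetwork(genes, C),
    )


@pytest.fixture
def sim_seeds():
    """One default-parameter simulation replicate: (truth, noisy seeds)."""
    truth = simulate_truth(seed=11)
    seeds = make_noisy_seeds(truth, NoiseSpec(), seed=12)
    return truth, seeds


def offdiag_mask(n):
    return ~np.eye(n, dtype=bool).ravel()
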