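import numpy as np
import pytest

from specdelim import DistanceMatrix, Partition


def random_distance_matrix(rng: np.random.Generator, n: int, scale: float = 1.0):
    """A random symmetric matrix with zero diagonal and continuous entries."""
    d = rng.uniform(0.001, scale, size=(n, n))
    d = np.triu(d, k=1)
    d = d + d.T
    labels = [f"s{i:03d}" for i in range(n)]
    return DistanceMatrix(labels, d)


def random_partition(rng: np.random.Generator, n: int, k: int) -> Partition:
    labels = rng.integers(0, k, n)
    return Partition({f"s{i:03d}": f"g{labels[i]}" for i in range(n)})


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def two_block_matrix():
    """Five objects in two clean blocks: within <= 0.01, between >= 0.2."""
    d = np.array(
        [
            [0.000, 0.005, 0.300, 0.250, 0.280],
            [0.005, 0.000, 0.270, 0.220, 0.260],
            [0.300, 0.270, 0.000, 0.008, 0.010],
            [0.250, 0.220, 0.008, 0.000, 0.004],
            [0.280, 0.260, 0.010, 0.004, 0.000],
        ]
    )
    m = DistanceMatrix(list("abcde"), d)
    ref = Partition.from_blocks({"A": ["a", "b"], "B": ["c", "d", "e"]})
    return m, ref
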