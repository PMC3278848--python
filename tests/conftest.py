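import numpy as np
import pytest

from bsnmf import generate_planted_factors
from bsnmf.partition import Partition


@pytest.fixture(scope="session")
def planted_small():
    """A small, low-noise planted dataset shared across read-only tests."""
    return generate_planted_factors(N=60, M=18, K=3, noise_sigma=0.05, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_partition(labels, source="test"):
    labels = np.asarray(labels, dtype=int)
    return Partition([str(i) for i in range(len(labels))], labels,
                     int(labels.max()), source)


@pytest.fixture
def partition_factory():
    return make_partition
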