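import numpy as np
import pytest

from chromdiff import (
    ChainParameters,
    CountDataset,
    GLMParameters,
    GenomicWindows,
    enumerate_patterns,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def grid_windows(m: int, width: int = 500, chrom: str = "chr1") -> GenomicWindows:
    start = np.arange(m, dtype=np.int64) * width
    return GenomicWindows(np.array([chrom] * m, dtype=object), start, start + width)


@pytest.fixture
def small_dataset(rng) -> CountDataset:
    """3 samples (2 conditions) x 4 windows of random counts."""
    counts = rng.integers(0, 20, size=(3, 4))
    return CountDataset(
        counts=counts,
        condition_of_sample=np.array([0, 0, 1]),
        windows=grid_windows(4),
    )


@pytest.fixture
def glm() -> GLMParameters:
    return GLMParameters(beta1=1.116, beta3=1.165, lambda1=1.281, lambda3=0.124)


def random_chain(rng, L: int = 2) -> ChainParameters:
    pi = rng.dirichlet(np.ones(3))
    gamma = rng.dirichlet(np.ones(3), size=3)
    delta = rng.dirichlet(np.ones(L))
    return ChainParameters(pi=pi, gamma=gamma, delta=delta)


@pytest.fixture
def design3():
    return enumerate_patterns(3)
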