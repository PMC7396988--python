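import numpy as np
import pytest

from popgenkit.types import HaplotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_matrix(rng, n_hap, n_sites, pops=None, chrom="1"):
    """Random segregating haplotype matrix (every site polymorphic)."""
    alleles = np.zeros((n_hap, n_sites), dtype=np.int8)
    for j in range(n_sites):
        k = int(rng.integers(1, n_hap))
        alleles[rng.choice(n_hap, size=k, replace=False), j] = 1
    positions = np.sort(rng.choice(np.arange(1, 100 * n_sites), size=n_sites, replace=False))
    return HaplotypeMatrix(alleles, positions, pop_labels=pops, chrom=chrom)


@pytest.fixture
def small_matrix(rng):
    return random_matrix(rng, 8, 50)
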