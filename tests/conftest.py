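import numpy as np
import pytest

from islandgen.core import GenotypeMatrix
from islandgen.drift import default_initial_frequencies


@pytest.fixture(scope="session")
def source_frequencies():
    """The deterministic 13-locus mainland-like frequency table."""
    return default_initial_frequencies()


@pytest.fixture
def toy_two_pop():
    """Two populations, two loci, handmade genotypes (includes missing)."""
    calls = np.array(
        [
            # popA: locus1 {(1,1),(1,2),(2,2)}, locus2 {(1,1),(1,1),missing}
            [[1, 1], [1, 1]],
            [[1, 2], [1, 1]],
            [[2, 2], [0, 0]],
            # popB: locus1 {(3,3),(3,3)}, locus2 {(1,2),(2,2)}
            [[3, 3], [1, 2]],
            [[3, 3], [2, 2]],
        ]
    )
    return GenotypeMatrix(
        individuals=["a1", "a2", "a3", "b1", "b2"],
        loci=["L1", "L2"],
        populations=["popA", "popA", "popA", "popB", "popB"],
        calls=calls,
    )


def random_genotype_matrix(seed, n_pops=3, n_loci=13, n_per_pop=20, max_allele=8,
                           missing_rate=0.05):
    """Unstructured random genotype matrix for round-trip/invariance tests."""
    rng = np.random.default_rng(seed)
    n = n_pops * n_per_pop
    calls = rng.integers(1, max_allele + 1, size=(n, n_loci, 2))
    miss = rng.random((n, n_loci)) < missing_rate
    calls[miss] = 0
    pops = [f"pop{k + 1}" for k in range(n_pops) for _ in range(n_per_pop)]
    return GenotypeMatrix(
        individuals=[f"ind{i}" for i in range(n)],
        loci=[f"L{j + 1}" for j in range(n_loci)],
        populations=pops,
        calls=calls,
    )
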