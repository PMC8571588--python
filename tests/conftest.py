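import numpy as np
import pytest

from ssrtrace.genotype_io import GenotypeMatrix


@pytest.fixture
def small_matrix() -> GenotypeMatrix:
    """Two populations, three loci, with one missing call."""
    calls = np.array(
        [
            [[10, 12], [20, 20], [30, 32]],
            [[10, 10], [20, 22], [30, 30]],
            [[12, 12], [22, 22], [-1, -1]],
            [[10, 12], [20, 22], [32, 32]],
        ],
        dtype=np.int64,
    )
    return GenotypeMatrix(
        ["a", "b", "c", "d"],
        ["L1", "L2", "L3"],
        calls,
        np.array(["P1", "P1", "P2", "P2"], dtype=object),
    )


@pytest.fixture
def hwe_population() -> GenotypeMatrix:
    """One population drawn exactly at Hardy-Weinberg proportions."""
    rng = np.random.default_rng(123)
    freqs = {10: 0.5, 12: 0.3, 14: 0.2}
    alleles = np.array(list(freqs))
    p = np.array(list(freqs.values()))
    calls = rng.choice(alleles, size=(100, 1, 2), p=p)
    return GenotypeMatrix(
        [f"i{k}" for k in range(100)],
        ["L1"],
        calls,
        np.array(["pop"] * 100, dtype=object),
    )
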