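import numpy as np
import pytest

from kbimpute.datatypes import MISSING, GenotypeMatrix, MarkerInfo, default_markers


def random_matrix(rng: np.random.Generator, n: int, m: int, missing_rate: float = 0.1,
                  with_alleles: bool = False) -> GenotypeMatrix:
    """A random valid genotype matrix, optionally with real allele labels."""
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((n, m)) < missing_rate
        calls[mask] = MISSING
    taxa = [f"tax{i}" for i in range(n)]
    if with_alleles:
        pairs = [("A", "C"), ("T", "G"), ("C", "T"), ("G", "A")]
        markers = [
            MarkerInfo(name=f"m{j}", chrom="1", pos=j + 1, alleles=pairs[j % 4])
            for j in range(m)
        ]
    else:
        markers = default_markers(m)
    return GenotypeMatrix(taxa, markers, calls)


@pytest.fixture
def small_gm() -> GenotypeMatrix:
    """4 individuals x 5 markers with a couple of missing calls."""
    calls = np.array(
        [
            [0, 1, 2, 0, 1],
            [0, MISSING, 2, 1, 1],
            [1, 1, 0, MISSING, 2],
            [2, 0, 0, 0, 2],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix([f"tax{i}" for i in range(4)], default_markers(5), calls)


@pytest.fixture
def structured_sim():
    """A small 3-subpopulation panel with stored truth haplotypes."""
    from kbimpute.popsim import PopSimConfig, simulate_population

    cfg = PopSimConfig(
        n_subpops=3, n_per_subpop=10, n_markers=300, divergence=0.3, pool_size=8, seed=11
    )
    return simulate_population(cfg)
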