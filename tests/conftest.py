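import numpy as np
import pytest

from msatpop.genepop import GenotypeDataset
from msatpop.synthetic import SyntheticSpec, generate_baseline


def dataset_from_calls(pops: dict[str, list[list[tuple[int, int]]]],
                       loci: list[str] | None = None) -> GenotypeDataset:
    """Build a dataset from explicit per-individual calls.

    ``pops[label]`` is a list of individuals, each a list of (a1, a2)
    pairs, one per locus.
    """
    n_loci = len(next(iter(pops.values()))[0])
    loci = loci or [f"L{i + 1}" for i in range(n_loci)]
    genotypes = {
        label: np.array(ind, dtype=np.int64).reshape(len(ind), n_loci, 2)
        for label, ind in pops.items()
    }
    return GenotypeDataset(loci=loci, genotypes=genotypes)


@pytest.fixture(scope="session")
def baseline():
    """Synthetic single-pool baseline: 8 loci, 84 alleles, mean He ~ 0.62."""
    return generate_baseline(SyntheticSpec(), seed=1)


@pytest.fixture
def toy_two_pops():
    """Two 4-individual populations at one biallelic locus (hand-checked)."""
    A, B = 1, 2
    return dataset_from_calls({
        "p1": [[(A, A)], [(A, A)], [(A, B)], [(A, B)]],
        "p2": [[(A, B)], [(B, B)], [(B, B)], [(B, B)]],
    })


@pytest.fixture
def fixed_difference():
    """Two populations fixed for different alleles (maximal divergence)."""
    return dataset_from_calls({
        "p1": [[(1, 1)]] * 6,
        "p2": [[(2, 2)]] * 6,
    })


def random_dataset(rng: np.random.Generator, n_pops=3, n_loci=2,
                   max_ind=8, max_allele=98, missing_rate=0.0) -> GenotypeDataset:
    genotypes = {}
    for p in range(n_pops):
        n = int(rng.integers(2, max_ind + 1))
        arr = rng.integers(1, max_allele + 1, size=(n, n_loci, 2))
        if missing_rate:
            miss = rng.random((n, n_loci)) < missing_rate
            arr[miss] = 0
        genotypes[f"pop{p + 1}"] = arr
    return GenotypeDataset(loci=[f"L{i + 1}" for i in range(n_loci)],
                           genotypes=genotypes)
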