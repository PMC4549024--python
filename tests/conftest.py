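import numpy as np
import pytest

import addomgs as A


@pytest.fixture(scope="session")
def small_map():
    """2 chromosomes x 10 cM, 0.5 cM spacing (40 loci), 8 QTL."""
    return A.GenomeMap.default(n_chromosomes=2, chrom_length_cm=10.0,
                               spacing_cm=0.5, n_qtl=8)


@pytest.fixture(scope="session")
def small_dataset(small_map):
    """Tiny end-to-end replicate: 5 families x 20 sibs, 40 markers."""
    return A.simulate_dataset(gmap=small_map, pop_size=200, n_families=5,
                              family_size=20, n_parents=10, seed=11)


@pytest.fixture(scope="session")
def medium_map():
    """5 chromosomes x 10 cM, 0.2 cM spacing (250 loci), 20 QTL."""
    return A.GenomeMap.default(n_chromosomes=5, chrom_length_cm=10.0,
                               spacing_cm=0.2, n_qtl=20)


@pytest.fixture(scope="session")
def medium_dataset(medium_map):
    """Mid-sized replicate used by the REML / MCMC recovery tests."""
    return A.simulate_dataset(gmap=medium_map, pop_size=500, n_families=10,
                              family_size=40, n_parents=20, seed=7)


@pytest.fixture(scope="session")
def medium_coding(medium_dataset):
    return A.build_coding(medium_dataset.dosages)
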