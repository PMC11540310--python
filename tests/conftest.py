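import numpy as np
import pytest

from cpsim.founders import FounderPanel
from cpsim.genome import PhasedPopulation, uniform_linkage_map


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_map():
    """2 chromosomes x 5 evenly spaced markers, 1 Morgan each."""
    return uniform_linkage_map(2, 5)


def random_population(rng, n, gmap, het=True):
    L = gmap.n_markers
    h0 = rng.integers(0, 2, (n, L), dtype=np.int8)
    h1 = rng.integers(0, 2, (n, L), dtype=np.int8) if het else h0.copy()
    return PhasedPopulation(hap0=h0, hap1=h1, ids=[f"I{i}" for i in range(n)])


@pytest.fixture
def small_pop(rng, small_map):
    return random_population(rng, 6, small_map)


def panel_from_matrix(alleles, chrom, pos_bp):
    """Inbred panel (hap0 == hap1) from a 0/1 accession x marker matrix."""
    alleles = np.asarray(alleles, dtype=np.int8)
    pop = PhasedPopulation(hap0=alleles, hap1=alleles.copy(),
                           ids=[f"A{i}" for i in range(alleles.shape[0])])
    return FounderPanel(population=pop, chrom=np.asarray(chrom),
                        pos_bp=np.asarray(pos_bp))
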