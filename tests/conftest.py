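import numpy as np
import pytest

from mitoribo.fixture import fixture_genome
from mitoribo.genome import MitoGenome, OrfAnnotation
from mitoribo.reads import GenomeIndex


@pytest.fixture(scope="session")
def mito():
    """Bundled synthetic human-layout genome and its 13-ORF annotation."""
    return fixture_genome()


@pytest.fixture(scope="session")
def genome(mito):
    return mito[0]


@pytest.fixture(scope="session")
def orfs(mito):
    return mito[1]


@pytest.fixture(scope="session")
def orf_by_gene(orfs):
    return {o.gene: o for o in orfs}


@pytest.fixture(scope="session")
def genome_index(genome):
    return GenomeIndex(genome)


@pytest.fixture
def toy_genome():
    """9-nt single-ORF toy: ATG AAA TAA."""
    return MitoGenome(name="toy", sequence="ATGAAATAA")


@pytest.fixture
def toy_orf():
    return OrfAnnotation(gene="G", start=0, end=9, strand="+", polya_completion=0)


def random_genome(rng: np.random.Generator, length: int) -> MitoGenome:
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    return MitoGenome(name=f"rand{length}", sequence=seq)
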