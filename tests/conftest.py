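import numpy as np
import pytest

from tripan.config import ThresholdConfig
from tripan.genome import GenomeSequence
from tripan.simulate import (
    EvolutionParams, evolve, plant_genes, simulate_ancestor,
)


@pytest.fixture(scope="session")
def config():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def ancestor_100k():
    return simulate_ancestor(100_000, gc=0.43, seed=11)


@pytest.fixture(scope="session")
def genic_ancestor():
    """100 kb ancestor carrying 20 intact two-exon genes."""
    anc = simulate_ancestor(100_000, gc=0.43, seed=11)
    return plant_genes(anc, 20, exons_per_gene=2, seed=12)


@pytest.fixture(scope="session")
def sv_free_pair(genic_ancestor):
    """Reference with genes and a descendant carrying only SNPs and small
    indels (the exact-recovery regime)."""
    ancestor, genes = genic_ancestor
    derived, truth = evolve(
        ancestor, EvolutionParams(pav_count=0, cnv_count=0, seed=13),
        genome_id="qry",
    )
    return {"ref": ancestor, "genes": genes, "qry": derived, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_genome(rng, length, genome_id="g", chrom="chr1"):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    return GenomeSequence(genome_id=genome_id, chromosomes=[(chrom, seq)])
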