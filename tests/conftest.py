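import pytest

from cirtseq.annotation import GeneModel, GenomeSequence, derive_introns
from cirtseq.pipeline import run_pipeline
from cirtseq.synthetic_data import SimConfig, simulate


@pytest.fixture
def toy_gene_plus():
    """Three exons on the plus strand: introns [100,200) and [300,400)."""
    return GeneModel(
        gene_id="G1", chrom="chr1", strand="+", exons=[(0, 100), (200, 300), (400, 500)]
    )


@pytest.fixture
def toy_gene_minus():
    return GeneModel(
        gene_id="G2", chrom="chr1", strand="-", exons=[(0, 100), (200, 300), (400, 500)]
    )


@pytest.fixture
def toy_genome():
    return GenomeSequence({"chr1": "ACGT" * 250})


@pytest.fixture(scope="session")
def sim_small():
    """A compact simulated dendrite sample shared across tests."""
    return simulate(SimConfig(seed=11, n_genes=60, cirt_gene_fraction=0.5))


@pytest.fixture(scope="session")
def sim_small_result(sim_small):
    return run_pipeline(
        sim_small.models,
        sim_small.fragments,
        chrom_lengths=sim_small.chrom_lengths,
        predicted_genes=sim_small.decoys["predicted_gene"],
        polya_sites=sim_small.decoys["polyA_site"],
        ncrnas=sim_small.decoys["ncRNA"],
        antisense=sim_small.decoys["antisense"],
    )
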