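import numpy as np
import pytest

from tsskit.genomic import GeneModel, GenomicInterval, Transcript


@pytest.fixture
def two_exon_gene():
    """'+'-strand gene with exons 10,000-10,100 and 20,000-20,200."""
    tx = Transcript(
        "GA.T1",
        [
            GenomicInterval("chr1", 10_000, 10_100, "+"),
            GenomicInterval("chr1", 20_000, 20_200, "+"),
        ],
    )
    return GeneModel("GA", "chr1", "+", [tx])


@pytest.fixture
def gene_models(two_exon_gene):
    """Small mixed-strand gene set on chr1."""
    minus = GeneModel(
        "GB",
        "chr1",
        "-",
        [
            Transcript(
                "GB.T1",
                [
                    GenomicInterval("chr1", 50_000, 50_300, "-"),
                    GenomicInterval("chr1", 49_000, 49_200, "-"),
                ],
            )
        ],
    )
    single = GeneModel(
        "GC",
        "chr1",
        "+",
        [Transcript("GC.T1", [GenomicInterval("chr1", 80_000, 82_000, "+")])],
    )
    return [two_exon_gene, minus, single]


@pytest.fixture
def toy_genome():
    from tsskit.fixtures import make_genome

    return make_genome(n_genes=12, multi_tss_fraction=0.4, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
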