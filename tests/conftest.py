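import numpy as np
import pytest

from exonskip.intervals import GeneModel, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def two_exon_gene():
    """Plus-strand gene: exons [10,30) and [50,70), intron [30,50)."""
    return GeneModel(
        gene_id="gA",
        intervals=[
            GenomicInterval("chr1", 10, 30, "+"),
            GenomicInterval("chr1", 50, 70, "+"),
        ],
        exon_ids=["gA:E001", "gA:E002"],
        cds_flags=[True, True],
    )


@pytest.fixture
def minus_gene():
    """Minus-strand mirror of a two-exon gene."""
    return GeneModel(
        gene_id="gB",
        intervals=[
            GenomicInterval("chr1", 10, 30, "-"),
            GenomicInterval("chr1", 50, 70, "-"),
        ],
        exon_ids=["gB:E001", "gB:E002"],
    )
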