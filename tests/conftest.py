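import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from poolvar.config import GeneModel, GenomicInterval, PipelineConfig


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def plus_gene():
    """+ strand gene: exons [101-200, 301-400], CDS [151-200, 301-350]."""
    return GeneModel(
        gene_id="gplus",
        chrom="chr1",
        strand="+",
        exons=(GenomicInterval("chr1", 101, 200, "+"), GenomicInterval("chr1", 301, 400, "+")),
        cds_segments=(GenomicInterval("chr1", 151, 200, "+"), GenomicInterval("chr1", 301, 350, "+")),
        utr5=(GenomicInterval("chr1", 101, 150, "+"),),
        utr3=(GenomicInterval("chr1", 351, 400, "+"),),
    )


@pytest.fixture
def minus_gene():
    """- strand mirror of the same exon structure (TSS at 400)."""
    return GeneModel(
        gene_id="gminus",
        chrom="chr1",
        strand="-",
        exons=(GenomicInterval("chr1", 301, 400, "-"), GenomicInterval("chr1", 101, 200, "-")),
        cds_segments=(GenomicInterval("chr1", 301, 350, "-"), GenomicInterval("chr1", 151, 200, "-")),
        utr5=(GenomicInterval("chr1", 351, 400, "-"),),
        utr3=(GenomicInterval("chr1", 101, 150, "-"),),
    )


@pytest.fixture
def overlap_models():
    """Constructed 3'UTR-in-intron overlap: gene A's 3'UTR inside gene B's
    intron (the TAP1/BF1-style configuration)."""
    a = GeneModel(
        gene_id="tap1_like",
        chrom="chr16",
        strand="+",
        exons=(GenomicInterval("chr16", 1000, 1500, "+"), GenomicInterval("chr16", 4600, 5000, "+")),
        cds_segments=(GenomicInterval("chr16", 1100, 1500, "+"), GenomicInterval("chr16", 4600, 4798, "+")),
        utr5=(GenomicInterval("chr16", 1000, 1099, "+"),),
        utr3=(GenomicInterval("chr16", 4799, 5000, "+"),),
    )
    b = GeneModel(
        gene_id="bf1_like",
        chrom="chr16",
        strand="+",
        exons=(GenomicInterval("chr16", 3600, 4100, "+"), GenomicInterval("chr16", 7200, 7800, "+")),
        cds_segments=(GenomicInterval("chr16", 3700, 4100, "+"), GenomicInterval("chr16", 7200, 7698, "+")),
        utr5=(GenomicInterval("chr16", 3600, 3699, "+"),),
        utr3=(GenomicInterval("chr16", 7699, 7800, "+"),),
    )
    return [a, b]
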