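import pytest

from isoforge.model import (
    AlignedRead,
    GenomicInterval,
    PolyAStatus,
    TranscriptModel,
)
from isoforge.reference_index import build_reference_index


def make_read(read_id, chrom, strand, blocks, polya=PolyAStatus.UNKNOWN, mapq=60):
    return AlignedRead(
        read_id=read_id,
        chrom=chrom,
        strand=strand,
        exon_blocks=tuple(GenomicInterval(chrom, s, e, strand) for s, e in blocks),
        polya=polya,
        mapq=mapq,
    )


def make_transcript(tid, chrom, strand, exons, gene_id=None):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id or f"G_{tid}",
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


@pytest.fixture
def two_gene_reference():
    """Two genes, one per strand: a 3-exon + gene and a 3-exon - gene with
    a skipped-exon variant each."""
    return [
        make_transcript("TXA.1", "chr1", "+", [(1000, 1200), (2000, 2200), (3000, 3300)], "GA"),
        make_transcript("TXA.2", "chr1", "+", [(1000, 1200), (3000, 3300)], "GA"),
        make_transcript("TXB.1", "chr1", "-", [(10000, 10200), (11000, 11200), (12000, 12300)], "GB"),
        make_transcript("TXB.2", "chr1", "-", [(10000, 10200), (12000, 12300)], "GB"),
    ]


@pytest.fixture
def two_gene_index(two_gene_reference):
    return build_reference_index(two_gene_reference)
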