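"""Core domain types shared across the pipeline.

Coordinate convention: everything in memory is 0-based half-open on the
forward genomic axis. Strand only changes *interpretation* (which end is
5', which intron boundary is the donor), never the stored coordinates.
Conversions to 1-based closed GTF coordinates happen exclusively in
:mod:`isoforge.formats_io`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Sequence


class PolyAStatus(str, enum.Enum):
    """Per-read polyadenylation call (tri-state).

    Reads absent from the caller's output table are ``UNKNOWN``; the
    pipeline treats unknown as not-polyadenylated when counting poly(A)
    evidence.
    """

    POLYADENYLATED = "polyadenylated"
    NOT_POLYADENYLATED = "not_polyadenylated"
    UNKNOWN = "unknown"


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """min(overlap/len(self), overlap/len(other)); 0 on different chroms."""
        ov = self.overlap_length(other)
        if ov == 0:
            return 0.0
        return min(ov / len(self), ov / len(other))


@dataclass(frozen=True, slots=True, order=True)
class SpliceJunction:
    """One intron as an interval: ``start`` is the first intronic base,
    ``end`` one past the last. On + the ``start`` boundary is the donor
    and ``end`` the acceptor; roles swap on -.
    """

    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"intron requires start < end, got [{self.start}, {self.end})")

    @property
    def donor(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True, slots=True)
class IntronChain:
    """The ordered intron list of a read or transcript — the collapsing key.

    ``junctions`` holds ``(start, end)`` intron intervals in genomic order.
    An empty tuple denotes a single-exon structure (clustered separately).
    Value-hashable so it can key dictionaries directly.
    """

    chrom: str
    strand: str
    junctions: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.junctions:
            if s >= e:
                raise ValueError(f"intron [{s}, {e}) is empty")
            if s <= prev_end:
                raise ValueError("introns must be strictly increasing and non-overlapping")
            prev_end = e

    def __len__(self) -> int:
        return len(self.junctions)

    def splice_junctions(self) -> Iterator[SpliceJunction]:
        for s, e in self.junctions:
            yield SpliceJunction(self.chrom, self.strand, s, e)

    def is_single_exon(self) -> bool:
        return not self.junctions


def _validate_blocks(blocks: Sequence[GenomicInterval]) -> None:
    if not blocks:
        raise ValueError("exon_blocks must be non-empty")
    chrom = blocks[0].chrom
    prev_end = None
    for b in blocks:
        if b.chrom != chrom:
            raise ValueError("all exon blocks must share one chrom")
        if prev_end is not None and b.start <= prev_end:
            raise ValueError("exon blocks must be separated by >= 1 bp gaps")
        prev_end = b.end


@dataclass(slots=True)
class AlignedRead:
    """One spliced read as strand-aware exon blocks plus its poly(A) call."""

    read_id: str
    chrom: str
    strand: str
    exon_blocks: tuple[GenomicInterval, ...]
    polya: PolyAStatus = PolyAStatus.UNKNOWN
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be + or -, got {self.strand!r}")
        self.exon_blocks = tuple(self.exon_blocks)
        _validate_blocks(self.exon_blocks)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exon_blocks[0].start, self.exon_blocks[-1].end, self.strand
        )

    def introns(self) -> tuple[tuple[int, int], ...]:
        b = self.exon_blocks
        return tuple((b[i].end, b[i + 1].start) for i in range(len(b) - 1))

    def intron_chain(self) -> IntronChain:
        return IntronChain(self.chrom, self.strand, self.introns())

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' terminus (read start in transcript
        orientation): leftmost start on +, rightmost end on -."""
        if self.strand == "+":
            return self.exon_blocks[0].start
        return self.exon_blocks[-1].end

    @property
    def three_prime(self) -> int:
        if self.strand == "+":
            return self.exon_blocks[-1].end
        return self.exon_blocks[0].start

    def is_spliced(self) -> bool:
        return len(self.exon_blocks) > 1


@dataclass(slots=True)
class TranscriptModel:
    """Exon-level transcript structure, reference or assembled."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    source: str = "reference"

    def __post_init__(self) -> None:
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        _validate_blocks(self.exons)

    def introns(self) -> tuple[tuple[int, int], ...]:
        e = self.exons
        return tuple((e[i].end, e[i + 1].start) for i in range(len(e) - 1))

    def intron_chain(self) -> IntronChain:
        return IntronChain(self.chrom, self.strand, self.introns())

    @property
    def tss(self) -> int:
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end

    @property
    def tes(self) -> int:
        return self.exons[-1].end if self.strand == "+" else self.exons[0].start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)


@dataclass(slots=True)
class IsoformCall:
    """An emitted transcript model with support counts, boundary provenance
    and filtering trace."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    chain: IntronChain
    n_reads: int
    n_polya: int
    is_novel_chain: bool
    tss_evidence: str = "none"  # annotated | cage | none
    single_exon: bool = False
    tss_method: str = "median"
    tes_method: str = "median"
    filter_trace: dict = field(default_factory=dict)
    source: str = "assembled"

    def __post_init__(self) -> None:
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        _validate_blocks(self.exons)

    def to_transcript_model(self) -> TranscriptModel:
        return TranscriptModel(
            self.transcript_id, self.gene_id, self.chrom, self.strand, self.exons, "assembled"
        )

    @property
    def tss(self) -> int:
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end

    @property
    def tes(self) -> int:
        return self.exons[-1].end if self.strand == "+" else self.exons[0].start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)
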