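"""Reference-guided splice-junction correction.

Basecalling noise around splice sites displaces reported junction
boundaries by a few bases, which would split reads of one isoform into
many spurious intron chains. Each non-annotated junction boundary is
snapped to the nearest annotated site of the same kind (donor/acceptor,
strand-aware) when the genomic offset is at most ``max_shift`` (40 bp by
default). Boundaries already on annotated sites are never moved, and a
snap that would collapse an exon below 1 bp or invert an intron is
cancelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import AlignedRead, GenomicInterval
from .reference_index import ReferenceIndex, nearest_site

DEFAULT_MAX_SHIFT = 40


@dataclass(frozen=True, slots=True)
class CorrectionRecord:
    read_id: str
    junction_index: int
    side: str  # donor | acceptor
    original: int
    corrected: int

    @property
    def shift(self) -> int:
        return self.corrected - self.original


@dataclass
class CorrectionSummary:
    n_reads: int = 0
    n_spliced_reads: int = 0
    n_junctions: int = 0
    corrected_donor: int = 0
    corrected_acceptor: int = 0
    already_annotated: int = 0
    out_of_range: int = 0
    cancelled: int = 0

    def merge_side(self, side: str) -> None:
        if side == "donor":
            self.corrected_donor += 1
        else:
            self.corrected_acceptor += 1


def correct_read(
    read: AlignedRead,
    index: ReferenceIndex,
    max_shift: int = DEFAULT_MAX_SHIFT,
    summary: CorrectionSummary | None = None,
) -> tuple[AlignedRead, list[CorrectionRecord]]:
    """Correct each junction boundary of one read independently.

    Returns the (possibly identical) corrected read and the records of
    applied shifts. The input read is not mutated.
    """
    if summary is None:
        summary = CorrectionSummary()
    blocks = [[b.start, b.end] for b in read.exon_blocks]
    records: list[CorrectionRecord] = []
    # boundary "start" of intron i is blocks[i].end; boundary "end" is
    # blocks[i+1].start; donor/acceptor roles depend on strand
    for i in range(len(blocks) - 1):
        start_kind = "donor" if read.strand == "+" else "acceptor"
        end_kind = "acceptor" if read.strand == "+" else "donor"

        pos = blocks[i][1]
        if index.is_annotated_site(read.chrom, read.strand, pos, start_kind):
            summary.already_annotated += 1
        else:
            hit = nearest_site(index, read.chrom, read.strand, pos, start_kind)
            if hit is None or hit[1] > max_shift:
                summary.out_of_range += 1
            elif hit[0] - blocks[i][0] >= 1 and hit[0] < blocks[i + 1][0]:
                blocks[i][1] = hit[0]
                records.append(CorrectionRecord(read.read_id, i, start_kind, pos, hit[0]))
                summary.merge_side(start_kind)
            else:
                summary.cancelled += 1

        pos = blocks[i + 1][0]
        if index.is_annotated_site(read.chrom, read.strand, pos, end_kind):
            summary.already_annotated += 1
        else:
            hit = nearest_site(index, read.chrom, read.strand, pos, end_kind)
            if hit is None or hit[1] > max_shift:
                summary.out_of_range += 1
            elif blocks[i + 1][1] - hit[0] >= 1 and hit[0] > blocks[i][1]:
                blocks[i + 1][0] = hit[0]
                records.append(CorrectionRecord(read.read_id, i, end_kind, pos, hit[0]))
                summary.merge_side(end_kind)
            else:
                summary.cancelled += 1

    if not records:
        return read, []
    corrected = AlignedRead(
        read_id=read.read_id,
        chrom=read.chrom,
        strand=read.strand,
        exon_blocks=tuple(
            GenomicInterval(read.chrom, s, e, read.strand) for s, e in blocks
        ),
        polya=read.polya,
        mapq=read.mapq,
    )
    return corrected, records


def correct_all(
    reads: list[AlignedRead],
    index: ReferenceIndex,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> tuple[list[AlignedRead], list[CorrectionRecord], CorrectionSummary]:
    """Correct every spliced read; unspliced reads pass through untouched."""
    summary = CorrectionSummary(n_reads=len(reads))
    out: list[AlignedRead] = []
    all_records: list[CorrectionRecord] = []
    for read in reads:
        if not read.is_spliced():
            out.append(read)
            continue
        summary.n_spliced_reads += 1
        summary.n_junctions += len(read.exon_blocks) - 1
        corrected, records = correct_read(read, index, max_shift, summary)
        out.append(corrected)
        all_records.extend(records)
    return out, all_records, summary


def write_correction_log(records: list[CorrectionRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tjunction_index\tside\toriginal\tcorrected\tshift\n")
        for r in records:
            fh.write(
                f"{r.read_id}\t{r.junction_index}\t{r.side}\t{r.original}\t{r.corrected}\t{r.shift}\n"
            )
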