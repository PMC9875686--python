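"""File-format boundary: SAM/BAM, GTF, BED and poly(A)-call TSV.

All coordinate-dialect conversions live here. Internally everything is
0-based half-open; GTF is written/read as 1-based closed, BED as 0-based
half-open.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gffutils
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .model import (
    AlignedRead,
    GenomicInterval,
    IsoformCall,
    PolyAStatus,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

# CIGAR op codes (pysam numeric encoding)
_REF_EXTEND = {0, 2, 7, 8}  # M, D, =, X extend the current exon block
_NO_REF = {1, 4, 5, 6}  # I, S, H, P consume no reference
_SKIP = 3  # N closes a block and opens the next


def blocks_from_cigar(cigartuples, reference_start: int) -> list[tuple[int, int]]:
    """Walk a parsed CIGAR into exon blocks.

    M/=/X/D extend the current block; N closes it; I/S/H/P are ignored on
    the reference axis. Returns 0-based half-open ``(start, end)`` blocks.
    """
    blocks: list[tuple[int, int]] = []
    pos = reference_start
    block_start = reference_start
    for op, length in cigartuples:
        if op in _REF_EXTEND:
            pos += length
        elif op == _SKIP:
            if pos > block_start:
                blocks.append((block_start, pos))
            pos += length
            block_start = pos
        elif op in _NO_REF:
            continue
        else:
            raise ValueError(f"unsupported CIGAR op code {op}")
    if pos > block_start:
        blocks.append((block_start, pos))
    if not blocks:
        raise ValueError("CIGAR consumes no reference bases")
    return blocks


def _transcript_strand(rec: pysam.AlignedSegment) -> str:
    """Transcript strand: prefer the aligner's spliced-strand tag (minimap2
    ``ts``: '+' means transcript strand equals alignment strand), else fall
    back to the alignment strand."""
    aln = "-" if rec.is_reverse else "+"
    if rec.has_tag("ts"):
        ts = rec.get_tag("ts")
        if ts == "-":
            return "-" if aln == "+" else "+"
    return aln


def parse_alignments(path: str | os.PathLike, min_mapq: int = 1) -> list[AlignedRead]:
    """Load primary spliced alignments from SAM/BAM into AlignedRead records.

    Secondary, supplementary and unmapped records are skipped, as are
    records below ``min_mapq``. Records with unusable CIGARs are skipped
    with a warning naming the read.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if rec.cigartuples is None:
                logger.warning("read %s has no CIGAR; skipped", rec.query_name)
                continue
            try:
                raw = blocks_from_cigar(rec.cigartuples, rec.reference_start)
                strand = _transcript_strand(rec)
                blocks = tuple(
                    GenomicInterval(rec.reference_name, s, e, strand) for s, e in raw
                )
                reads.append(
                    AlignedRead(
                        read_id=rec.query_name,
                        chrom=rec.reference_name,
                        strand=strand,
                        exon_blocks=blocks,
                        mapq=rec.mapping_quality,
                    )
                )
            except ValueError as exc:
                logger.warning("read %s: %s; skipped", rec.query_name, exc)
    return reads


def parse_annotation(path: str | os.PathLike) -> list[TranscriptModel]:
    """Parse a GTF into TranscriptModel records (0-based half-open exons).

    Exon features lacking a ``transcript_id`` are skipped with a warning;
    transcripts whose exons overlap are rejected as malformed records.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        return []
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception:
        # a file with only comment lines or no parsable features
        return []

    by_tid: dict[str, dict] = {}
    order: list[str] = []
    for feat in db.features_of_type("exon"):
        tids = feat.attributes.get("transcript_id")
        if not tids:
            logger.warning("exon at %s:%d-%d lacks transcript_id; skipped", feat.seqid, feat.start, feat.end)
            continue
        tid = tids[0]
        gid = (feat.attributes.get("gene_id") or [tid])[0]
        rec = by_tid.get(tid)
        if rec is None:
            rec = {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
            by_tid[tid] = rec
            order.append(tid)
        # GTF is 1-based closed -> 0-based half-open
        rec["exons"].append((feat.start - 1, feat.end))

    transcripts: list[TranscriptModel] = []
    for tid in order:
        rec = by_tid[tid]
        exons = sorted(rec["exons"])
        prev_end = -1
        ok = True
        for s, e in exons:
            if s < prev_end:
                logger.warning("transcript %s has overlapping exons; skipped", tid)
                ok = False
                break
            prev_end = e
        if not ok:
            continue
        strand = rec["strand"] if rec["strand"] in ("+", "-") else "+"
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=strand,
                exons=tuple(GenomicInterval(rec["chrom"], s, e, strand) for s, e in exons),
            )
        )
    return transcripts


@dataclass
class PolyACallTable:
    """read_id -> poly(A) status; reads absent from the table are unknown."""

    calls: dict[str, PolyAStatus] = field(default_factory=dict)

    def get(self, read_id: str) -> PolyAStatus:
        return self.calls.get(read_id, PolyAStatus.UNKNOWN)

    def __len__(self) -> int:
        return len(self.calls)

    def attach(self, reads: list[AlignedRead]) -> None:
        for r in reads:
            r.polya = self.get(r.read_id)


def parse_polya_table(
    path: str | os.PathLike,
    read_col: str = "readname",
    qc_col: str = "qc_tag",
    pass_tag: str = "PASS",
) -> PolyACallTable:
    """Parse a per-read poly(A) QC table (nanopolish-polya dialect by default).

    Rows whose QC tag equals ``pass_tag`` become polyadenylated; every other
    listed read becomes not-polyadenylated. Duplicate read ids keep the
    first row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if read_col not in df.columns or qc_col not in df.columns:
        # headerless fallback: first column read id, last column QC tag
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
        df = df.rename(columns={df.columns[0]: read_col, df.columns[-1]: qc_col})
    calls: dict[str, PolyAStatus] = {}
    n_dup = 0
    for rid, tag in zip(df[read_col], df[qc_col]):
        if rid in calls:
            n_dup += 1
            continue
        calls[rid] = (
            PolyAStatus.POLYADENYLATED if tag == pass_tag else PolyAStatus.NOT_POLYADENYLATED
        )
    if n_dup:
        logger.warning("%d duplicate read ids in poly(A) table; kept first occurrence", n_dup)
    return PolyACallTable(calls)


@dataclass
class PeakSet:
    """Strand-aware interval set (CAGE/SAGE peaks or poly(A) clusters)."""

    label: str = "cage"
    _trees: dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree())[iv.start:iv.end] = iv.strand

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def contains(self, chrom: str, position: int, window: int = 0, strand: str | None = None) -> bool:
        """True iff ``position`` falls inside some peak extended by ±window.

        Peaks without strand ('.') match any query strand; a query without
        strand matches peaks on either strand.
        """
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        for hit in tree.overlap(position - window, position + window + 1):
            if strand is None or hit.data == "." or hit.data == strand:
                return True
        return False


def parse_bed(path: str | os.PathLike, label: str = "cage") -> PeakSet:
    """Read a BED3/BED6 file of peaks (0-based half-open, as BED is)."""
    peaks = PeakSet(label=label)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            peaks.add(GenomicInterval(chrom, start, end, strand))
    return peaks


def write_bed(intervals: list[GenomicInterval], path: str | os.PathLike, names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"peak_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def _gtf_attributes(obj) -> str:
    attrs = [f'gene_id "{obj.gene_id}"', f'transcript_id "{obj.transcript_id}"']
    if isinstance(obj, IsoformCall):
        attrs.append(f'read_support "{obj.n_reads}"')
        attrs.append(f'polya_reads "{obj.n_polya}"')
        attrs.append(f'novel_chain "{str(obj.is_novel_chain).lower()}"')
        attrs.append(f'tss_evidence "{obj.tss_evidence}"')
        if obj.single_exon:
            attrs.append('single_exon "true"')
    return "; ".join(attrs) + ";"


def write_isoform_gtf(
    isoforms: list[IsoformCall] | list[TranscriptModel],
    path: str | os.PathLike,
    source: str = "isoforge",
) -> None:
    """Write transcript models as GTF (1-based closed); round-trips through
    :func:`parse_annotation` losslessly at the exon-structure level."""
    with open(path, "w") as fh:
        for iso in isoforms:
            attrs = _gtf_attributes(iso)
            left = iso.exons[0].start + 1
            right = iso.exons[-1].end
            fh.write(
                f"{iso.chrom}\t{source}\ttranscript\t{left}\t{right}\t.\t{iso.strand}\t.\t{attrs}\n"
            )
            for ex in iso.exons:
                fh.write(
                    f"{iso.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t{iso.strand}\t.\t{attrs}\n"
                )
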