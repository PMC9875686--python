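"""Benchmarking and characterization metrics for assembled isoform sets.

Matching follows the intron-chain-equality ("=" class code) convention:
an assembled isoform matches a reference transcript when their ordered
junction lists are identical on the same chromosome and strand; terminal
TSS/TES positions are not compared. Structural categories follow the
standard long-read taxonomy: FSM (full-splice match), ISM (contiguous
sub-chain of a reference chain), NIC (all splice sites annotated but the
chain is new), NNC (at least one unannotated site).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .formats_io import PeakSet
from .model import IntronChain, IsoformCall, TranscriptModel
from .reference_index import ReferenceIndex


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else math.nan

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan


@dataclass
class StructuralCategory:
    category: str  # FSM | ISM | NIC | NNC | single_exon
    truncation: str | None = None  # for ISM: 5prime | 3prime | both | internal
    parent_transcript_id: str | None = None


@dataclass(frozen=True)
class ExpressionRecord:
    transcript_id: str
    tpm: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.tpm) or self.tpm < 0:
            raise ValueError(f"tpm must be finite and >= 0, got {self.tpm}")


def _chain_of(iso) -> IntronChain:
    return iso.chain if isinstance(iso, IsoformCall) else iso.intron_chain()


def match_isoform(assembled, index: ReferenceIndex) -> str | None:
    """Reference transcript_id with an identical intron chain, or None.

    Single-exon isoforms match a single-exon reference transcript by
    reciprocal overlap >= 0.5. When several references share the chain,
    the smallest transcript_id is returned (deterministic).
    """
    chain = _chain_of(assembled)
    if chain.is_single_exon():
        refs = index.single_exon_refs.get((assembled.chrom, assembled.strand), [])
        span = assembled.span
        best = None
        for s, e, tid in refs:
            ov = max(0, min(e, span.end) - max(s, span.start))
            if ov and min(ov / len(span), ov / (e - s)) >= 0.5:
                if best is None or tid < best:
                    best = tid
        return best
    tids = index.chain_lookup.get(chain)
    return min(tids) if tids else None


def precision_recall(assembly: list, index: ReferenceIndex) -> EvaluationResult:
    """Assembly-level precision/recall by intron-chain matching.

    Each reference transcript can satisfy at most one assembled isoform;
    assembled isoforms are processed in sorted transcript_id order.
    """
    consumed: set[str] = set()
    tp = fp = 0
    ordered = sorted(assembly, key=lambda i: i.transcript_id)
    for iso in ordered:
        chain = _chain_of(iso)
        candidates: list[str] = []
        if chain.is_single_exon():
            hit = match_isoform(iso, index)
            if hit is not None:
                refs = index.single_exon_refs.get((iso.chrom, iso.strand), [])
                span = iso.span
                for s, e, tid in refs:
                    ov = max(0, min(e, span.end) - max(s, span.start))
                    if ov and min(ov / len(span), ov / (e - s)) >= 0.5:
                        candidates.append(tid)
        else:
            candidates = list(index.chain_lookup.get(chain, []))
        free = sorted(c for c in candidates if c not in consumed)
        if free:
            consumed.add(free[0])
            tp += 1
        else:
            fp += 1
    fn = len(index.transcripts) - len(consumed)
    return EvaluationResult(tp=tp, fp=fp, fn=fn)


def boundary_support_rate(
    isoforms: list, peaks: PeakSet, side: str = "tss", window: int = 25
) -> float:
    """Fraction of isoforms whose 5' (or 3') terminus falls within a peak
    extended by ±window bp. NaN on an empty isoform set."""
    if side not in ("tss", "tes"):
        raise ValueError(f"side must be tss or tes, got {side!r}")
    if not isoforms:
        return math.nan
    n_supported = 0
    for iso in isoforms:
        pos = iso.tss if side == "tss" else iso.tes
        if peaks.contains(iso.chrom, pos, window, iso.strand):
            n_supported += 1
    return n_supported / len(isoforms)


def recall_under_cutoff(
    assembly: list,
    index: ReferenceIndex,
    expression: list[ExpressionRecord],
    cutoff: float,
) -> float:
    """Recall restricted to reference transcripts expressed at 0 < TPM <= cutoff."""
    tpm = {rec.transcript_id: rec.tpm for rec in expression}
    eligible = [
        tx.transcript_id
        for tx in index.transcripts
        if 0 < tpm.get(tx.transcript_id, 0.0) <= cutoff
    ]
    if not eligible:
        return math.nan
    matched: set[str] = set()
    for iso in assembly:
        chain = _chain_of(iso)
        if chain.is_single_exon():
            hit = match_isoform(iso, index)
            if hit is not None:
                matched.add(hit)
        else:
            for tid in index.chain_lookup.get(chain, []):
                matched.add(tid)
    return sum(1 for tid in eligible if tid in matched) / len(eligible)


def _is_contiguous_subchain(
    sub: tuple[tuple[int, int], ...], parent: tuple[tuple[int, int], ...]
) -> int | None:
    """Genomic start index of sub within parent as a consecutive run, else None."""
    n, m = len(sub), len(parent)
    if n == 0 or n > m:
        return None
    for i in range(m - n + 1):
        if parent[i : i + n] == sub:
            return i
    return None


def classify_structure(isoform, index: ReferenceIndex) -> StructuralCategory:
    """Assign FSM/ISM/NIC/NNC (or single_exon) by chain comparison."""
    chain = _chain_of(isoform)
    if chain.is_single_exon():
        return StructuralCategory("single_exon")
    key = (chain.chrom, chain.strand)
    tids = index.chain_lookup.get(chain)
    if tids:
        return StructuralCategory("FSM", parent_transcript_id=min(tids))
    best_parent = None
    for parent_junctions, tid in sorted(index.chains_by_key.get(key, []), key=lambda x: x[1]):
        if len(parent_junctions) <= len(chain.junctions):
            continue
        offset = _is_contiguous_subchain(chain.junctions, parent_junctions)
        if offset is not None:
            best_parent = (tid, parent_junctions, offset)
            break
    if best_parent is not None:
        tid, parent_junctions, _ = best_parent
        parent_chain = IntronChain(chain.chrom, chain.strand, parent_junctions)
        trunc = ism_truncation(chain, parent_chain)
        return StructuralCategory("ISM", truncation=trunc, parent_transcript_id=tid)
    all_known = all(
        index.is_annotated_site(chain.chrom, chain.strand, sj.donor, "donor")
        and index.is_annotated_site(chain.chrom, chain.strand, sj.acceptor, "acceptor")
        for sj in chain.splice_junctions()
    )
    return StructuralCategory("NIC" if all_known else "NNC")


def ism_truncation(ism: IntronChain, parent: IntronChain) -> str:
    """Which transcript end(s) an incomplete splice match lost.

    In transcript orientation: keeping the parent's first junction while
    ending early is a 3' truncation; keeping the last while starting late
    is a 5' truncation; losing both ends is 'both'. Strand-aware: on -,
    the genomic-first junction is the transcript-last one.
    """
    offset = _is_contiguous_subchain(ism.junctions, parent.junctions)
    if offset is None or len(ism.junctions) >= len(parent.junctions):
        raise ValueError("ism must be a proper contiguous sub-chain of parent")
    at_genomic_start = offset == 0
    at_genomic_end = offset + len(ism.junctions) == len(parent.junctions)
    if ism.strand == "+":
        at_5p, at_3p = at_genomic_start, at_genomic_end
    else:
        at_5p, at_3p = at_genomic_end, at_genomic_start
    if at_5p and not at_3p:
        return "3prime"
    if at_3p and not at_5p:
        return "5prime"
    if not at_5p and not at_3p:
        return "both"
    return "internal"  # unreachable for a proper sub-chain


def relative_start_exon(ism, parent: TranscriptModel) -> float:
    """Ordinal of the ISM's starting exon over the parent's exon count,
    both in transcript (5'->3') orientation."""
    ism_chain = _chain_of(ism)
    parent_junctions = parent.introns()
    offset = _is_contiguous_subchain(ism_chain.junctions, parent_junctions)
    if offset is None:
        raise ValueError("ism chain does not map onto parent exon structure")
    n_exons = len(parent.exons)
    if parent.strand == "+":
        ordinal = offset + 1
    else:
        genomic_last = offset + len(ism_chain.junctions)  # exon index after last junction
        ordinal = n_exons - genomic_last
    return ordinal / n_exons


def relative_intron_position(intron_ordinal: int, total_introns: int) -> float:
    """Ordinal / total, in transcript orientation (1-based ordinal)."""
    if total_introns <= 0:
        raise ValueError("total_introns must be positive")
    if not 1 <= intron_ordinal <= total_introns:
        raise ValueError("intron_ordinal out of range")
    return intron_ordinal / total_introns


def read_count_cdf(isoforms: list[IsoformCall]) -> list[tuple[int, float]]:
    """Cumulative fraction of isoforms with read support <= x, ascending x."""
    if not isoforms:
        return []
    counts = sorted(iso.n_reads for iso in isoforms)
    n = len(counts)
    out: list[tuple[int, float]] = []
    seen = 0
    for value in sorted(set(counts)):
        seen += counts.count(value)
        out.append((value, seen / n))
    return out


def low_coverage_probability(
    tpm: float,
    total_reads: int,
    max_reads: int = 2,
    mode: str = "exact",
    n_sims: int = 100_000,
    seed: int = 42,
) -> float:
    """P(a transcript at ``tpm`` receives <= max_reads reads) in a run of
    ``total_reads``, under binomial sampling with p = tpm * 1e-6."""
    if tpm < 0 or total_reads < 1:
        raise ValueError("tpm must be >= 0 and total_reads >= 1")
    p = tpm * 1e-6
    if p > 1:
        raise ValueError(f"tpm {tpm} implies sampling probability > 1")
    if p == 0:
        return 1.0
    if mode == "exact":
        return float(stats.binom.cdf(max_reads, total_reads, p))
    if mode == "simulate":
        rng = np.random.default_rng(seed)
        draws = rng.binomial(total_reads, p, size=n_sims)
        return float(np.mean(draws <= max_reads))
    raise ValueError(f"mode must be exact or simulate, got {mode!r}")
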