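"""Three-step artifact/truncation filtering and pipeline orchestration.

A collapsed cluster survives when

1. every *novel* splice junction it uses is seen in at least
   ``min_sj_reads`` reads genome-wide (annotated junctions are exempt);
2. if its intron chain is novel, at least ``min_polya_reads`` member reads
   carry a confirmed polyadenylation event (reference chains are exempt;
   single-exon clusters are always subject);
3. its estimated TSS is supported — within ``tss_window`` of an annotated
   TSS, or inside a CAGE peak extended by the same window.

Survivors are emitted as high-consensus full-length isoforms. Because the
filters judge evidence quality rather than read depth, an isoform backed
by a single polyadenylated, TSS-supported read is kept — the low-abundance
rescue that coverage-thresholding assemblers cannot perform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from intervaltree import IntervalTree

from .clustering_boundaries import (
    BoundaryEstimate,
    ReadCluster,
    cluster_model_exons,
    cluster_single_exon,
    estimate_boundaries,
    group_by_intron_chain,
)
from .formats_io import (
    PeakSet,
    PolyACallTable,
    parse_alignments,
    parse_annotation,
    parse_bed,
    parse_polya_table,
    write_isoform_gtf,
)
from .junction_correction import correct_all
from .model import AlignedRead, IntronChain, IsoformCall, SpliceJunction, TranscriptModel
from .reference_index import ReferenceIndex, build_reference_index

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """All pipeline thresholds in one place."""

    max_shift: int = 40          # junction correction bound (bp)
    min_sj_reads: int = 2        # genome-wide support for a novel junction
    min_polya_reads: int = 1     # confirmed poly(A) reads for a novel chain
    tss_window: int = 50         # TSS filter window (bp)
    eval_window: int = 25        # orthogonal-evidence window for evaluation (bp)
    min_gmm_reads: int = 3       # below this, median boundary fallback
    max_components: int = 3
    min_component_weight: float = 0.2
    variance_floor: float = 1.0  # bp^2
    min_overlap_frac: float = 0.5
    min_mapq: int = 1
    polya_pass_tag: str = "PASS"
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("max_shift", "min_sj_reads", "min_polya_reads", "tss_window",
                     "eval_window", "min_gmm_reads", "min_mapq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ClusterCall:
    """A cluster plus everything the filters need to judge it."""

    cluster: ReadCluster
    tss: BoundaryEstimate
    tes: BoundaryEstimate
    is_novel_chain: bool
    tss_evidence: str = "none"
    filter_trace: dict = field(default_factory=dict)

    @property
    def chain(self) -> IntronChain:
        return self.cluster.chain

    @property
    def n_reads(self) -> int:
        return self.cluster.n_reads

    @property
    def n_polya(self) -> int:
        return self.cluster.n_polya

    @property
    def single_exon(self) -> bool:
        return self.chain.is_single_exon()


def count_junction_support(reads: list[AlignedRead]) -> dict[SpliceJunction, int]:
    """Per-junction read counts over the full (pre-collapse) read set."""
    counts: dict[SpliceJunction, int] = {}
    for read in reads:
        for sj in read.intron_chain().splice_junctions():
            counts[sj] = counts.get(sj, 0) + 1
    return counts


def evaluate_clusters(
    clusters: list[ReadCluster], index: ReferenceIndex, config: FilterConfig
) -> list[ClusterCall]:
    """Estimate boundaries and novelty for each cluster."""
    calls = []
    for cluster in clusters:
        tss, tes = estimate_boundaries(
            cluster,
            min_gmm_reads=config.min_gmm_reads,
            max_components=config.max_components,
            min_component_weight=config.min_component_weight,
            variance_floor=config.variance_floor,
            seed=config.seed,
        )
        if cluster.chain.is_single_exon():
            novel = not _matches_single_exon_ref(cluster, index)
        else:
            novel = not index.has_chain(cluster.chain)
        calls.append(ClusterCall(cluster=cluster, tss=tss, tes=tes, is_novel_chain=novel))
    return calls


def _matches_single_exon_ref(cluster: ReadCluster, index: ReferenceIndex) -> bool:
    refs = index.single_exon_refs.get((cluster.chrom, cluster.strand), [])
    span = None
    lo = min(cluster.start_positions + cluster.end_positions)
    hi = max(cluster.start_positions + cluster.end_positions)
    length = hi - lo
    if length <= 0:
        return False
    for s, e, _tid in refs:
        ov = max(0, min(e, hi) - max(s, lo))
        if ov and min(ov / length, ov / (e - s)) >= 0.5:
            return True
    return False


def filter_novel_junctions(
    calls: list[ClusterCall],
    index: ReferenceIndex,
    support: dict[SpliceJunction, int],
    min_sj_reads: int = 2,
) -> tuple[list[ClusterCall], list[ClusterCall]]:
    """Step 1: drop clusters using an under-supported novel junction."""
    kept, dropped = [], []
    for call in calls:
        bad = False
        for sj in call.chain.splice_junctions():
            if not index.is_annotated_junction(sj) and support.get(sj, 0) < min_sj_reads:
                bad = True
                break
        call.filter_trace["novel_junction"] = "fail" if bad else "pass"
        (dropped if bad else kept).append(call)
    return kept, dropped


def filter_polya(
    calls: list[ClusterCall],
    index: ReferenceIndex,
    min_polya_reads: int = 1,
) -> tuple[list[ClusterCall], list[ClusterCall]]:
    """Step 2: novel chains (and all single-exon clusters) need confirmed
    polyadenylation; reference chains are exempt."""
    kept, dropped = [], []
    for call in calls:
        subject = call.is_novel_chain or call.single_exon
        if not subject:
            call.filter_trace["polya"] = "exempt"
            kept.append(call)
        elif call.n_polya >= min_polya_reads:
            call.filter_trace["polya"] = "pass"
            kept.append(call)
        else:
            call.filter_trace["polya"] = "fail"
            dropped.append(call)
    return kept, dropped


def filter_tss(
    calls: list[ClusterCall],
    index: ReferenceIndex,
    cage: PeakSet | None = None,
    tss_window: int = 50,
) -> tuple[list[ClusterCall], list[ClusterCall]]:
    """Step 3: the primary TSS needs annotated-TSS or CAGE support."""
    kept, dropped = [], []
    for call in calls:
        chrom, strand = call.cluster.chrom, call.cluster.strand
        evidence = "none"
        dist = index.nearest_tss_distance(chrom, strand, call.tss.primary)
        if dist is not None and dist <= tss_window:
            evidence = "annotated"
        elif cage is not None and cage.contains(chrom, call.tss.primary, tss_window, strand):
            evidence = "cage"
        call.tss_evidence = evidence
        call.filter_trace["tss"] = "pass" if evidence != "none" else "fail"
        (kept if evidence != "none" else dropped).append(call)
    return kept, dropped


def filter_min_reads(
    calls: list[ClusterCall], min_reads: int = 3
) -> tuple[list[ClusterCall], list[ClusterCall]]:
    """Coverage-threshold baseline (what depth-reliant assemblers do);
    used only for comparison, never by the pipeline itself."""
    kept = [c for c in calls if c.n_reads >= min_reads]
    dropped = [c for c in calls if c.n_reads < min_reads]
    return kept, dropped


def _assign_gene_ids(calls: list[ClusterCall], index: ReferenceIndex) -> list[str]:
    """Reference gene with maximal exonic overlap; novel loci get a
    NOVELG_ counter shared by overlapping novel calls."""
    trees: dict[str, IntervalTree] = {}
    for tx in index.transcripts:
        tree = trees.setdefault(tx.chrom, IntervalTree())
        for ex in tx.exons:
            tree[ex.start:ex.end] = tx.gene_id

    gene_ids: list[str] = [""] * len(calls)
    novel: list[int] = []
    for i, call in enumerate(calls):
        lo = min(call.tss.primary, call.tes.primary)
        hi = max(call.tss.primary, call.tes.primary)
        overlap: dict[str, int] = {}
        tree = trees.get(call.cluster.chrom)
        if tree is not None:
            for hit in tree.overlap(lo, hi):
                ov = min(hit.end, hi) - max(hit.begin, lo)
                overlap[hit.data] = overlap.get(hit.data, 0) + ov
        if overlap:
            gene_ids[i] = max(sorted(overlap), key=lambda g: overlap[g])
        else:
            novel.append(i)

    # group novel calls into loci by span overlap on the same strand
    novel.sort(key=lambda i: (calls[i].cluster.chrom, min(calls[i].tss.primary, calls[i].tes.primary)))
    counter = 0
    locus_end: dict[tuple[str, str], int] = {}
    locus_id: dict[tuple[str, str], str] = {}
    for i in novel:
        call = calls[i]
        key = (call.cluster.chrom, call.cluster.strand)
        lo = min(call.tss.primary, call.tes.primary)
        hi = max(call.tss.primary, call.tes.primary)
        if key in locus_end and lo < locus_end[key]:
            locus_end[key] = max(locus_end[key], hi)
        else:
            counter += 1
            locus_id[key] = f"NOVELG_{counter:05d}"
            locus_end[key] = hi
        gene_ids[i] = locus_id[key]
    return gene_ids


def emit_isoforms(calls: list[ClusterCall], index: ReferenceIndex) -> list[IsoformCall]:
    """Build IsoformCall records for surviving clusters, re-asserting the
    three filter predicates."""
    calls = sorted(
        calls, key=lambda c: (c.cluster.chrom, min(c.tss.primary, c.tes.primary), c.cluster.strand)
    )
    gene_ids = _assign_gene_ids(calls, index)
    isoforms: list[IsoformCall] = []
    for i, call in enumerate(calls):
        assert call.filter_trace.get("novel_junction") != "fail"
        assert call.filter_trace.get("polya") != "fail"
        assert call.tss_evidence != "none"
        exons = cluster_model_exons(call.cluster, call.tss, call.tes)
        isoforms.append(
            IsoformCall(
                transcript_id=f"ISOFORGE_{i + 1:06d}",
                gene_id=gene_ids[i],
                chrom=call.cluster.chrom,
                strand=call.cluster.strand,
                exons=exons,
                chain=call.chain,
                n_reads=call.n_reads,
                n_polya=call.n_polya,
                is_novel_chain=call.is_novel_chain,
                tss_evidence=call.tss_evidence,
                single_exon=call.single_exon,
                tss_method=call.tss.method,
                tes_method=call.tes.method,
                filter_trace=dict(call.filter_trace),
            )
        )
    return isoforms


@dataclass
class PipelineResult:
    isoforms: list[IsoformCall]
    stage_counts: dict[str, int]
    dropped: dict[str, list[ClusterCall]]


def run_pipeline(
    reads: list[AlignedRead],
    reference: list[TranscriptModel],
    polya: PolyACallTable | None = None,
    cage: PeakSet | None = None,
    config: FilterConfig | None = None,
) -> PipelineResult:
    """In-memory pipeline: correct -> collapse -> boundaries -> 3 filters -> emit."""
    config = config or FilterConfig()
    index = build_reference_index(reference)
    if polya is not None:
        polya.attach(reads)

    corrected, _records, summary = correct_all(reads, index, config.max_shift)
    support = count_junction_support(corrected)

    clusters = group_by_intron_chain(corrected)
    clusters += cluster_single_exon(corrected, config.min_overlap_frac)
    calls = evaluate_clusters(clusters, index, config)

    kept1, drop1 = filter_novel_junctions(calls, index, support, config.min_sj_reads)
    kept2, drop2 = filter_polya(kept1, index, config.min_polya_reads)
    kept3, drop3 = filter_tss(kept2, index, cage, config.tss_window)
    isoforms = emit_isoforms(kept3, index)

    stage_counts = {
        "reads": len(reads),
        "spliced_reads": summary.n_spliced_reads,
        "corrected_junction_sides": summary.corrected_donor + summary.corrected_acceptor,
        "clusters": len(calls),
        "after_junction_filter": len(kept1),
        "after_polya_filter": len(kept2),
        "after_tss_filter": len(kept3),
        "isoforms": len(isoforms),
    }
    for name, n in stage_counts.items():
        logger.info("%s: %d", name, n)
    return PipelineResult(
        isoforms=isoforms,
        stage_counts=stage_counts,
        dropped={"novel_junction": drop1, "polya": drop2, "tss": drop3},
    )


def call_isoforms(
    bam: str,
    gtf: str,
    polya: str | None = None,
    cage: str | None = None,
    out_gtf: str | None = None,
    config: FilterConfig | None = None,
) -> PipelineResult:
    """Path-based entry point mirroring the CLI."""
    config = config or FilterConfig()
    reads = parse_alignments(bam, min_mapq=config.min_mapq)
    reference = parse_annotation(gtf)
    polya_table = (
        parse_polya_table(polya, pass_tag=config.polya_pass_tag) if polya else None
    )
    cage_peaks = parse_bed(cage, label="cage") if cage else None
    result = run_pipeline(reads, reference, polya_table, cage_peaks, config)
    if out_gtf is not None:
        if not result.isoforms:
            logger.warning("no isoforms survived filtering; writing empty GTF")
        write_isoform_gtf(result.isoforms, out_gtf)
    return result


def merge_assemblies(assemblies: list[list[IsoformCall]]) -> list[IsoformCall]:
    """Merge fraction-specific assemblies into a nonredundant isoform set.

    Spliced isoforms merge on identical (chrom, strand, intron chain); the
    member with most reads contributes the boundaries and read counts are
    summed. Single-exon isoforms merge by reciprocal overlap >= 0.5
    (single linkage) on the same strand.
    """
    by_chain: dict[IntronChain, list[IsoformCall]] = {}
    single: list[IsoformCall] = []
    for assembly in assemblies:
        for iso in assembly:
            if iso.single_exon or iso.chain.is_single_exon():
                single.append(iso)
            else:
                by_chain.setdefault(iso.chain, []).append(iso)

    merged: list[IsoformCall] = []
    for members in by_chain.values():
        merged.append(_merge_members(members))

    # single-linkage on single-exon spans
    by_key: dict[tuple[str, str], list[IsoformCall]] = {}
    for iso in single:
        by_key.setdefault((iso.chrom, iso.strand), []).append(iso)
    for group in by_key.values():
        group = sorted(group, key=lambda i: (i.span.start, i.span.end, i.transcript_id))
        parent = list(range(len(group)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a in range(len(group)):
            for b in range(a + 1, len(group)):
                if group[b].span.start >= group[a].span.end:
                    break
                if group[a].span.reciprocal_overlap(group[b].span) >= 0.5:
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[rb] = ra
        comp: dict[int, list[IsoformCall]] = {}
        for i in range(len(group)):
            comp.setdefault(find(i), []).append(group[i])
        for members in comp.values():
            merged.append(_merge_members(members))

    merged.sort(key=lambda i: (i.chrom, i.span.start, i.transcript_id))
    return merged


def _merge_members(members: list[IsoformCall]) -> IsoformCall:
    rep = max(members, key=lambda i: (i.n_reads, i.transcript_id))
    if len(members) == 1:
        return rep
    return replace(
        rep,
        n_reads=sum(m.n_reads for m in members),
        n_polya=sum(m.n_polya for m in members),
        filter_trace=dict(rep.filter_trace),
    )
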