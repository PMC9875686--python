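"""Intron-chain collapsing and transcript-boundary estimation.

Corrected reads sharing an identical intron chain are collapsed into one
cluster. The cluster's 5' start positions and 3' end positions are then
modelled with a one-dimensional Gaussian mixture (component count chosen
by BIC over k = 1..3): with pervasive 5' truncation the start positions
are a mixture of a true-TSS mode and one or more truncation modes, and
the highest-weight component identifies the transcript start. Clusters
too small for EM fall back to an order-statistic median that favours the
5'-most (for TSS) / 3'-most (for TES) observation on even counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .model import AlignedRead, GenomicInterval, IntronChain, PolyAStatus

DEFAULT_MIN_GMM_READS = 3
DEFAULT_MAX_COMPONENTS = 3
DEFAULT_MIN_COMPONENT_WEIGHT = 0.2
DEFAULT_VARIANCE_FLOOR = 1.0


@dataclass
class ReadCluster:
    """Reads sharing one intron chain, with their terminus samples."""

    chain: IntronChain
    reads: list[AlignedRead] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.chain.chrom

    @property
    def strand(self) -> str:
        return self.chain.strand

    @property
    def start_positions(self) -> list[int]:
        return [r.five_prime for r in self.reads]

    @property
    def end_positions(self) -> list[int]:
        return [r.three_prime for r in self.reads]

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def n_polya(self) -> int:
        return sum(1 for r in self.reads if r.polya is PolyAStatus.POLYADENYLATED)


@dataclass
class GmmFit:
    means: tuple[float, ...]
    variances: tuple[float, ...]
    weights: tuple[float, ...]
    k: int
    bic_by_k: dict[int, float] = field(default_factory=dict)


@dataclass
class BoundaryEstimate:
    primary: int
    candidates: list[tuple[int, float]]
    method: str  # gmm | median


def group_by_intron_chain(reads: list[AlignedRead]) -> list[ReadCluster]:
    """Exact partition of spliced reads by (chrom, strand, intron chain)."""
    clusters: dict[IntronChain, ReadCluster] = {}
    for read in reads:
        if not read.is_spliced():
            continue
        chain = read.intron_chain()
        cluster = clusters.get(chain)
        if cluster is None:
            cluster = clusters[chain] = ReadCluster(chain=chain)
        cluster.reads.append(read)
    return list(clusters.values())


def cluster_single_exon(
    reads: list[AlignedRead], min_overlap_frac: float = 0.5
) -> list[ReadCluster]:
    """Single-linkage clustering of unspliced reads by reciprocal overlap.

    Two same-strand reads are linked when their reciprocal overlap (the
    smaller of overlap/len_a and overlap/len_b) reaches ``min_overlap_frac``.
    """
    by_key: dict[tuple[str, str], list[AlignedRead]] = {}
    for read in reads:
        if read.is_spliced():
            continue
        by_key.setdefault((read.chrom, read.strand), []).append(read)

    clusters: list[ReadCluster] = []
    for (chrom, strand), group in by_key.items():
        group = sorted(group, key=lambda r: (r.span.start, r.span.end, r.read_id))
        parent = list(range(len(group)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i: int, j: int) -> None:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

        active: list[int] = []
        for j, read in enumerate(group):
            span_j = read.span
            still = []
            for i in active:
                span_i = group[i].span
                if span_i.end <= span_j.start:
                    continue
                still.append(i)
                if span_i.reciprocal_overlap(span_j) >= min_overlap_frac:
                    union(i, j)
            active = still + [j]

        members: dict[int, list[AlignedRead]] = {}
        for i, read in enumerate(group):
            members.setdefault(find(i), []).append(read)
        for reads_in in members.values():
            clusters.append(
                ReadCluster(chain=IntronChain(chrom, strand, ()), reads=reads_in)
            )
    return clusters


def fit_boundary_gmm(
    positions: list[int],
    max_components: int = DEFAULT_MAX_COMPONENTS,
    seed: int = 42,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    min_gmm_reads: int = DEFAULT_MIN_GMM_READS,
) -> GmmFit:
    """Fit 1-D Gaussian mixtures for k = 1..min(max_components, #distinct)
    and return the BIC-minimizing fit. The variance floor enters EM as a
    covariance regularizer, preventing singular components on duplicated
    positions."""
    if len(positions) < min_gmm_reads:
        raise ValueError(
            f"need >= {min_gmm_reads} positions for a mixture fit, got {len(positions)}"
        )
    arr = np.asarray(positions, dtype=float).reshape(-1, 1)
    n_distinct = len(np.unique(arr))
    if n_distinct == 1:
        return GmmFit(
            means=(float(arr[0, 0]),),
            variances=(variance_floor,),
            weights=(1.0,),
            k=1,
            bic_by_k={1: float("nan")},
        )
    best = None
    bic_by_k: dict[int, float] = {}
    for k in range(1, min(max_components, n_distinct) + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            reg_covar=variance_floor,
            random_state=seed,
            n_init=1,
            max_iter=200,
        ).fit(arr)
        bic = float(gm.bic(arr))
        bic_by_k[k] = bic
        if best is None or bic < best[0]:
            best = (bic, gm, k)
    _, gm, k = best
    return GmmFit(
        means=tuple(float(m) for m in gm.means_.ravel()),
        variances=tuple(float(v) for v in gm.covariances_.ravel()),
        weights=tuple(float(w) for w in gm.weights_.ravel()),
        k=k,
        bic_by_k=bic_by_k,
    )


def _directional_median(positions: list[int], prefer_high: bool) -> int:
    """Order-statistic median; on even counts, take the element nearer the
    preferred (5' or 3') side rather than interpolating."""
    s = sorted(positions)
    n = len(s)
    return s[n // 2] if prefer_high else s[(n - 1) // 2]


def _estimate_one(
    positions: list[int],
    prefer_high: bool,
    min_gmm_reads: int,
    max_components: int,
    min_component_weight: float,
    variance_floor: float,
    seed: int,
) -> BoundaryEstimate:
    lo, hi = min(positions), max(positions)
    if len(positions) < min_gmm_reads or lo == hi:
        pos = _directional_median(positions, prefer_high)
        return BoundaryEstimate(primary=pos, candidates=[(pos, 1.0)], method="median")
    fit = fit_boundary_gmm(
        positions,
        max_components=max_components,
        seed=seed,
        variance_floor=variance_floor,
        min_gmm_reads=min_gmm_reads,
    )
    # highest-weight component wins; weight ties (within 1e-9) break toward
    # the preferred terminus side, since truncation only shifts positions
    # away from the true terminus
    wmax = max(fit.weights)
    tied = [i for i, w in enumerate(fit.weights) if w >= wmax - 1e-9]
    order = max(tied, key=lambda i: fit.means[i]) if prefer_high else min(
        tied, key=lambda i: fit.means[i]
    )
    primary = int(round(fit.means[order]))
    primary = min(max(primary, lo), hi)
    candidates = [
        (min(max(int(round(m)), lo), hi), w)
        for m, w in zip(fit.means, fit.weights)
        if w >= min_component_weight
    ]
    if primary not in [c[0] for c in candidates]:
        candidates.append((primary, fit.weights[order]))
    candidates.sort(key=lambda c: -c[1])
    return BoundaryEstimate(primary=primary, candidates=candidates, method="gmm")


def estimate_boundaries(
    cluster: ReadCluster,
    min_gmm_reads: int = DEFAULT_MIN_GMM_READS,
    max_components: int = DEFAULT_MAX_COMPONENTS,
    min_component_weight: float = DEFAULT_MIN_COMPONENT_WEIGHT,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    seed: int = 42,
) -> tuple[BoundaryEstimate, BoundaryEstimate]:
    """Estimate (TSS, TES) for one cluster, each independently.

    The TES (and symmetrically the TSS) is clamped so the terminal exons of
    the resulting model keep at least 1 bp beyond the outermost junctions.
    """
    if not cluster.reads:
        raise ValueError("cannot estimate boundaries of an empty cluster")
    minus = cluster.strand == "-"
    # 5'-most means the smaller coordinate on +, the larger on -
    tss = _estimate_one(
        cluster.start_positions, minus, min_gmm_reads, max_components,
        min_component_weight, variance_floor, seed,
    )
    tes = _estimate_one(
        cluster.end_positions, not minus, min_gmm_reads, max_components,
        min_component_weight, variance_floor, seed,
    )
    junctions = cluster.chain.junctions
    if junctions:
        first, last = junctions[0], junctions[-1]
        if not minus:
            tss.primary = min(tss.primary, first[0] - 1)
            tes.primary = max(tes.primary, last[1] + 1)
        else:
            tss.primary = max(tss.primary, last[1] + 1)
            tes.primary = min(tes.primary, first[0] - 1)
    elif tss.primary == tes.primary:
        # degenerate single-exon cluster: keep a 1 bp model
        if minus:
            tss.primary += 1
        else:
            tes.primary += 1
    return tss, tes


def cluster_model_exons(
    cluster: ReadCluster, tss: BoundaryEstimate, tes: BoundaryEstimate
) -> tuple[GenomicInterval, ...]:
    """Exon structure of the collapsed model: the chain's introns spanned
    from primary TSS to primary TES."""
    left = min(tss.primary, tes.primary)
    right = max(tss.primary, tes.primary)
    bounds = [left]
    for s, e in cluster.chain.junctions:
        bounds.extend((s, e))
    bounds.append(right)
    exons = []
    for i in range(0, len(bounds), 2):
        exons.append(GenomicInterval(cluster.chrom, bounds[i], bounds[i + 1], cluster.strand))
    return tuple(exons)
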