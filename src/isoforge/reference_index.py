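"""Lookup structures over the reference annotation.

The index exposes exactly what downstream stages consult: per-strand
donor/acceptor splice-site sets (for junction correction), annotated
TSS/TES positions (for the start-site filter and evaluation), and an
intron-chain dictionary (for novelty calls and full-splice matching).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from .model import IntronChain, SpliceJunction, TranscriptModel

Key = tuple[str, str]  # (chrom, strand)


@dataclass
class _SiteSet:
    """Sorted positions plus a set for O(1) membership."""

    sorted_positions: list[int] = field(default_factory=list)
    members: set[int] = field(default_factory=set)

    def add(self, pos: int) -> None:
        if pos not in self.members:
            self.members.add(pos)
            bisect.insort(self.sorted_positions, pos)


@dataclass
class ReferenceIndex:
    donor_sites: dict[Key, _SiteSet] = field(default_factory=dict)
    acceptor_sites: dict[Key, _SiteSet] = field(default_factory=dict)
    annotated_tss: dict[Key, _SiteSet] = field(default_factory=dict)
    annotated_tes: dict[Key, _SiteSet] = field(default_factory=dict)
    chain_lookup: dict[IntronChain, list[str]] = field(default_factory=dict)
    junction_set: set[SpliceJunction] = field(default_factory=set)
    chains_by_key: dict[Key, list[tuple[tuple[tuple[int, int], ...], str]]] = field(
        default_factory=dict
    )
    single_exon_refs: dict[Key, list[tuple[int, int, str]]] = field(default_factory=dict)
    transcripts: list[TranscriptModel] = field(default_factory=list)
    gene_of_transcript: dict[str, str] = field(default_factory=dict)

    def _sites(self, table: dict[Key, _SiteSet], key: Key) -> _SiteSet:
        ss = table.get(key)
        if ss is None:
            ss = table[key] = _SiteSet()
        return ss

    def is_annotated_site(self, chrom: str, strand: str, position: int, site_kind: str) -> bool:
        table = self.donor_sites if site_kind == "donor" else self.acceptor_sites
        ss = table.get((chrom, strand))
        return ss is not None and position in ss.members

    def is_annotated_junction(self, junction: SpliceJunction) -> bool:
        return junction in self.junction_set

    def has_chain(self, chain: IntronChain) -> bool:
        return chain in self.chain_lookup

    def nearest_tss_distance(self, chrom: str, strand: str, position: int) -> int | None:
        hit = nearest_position(self.annotated_tss.get((chrom, strand)), position)
        return None if hit is None else hit[1]


def nearest_position(site_set: _SiteSet | None, position: int) -> tuple[int, int] | None:
    """Nearest position in a sorted set; ties break toward the smaller
    coordinate. None for an empty/missing set."""
    if site_set is None or not site_set.sorted_positions:
        return None
    positions = site_set.sorted_positions
    i = bisect.bisect_left(positions, position)
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(positions):
            cand = positions[j]
            dist = abs(cand - position)
            if best is None or dist < best[1] or (dist == best[1] and cand < best[0]):
                best = (cand, dist)
    return best


def build_reference_index(transcripts: list[TranscriptModel]) -> ReferenceIndex:
    """Enumerate splice sites, termini and intron chains from an annotation.

    Single-exon transcripts contribute TSS/TES (and the single-exon match
    table) but no junctions.
    """
    index = ReferenceIndex(transcripts=list(transcripts))
    for tx in transcripts:
        key = (tx.chrom, tx.strand)
        index.gene_of_transcript[tx.transcript_id] = tx.gene_id
        index._sites(index.annotated_tss, key).add(tx.tss)
        index._sites(index.annotated_tes, key).add(tx.tes)
        chain = tx.intron_chain()
        if chain.is_single_exon():
            index.single_exon_refs.setdefault(key, []).append(
                (tx.exons[0].start, tx.exons[0].end, tx.transcript_id)
            )
            continue
        for sj in chain.splice_junctions():
            index.junction_set.add(sj)
            index._sites(index.donor_sites, key).add(sj.donor)
            index._sites(index.acceptor_sites, key).add(sj.acceptor)
        index.chain_lookup.setdefault(chain, []).append(tx.transcript_id)
        index.chains_by_key.setdefault(key, []).append((chain.junctions, tx.transcript_id))
    return index


def nearest_site(
    index: ReferenceIndex, chrom: str, strand: str, position: int, site_kind: str
) -> tuple[int, int] | None:
    """Nearest annotated donor or acceptor on (chrom, strand), with its
    absolute distance. Lookups are same-strand only."""
    if site_kind not in ("donor", "acceptor"):
        raise ValueError(f"site_kind must be donor or acceptor, got {site_kind!r}")
    table = index.donor_sites if site_kind == "donor" else index.acceptor_sites
    return nearest_position(table.get((chrom, strand)), position)
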