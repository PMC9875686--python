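"""Benchmarking metrics: matching, precision/recall, classification,
relative positions, read-count CDF and the coverage probability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoforge.evaluation_metrics import (
    ExpressionRecord,
    boundary_support_rate,
    classify_structure,
    ism_truncation,
    low_coverage_probability,
    match_isoform,
    precision_recall,
    read_count_cdf,
    recall_under_cutoff,
    relative_intron_position,
    relative_start_exon,
)
from isoforge.formats_io import PeakSet
from isoforge.model import GenomicInterval, IntronChain, IsoformCall
from isoforge.reference_index import build_reference_index

from conftest import make_transcript


def _iso(tid, chrom, strand, exons, n_reads=1):
    blocks = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    chain = IntronChain(
        chrom, strand, tuple((exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1))
    )
    return IsoformCall(
        transcript_id=tid, gene_id="g", chrom=chrom, strand=strand, exons=blocks,
        chain=chain, n_reads=n_reads, n_polya=0, is_novel_chain=False,
        tss_evidence="annotated", single_exon=not chain.junctions,
    )


@pytest.fixture
def ref_index():
    return build_reference_index(
        [
            make_transcript("R1", "c", "+", [(100, 200), (300, 400), (500, 600), (700, 800)]),
            make_transcript("R2", "c", "+", [(100, 200), (500, 600), (700, 800)]),
            make_transcript("MONO", "c", "+", [(5000, 6000)]),
        ]
    )


def test_match_ignores_terminal_ends(ref_index):
    iso = _iso("a", "c", "+", [(120, 200), (300, 400), (500, 600), (700, 880)])
    assert match_isoform(iso, ref_index) == "R1"


def test_match_requires_full_chain(ref_index):
    iso = _iso("a", "c", "+", [(300, 400), (500, 600), (700, 800)])  # missing first junction
    assert match_isoform(iso, ref_index) is None


def test_match_single_exon_by_reciprocal_overlap(ref_index):
    assert match_isoform(_iso("a", "c", "+", [(5100, 5900)]), ref_index) == "MONO"
    assert match_isoform(_iso("b", "c", "+", [(5900, 9000)]), ref_index) is None


def test_match_empty_reference():
    iso = _iso("a", "c", "+", [(0, 10), (20, 30)])
    assert match_isoform(iso, build_reference_index([])) is None


def test_precision_recall_worked_example():
    # 10 distinct reference chains; assemble 8 of them plus 2 misses -> TP=8 FP=2 FN=2
    refs = [
        make_transcript(f"R{i}", "c", "+", [(i * 1000, i * 1000 + 100), (i * 1000 + 200, i * 1000 + 300)])
        for i in range(10)
    ]
    index = build_reference_index(refs)
    assembly = [
        _iso(f"a{i}", "c", "+", [(i * 1000, i * 1000 + 100), (i * 1000 + 200, i * 1000 + 300)])
        for i in range(8)
    ] + [
        _iso("x1", "c", "+", [(50_000, 50_100), (50_200, 50_300)]),
        _iso("x2", "c", "+", [(60_000, 60_100), (60_200, 60_300)]),
    ]
    result = precision_recall(assembly, index)
    assert (result.tp, result.fp, result.fn) == (8, 2, 2)
    assert result.precision == pytest.approx(0.8)
    assert result.recall == pytest.approx(0.8)


def test_precision_recall_identity_and_empty(ref_index):
    assembly = [
        _iso("a", "c", "+", [(100, 200), (300, 400), (500, 600), (700, 800)]),
        _iso("b", "c", "+", [(100, 200), (500, 600), (700, 800)]),
        _iso("m", "c", "+", [(5000, 6000)]),
    ]
    result = precision_recall(assembly, ref_index)
    assert (result.precision, result.recall) == (1.0, 1.0)
    empty = precision_recall([], ref_index)
    assert math.isnan(empty.precision) and empty.recall == 0.0


def brute_force_precision_recall(assembly_chains, reference_chains):
    """All-pairs greedy matching oracle over plain chain tuples."""
    available = dict(enumerate(reference_chains))
    tp = 0
    for chain in assembly_chains:
        hit = next((i for i, rc in sorted(available.items()) if rc == chain), None)
        if hit is not None:
            del available[hit]
            tp += 1
    fp = len(assembly_chains) - tp
    fn = len(reference_chains) - tp
    return tp, fp, fn


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_precision_recall_matches_brute_force(data):
    universe = [((100 * i + 10, 100 * i + 20),) for i in range(8)]
    ref_pick = data.draw(st.lists(st.integers(0, 7), min_size=1, max_size=6))
    asm_pick = data.draw(st.lists(st.integers(0, 7), min_size=0, max_size=6))
    refs = [
        make_transcript(
            f"R{n}", "c", "+",
            [(universe[i][0][0] - 10, universe[i][0][0]), (universe[i][0][1], universe[i][0][1] + 10)],
        )
        for n, i in enumerate(ref_pick)
    ]
    index = build_reference_index(refs)
    assembly = [
        _iso(
            f"a{n}", "c", "+",
            [(universe[i][0][0] - 10, universe[i][0][0]), (universe[i][0][1], universe[i][0][1] + 10)],
        )
        for n, i in enumerate(asm_pick)
    ]
    got = precision_recall(assembly, index)
    exp = brute_force_precision_recall(
        [universe[i] for i in sorted(asm_pick)], [universe[i] for i in ref_pick]
    )
    assert (got.tp, got.fp, got.fn) == exp
    assert got.tp + got.fp == len(assembly)


def test_boundary_support_rate_window_rule():
    peaks = PeakSet("cage")
    peaks.add(GenomicInterval("c", 990, 1010, "+"))
    inside = _iso("a", "c", "+", [(1000, 2000), (2500, 3000)])
    outside = _iso("b", "c", "+", [(1100, 2000), (2500, 3000)])
    assert boundary_support_rate([inside], peaks, "tss", 25) == 1.0
    assert boundary_support_rate([inside, outside], peaks, "tss", 25) == 0.5
    assert math.isnan(boundary_support_rate([], peaks, "tss", 25))
    # monotone in window size
    r10 = boundary_support_rate([inside, outside], peaks, "tss", 10)
    r100 = boundary_support_rate([inside, outside], peaks, "tss", 100)
    assert r100 >= r10


def test_recall_under_cutoff(ref_index):
    expr = [
        ExpressionRecord("R1", 0.5),
        ExpressionRecord("R2", 0.8),
        ExpressionRecord("MONO", 50.0),
    ]
    assembly = [_iso("a", "c", "+", [(100, 200), (300, 400), (500, 600), (700, 800)])]
    assert recall_under_cutoff(assembly, ref_index, expr, 1.0) == pytest.approx(0.5)
    assert math.isnan(recall_under_cutoff(assembly, ref_index, expr, 0.1))


def test_structural_categories(ref_index):
    fsm = _iso("f", "c", "+", [(110, 200), (300, 400), (500, 600), (700, 790)])
    assert classify_structure(fsm, ref_index).category == "FSM"
    # junctions 2..3 of R1 (contiguous, proper)
    ism = _iso("i", "c", "+", [(300, 400), (500, 600), (700, 800)])
    cat = classify_structure(ism, ref_index)
    assert cat.category == "ISM" and cat.parent_transcript_id == "R1"
    # known sites, unseen combination: R1 donor 200 with acceptor 700
    nic = _iso("n", "c", "+", [(100, 200), (700, 800)])
    assert classify_structure(nic, ref_index).category == "NIC"
    nnc = _iso("x", "c", "+", [(100, 200), (333, 400), (500, 600), (700, 800)])
    assert classify_structure(nnc, ref_index).category == "NNC"
    mono = _iso("m", "c", "+", [(5000, 6000)])
    assert classify_structure(mono, ref_index).category == "single_exon"


def test_fsm_iff_match(ref_index):
    candidates = [
        _iso("a", "c", "+", [(100, 200), (300, 400), (500, 600), (700, 800)]),
        _iso("b", "c", "+", [(300, 400), (500, 600), (700, 800)]),
        _iso("n", "c", "+", [(100, 200), (700, 800)]),
    ]
    for iso in candidates:
        is_fsm = classify_structure(iso, ref_index).category == "FSM"
        assert is_fsm == (match_isoform(iso, ref_index) is not None)


@pytest.mark.parametrize(
    "strand,sub,expected",
    [
        ("+", (0, 3), "3prime"),  # junctions 1..3 of 5
        ("+", (2, 5), "5prime"),  # junctions 3..5 of 5
        ("+", (1, 4), "both"),
        ("-", (0, 3), "5prime"),  # genomic-first junctions are transcript-last on -
        ("-", (2, 5), "3prime"),
        ("-", (1, 4), "both"),
    ],
)
def test_ism_truncation_sides(strand, sub, expected):
    junctions = tuple((1000 * i + 100, 1000 * i + 500) for i in range(5))
    parent = IntronChain("c", strand, junctions)
    ism = IntronChain("c", strand, junctions[sub[0] : sub[1]])
    assert ism_truncation(ism, parent) == expected


def test_ism_truncation_rejects_non_subchain():
    parent = IntronChain("c", "+", ((100, 200), (300, 400)))
    stranger = IntronChain("c", "+", ((150, 250),))
    with pytest.raises(ValueError):
        ism_truncation(stranger, parent)


def test_relative_start_exon_plus_and_minus():
    exons = [(1000 * i, 1000 * i + 100) for i in range(10)]
    parent_plus = make_transcript("P", "c", "+", exons)
    # ISM starting at exon 3 (transcript orientation): parent junctions 3..9
    ism_exons = exons[2:]
    ism = _iso("i", "c", "+", ism_exons)
    assert relative_start_exon(ism, parent_plus) == pytest.approx(0.3)
    ism_full = _iso("j", "c", "+", exons[0:4])
    assert relative_start_exon(ism_full, parent_plus) == pytest.approx(0.1)

    # strand-mirrored: on -, transcript exon 1 is the genomic last
    parent_minus = make_transcript("M", "c", "-", exons)
    # ISM covering genomic exons 0..7 starts (5'->3') at genomic exon 7 = ordinal 3
    ism_minus = _iso("k", "c", "-", exons[0:8])
    assert relative_start_exon(ism_minus, parent_minus) == pytest.approx(0.3)


def test_relative_intron_position():
    assert relative_intron_position(7, 14) == pytest.approx(0.5)
    assert relative_intron_position(1, 1) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        relative_intron_position(1, 0)
    with pytest.raises(ValueError):
        relative_intron_position(5, 4)


def test_read_count_cdf():
    isoforms = [_iso(f"i{n}", "c", "+", [(0, 10), (20, 30)], n_reads=k) for n, k in enumerate([1, 1, 2, 5])]
    cdf = dict(read_count_cdf(isoforms))
    assert cdf[2] == pytest.approx(0.75)
    assert cdf[5] == pytest.approx(1.0)
    values = [frac for _, frac in read_count_cdf(isoforms)]
    assert values == sorted(values)
    assert read_count_cdf([]) == []


def test_low_coverage_probability_exact_matches_poisson_limit():
    exact = low_coverage_probability(1.0, 1_000_000, 2, mode="exact")
    poisson_limit = 2.5 * math.exp(-1)
    assert exact > 0.90
    assert abs(exact - poisson_limit) < 0.002


def test_low_coverage_probability_edge_cases():
    assert low_coverage_probability(0.0, 100) == 1.0
    with pytest.raises(ValueError):
        low_coverage_probability(2e6, 100)


def test_low_coverage_simulation_converges_to_exact():
    exact = low_coverage_probability(1.0, 1_000_000, 2, mode="exact")
    n_sims = 100_000
    sim = low_coverage_probability(1.0, 1_000_000, 2, mode="simulate", n_sims=n_sims, seed=0)
    se = math.sqrt(exact * (1 - exact) / n_sims)
    assert abs(sim - exact) <= 3 * se
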