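# Methods

## Coordinate conventions and read model

All in-memory coordinates are 0-based half-open on the forward genomic
axis; GTF (1-based closed) and BED (0-based half-open) dialects are
converted only at file boundaries. A read is a tuple of exon blocks
derived by walking its CIGAR: M/=/X/D extend the current block, N closes
it, I/S/H/P consume no reference. Deletions extending a block (rather
than splitting it) means small indels never masquerade as introns; only
N operations do. The transcript strand is taken from the aligner's
spliced-strand tag when present (minimap2 `ts`), else from the alignment
strand; DRS reads are inherently stranded so the tag is normally present
and consistent. Secondary and supplementary alignments are skipped, and
records below `min_mapq` (default 1) are dropped — published descriptions
of this pipeline family do not state a mapping-quality rule, so the
default is the weakest filter that removes unmapped/ambiguous records,
and it is configurable.

Per-read polyadenylation is a tri-state: reads listed in the caller's
table with the pass tag (default `PASS`, nanopolish-polya dialect) are
*polyadenylated*, other listed reads *not_polyadenylated*, unlisted reads
*unknown*. Unknown counts as not-polyadenylated wherever poly(A) evidence
is tallied — the conservative reading, since an uncalled read cannot
confirm a complete 3′ end.

## Junction correction

Splice sites are indexed per (chromosome, strand) as donor and acceptor
position sets (an intron's start boundary is the donor on +, the acceptor
on −). Each junction boundary not already on an annotated site of its
kind is moved to the nearest same-kind, same-strand annotated site if the
genomic offset is at most `max_shift` = 40 bp; larger offsets leave the
boundary untouched. The bound is interpreted as a positional shift, not a
sequence edit distance — the per-site phrasing and the 40 bp scale only
make sense on the genomic axis. Ties between equidistant sites break to
the smaller coordinate (determinism). A correction that would shrink an
exon below 1 bp or invert an intron is cancelled rather than merging
blocks, since merging would silently change the intron chain. Correction
is idempotent: a corrected boundary sits on an annotated site and is
never revisited.

## Collapsing and boundary estimation

Corrected spliced reads are partitioned by exact (chromosome, strand,
intron chain) equality; correction is responsible for absorbing jitter,
so no tolerance is applied at this stage. Single-exon reads — the class
with the highest artifact risk — are clustered separately by
single-linkage reciprocal overlap ≥ 0.5 on the same strand.

Within a cluster the 5′ start positions and 3′ end positions are modelled
independently with one-dimensional Gaussian mixtures, k = 1..3 selected
by BIC, EM seeded from a fixed `seed` (default 42) so runs are
bit-reproducible. A variance floor of 1 bp² enters EM as the covariance
regularizer, keeping components non-singular when many reads share one
terminus. The primary boundary is the rounded mean of the highest-weight
component, clamped into the observed position range; components with
weight ≥ 0.2 are retained as candidate metadata. Two deliberate
refinements handle the truncation-dominated small-cluster regime:

- **Weight ties** (within 1e-9) break toward the 5′-most component mean
  for the TSS and the 3′-most for the TES. Truncation can only move a
  read's terminus *away* from the true one, so among equally supported
  modes the outermost is the better terminus estimate. Without this rule
  a three-read cluster with uniform 1/3 weights picks an arbitrary
  component.
- Clusters below `min_gmm_reads` = 3 (EM on fewer points is ill-posed)
  use an **order-statistic median** that favours the same outermost side
  on even counts, instead of interpolating: the midpoint of a true start
  and a truncation start is a position no read supports.

One isoform is emitted per cluster — the primary TSS/TES spanning the
chain — with minor components kept as metadata only; emitting
per-component isoforms would inflate false positives. The TES is clamped
at least 1 bp beyond the outermost junction (symmetrically for the TSS)
so terminal exons never collapse to zero length.

## Three-step filtering

Filters run junction → poly(A) → TSS; each predicate is per-cluster and
independent, so the order affects only the attribution recorded in
`filter_trace`, not the surviving set.

1. **Novel-junction support.** A cluster is discarded iff any of its
   junctions is absent from the annotated junction set *and* is seen in
   fewer than `min_sj_reads` = 2 reads, counted over the full corrected
   read set before collapsing. Annotated junctions are exempt regardless
   of support.
2. **Polyadenylation.** Clusters whose chain is absent from the reference
   chain dictionary need at least `min_polya_reads` = 1 member read with
   a confirmed poly(A) event; one confirmed read is the weakest evidence
   consistent with requiring "sufficient" polyadenylation, and the
   threshold is configurable. Reference-chain clusters are exempt;
   single-exon clusters are always subject.
3. **TSS support.** The primary TSS must lie within `tss_window` = 50 bp
   of an annotated same-strand TSS or inside a CAGE peak extended by the
   same window. This applies to reference and novel chains alike — a
   truncated copy of an annotated chain is still truncated. The filter
   window is deliberately separate from the ±25 bp `eval_window` used for
   orthogonal-evidence *reporting*: filtering tolerates boundary
   estimation noise, evaluation follows the stricter community
   convention.

Gene ids are inherited from the reference gene with maximal exonic
overlap; non-overlapping isoforms get per-locus `NOVELG_` counters.
Assemblies from multiple runs/fractions merge on identical chains
(boundaries from the best-supported member, read counts summed), with
single-exon isoforms merged by reciprocal overlap ≥ 0.5.

## Evaluation metrics

Matching uses intron-chain equality, ignoring terminal positions (the
"=" class-code convention); each reference transcript counts at most once
toward TP, consumed greedily in sorted-id order. Precision = TP/(TP+FP),
recall = TP/(TP+FN); undefined ratios are reported as NaN, never 0.
Structural classes: FSM (chain equals a reference chain), ISM (proper
*contiguous* sub-chain — skipping internal junctions is NIC/NNC), NIC
(every donor and acceptor annotated, chain new), NNC (≥ 1 unannotated
site). ISM truncation sides and the relative start-exon and intron
positions are computed in transcript orientation (on − the genomic-first
junction is the transcript-last one). The coverage probability
`P(X ≤ max_reads)` is the exact binomial CDF, with a seeded simulation
mode for cross-checking.

## Simulator

The generator builds each gene as an exon backbone (4–8 exons of
100–300 bp, introns 200–2000 bp); the first isoform is the full backbone
and each further isoform skips one distinct internal exon, so isoforms of
a gene share junctions while chains stay pairwise distinct. Genes
alternate strands across two contigs with 10 kb gaps. Expression is
log-normal (μ = 3, σ = 1 on the log scale) renormalized to 10⁶ TPM; reads
are drawn multinomially.

Per read: with probability 0.2 an exponential (mean 300 bp) prefix is
removed from the 5′ end respecting exon structure (a switch emulates
3′-degraded samples instead); each junction side is displaced with
probability 0.3 by a nonzero uniform offset up to 20 bp, clamped so every
exon and intron keeps ≥ 1 bp; termini wobble by N(0, 3 bp); poly(A) is
confirmed with probability 0.95 for full-length and 0.3 for truncated
reads, with an optional dropout leaving reads uncalled. SAM output
reconstructs the exact exon blocks via CIGAR, with placeholder base
content — no base-level error simulation, since no implemented operation
reads sequence. Truth GTF, per-read source/truncation labels, and ±10 bp
CAGE/poly(A)-cluster BEDs around the true termini accompany every run.

What the simulator does *not* emulate: base-level sequencing error and
its interaction with alignment (jitter is injected directly), expression-
dependent truncation, internal priming, multi-mapping ambiguity, or
incomplete reference annotation. Passing tests therefore demonstrate the
pipeline's logic — correction, collapsing, mixture-based boundary calls,
evidence filtering — under controlled noise, not end-to-end accuracy on
real flowcell data.

## Problem sizes and determinism

The test suite and the acceptance script run simulations of 10–25 genes
and 2–10 thousand reads — large enough that every noise mode is exercised
and per-gene read depth spans single-read to hundreds — and complete in
well under a minute. All randomness flows from explicit seeds
(numpy `default_rng`; scikit-learn EM `random_state`), making every
reported number bit-reproducible.

## Known limitations

- One isoform per intron chain: genuinely distinct TSS/TES variants
  sharing a chain are reported as mixture candidates, not separate models.
- Correction trusts the annotation; a truly novel splice site within
  40 bp of an annotated one is snapped away unless its exact position
  recurs as annotated.
- Single-exon transcript handling (overlap clustering, mandatory poly(A)
  + TSS evidence) is a documented package choice; upstream descriptions
  of this pipeline family leave the single-exon pathway unspecified.
- The TSS filter keys on the primary component only; a minority true-TSS
  mode outweighed by truncation in a small cluster can be lost.
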