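# Methods

This note records the models, conventions and deliberate design choices
behind `targetec`, in the order the pipeline uses them.

## Interval algebra

All genomic sets are kept in a single canonical form: per contig, sorted by
start, pairwise disjoint, with abutting intervals joined. Construction *is*
merging, so every operation (union, subtraction, intersection, expansion)
returns canonical sets and equality is base-set equality. Abutting
intervals (gap 0) are joined, matching the default of the standard
BED-merge tooling. Strand is ignored throughout: capture targets are
strand-free.

The minimum-length expansion grows a region of length `l < m` by
`⌊(m−l)/2⌋` bp on the left and `⌈(m−l)/2⌉` on the right. When the growth
would cross a contig boundary it is clipped and the clipped deficit is
pushed to the opposite side, so the target length `min(m, contig length)`
is always reached. Expansion can make neighbours overlap; the result is
re-merged, which is why the final region count can be smaller than the
input count.

## Target design and region classes

The panel is `merge(expand_m(merge(exons ∪ conserved)))` with `m = 100` bp
by default — short conserved elements (median ~5 bp) are unusable as
hybridization targets without this expansion, and the expansion is the sole
source of the OTHER class below. The conserved seed is every position at
the top of the conservation scale (score ≥ 1.0 by default); lowering the
threshold grows the panel rapidly because moderately conserved sequence is
far more abundant.

Reporting partitions target bases by priority: CDS ≻ UTR ≻ CNS ≻ OTHER.

* CDS is the union over transcripts of `exons ∩ cdsSpan`; a base coding in
  *any* isoform is CDS.
* UTR is exonic sequence of coding transcripts outside their CDS span,
  minus CDS. Exons of transcripts without a CDS span (non-coding RNAs)
  deliberately contribute to neither CDS nor UTR — they enter the panel via
  the exon union and classify as CNS or OTHER. This is one consistent
  reading of genePred semantics; the alternative (counting them as UTR)
  would inflate UTR with biotypes that have no translated frame.
* CNS is conserved sequence not already claimed by an exonic class, so the
  reported CNS matches the non-coding usage of the term even though the
  design seed uses all conserved bases.
* OTHER is everything else: expansion flanks.

The partition is validated structurally (`RegionClassMap` refuses class
sets that overlap or fail to cover the panel).

## Deletion detectability

"What fraction of the genome would reveal a deletion of length L?" is
formalized as a fraction of *placements*: start positions `p` with
`[p, p+L)` fully inside a contig, counted as detecting when the window
overlaps ≥ 1 target base. Placements are not allowed to run off contig
ends (a deletion is an interval of the genome), and contigs shorter than
`L` drop out of the denominator. The numerator is computed in closed form:
for a target `[s, e)` the detecting starts are `[s−L+1, e)` clipped to the
valid range, and the union of these windows is measured as an interval set.
This definition is parameter-free, exactly reproduces superset dominance
(a panel always detects at least as well as any subset, e.g. its exon-only
part), and is non-decreasing in `L`.

CNS-to-exon proximity is counted **per CNS region**, not per base, using
gap distance (0 when overlapping or abutting). A CNS within 250 bp of an
exon may be captured incidentally by a conventional exome library because
typical insert sizes reach that far; the reported fraction quantifies how
much of the conserved space an exome design would still miss.

## Capture QC

Read trimming removes 3' bases until the terminal base has quality ≥ 30,
then drops reads shorter than 30 — a simple end-trim, no sliding window,
idempotent by construction. A read is on-target if it is aligned,
not flagged duplicate, and overlaps the panel by ≥ 1 bp. Depth statistics
(mean target depth, fraction of target bases at ≥ d, uncovered fraction)
are per-base over target bases only, computed from a run-length coverage
track; duplicate marking itself is upstream of this package — flags are
consumed, never computed.

## Variant analysis

VCF ingestion (via pysam) splits multi-allelic records one variant per alt
allele, converts positions to 0-based, takes depth from the first sample's
DP (else INFO/DP), and classes the genotype per split allele. Variants with
ref and alt of equal length > 1 (MNVs) are counted as neither SNV nor
INDEL in tables.

Known-variant subtraction is **position-based by default**: any variant
co-located with a known site is dropped, regardless of allele. This mirrors
coordinate-level subtraction against a known-sites BED, which is how such
filtering is usually done in practice; an allele-aware mode (exact
(pos, ref, alt) match) is available for correctness-minded users.

Per-class tables assign INDELs by their anchor-base position. The TOTAL row
counts every depth-passing variant whether or not it lies in the panel;
class rows count only in-class variants, so class counts do not sum to
TOTAL. Ti/Tv is transitions (A↔G, C↔T) over transversions, reported as
undefined (None) when no transversion exists; a substitution process
uniform over the 12 ordered changes gives 4/8 = 0.5.

SNV density per conservation bin uses bins `[i·w, (i+1)·w)` with `w = 0.05`
and the last bin closed at 1.0. Denominators count scored **target** bases
only; unscored bases, and SNVs at them, are excluded rather than binned at
zero, and an empty bin reports density `None`, not 0.

## Deletion screen

The screen replaces peak-calling-plus-subtraction with an explicit
contract: covered segments are maximal runs of depth ≥ `min_depth` (5),
with runs separated by ≤ `max_gap` (200 bp) joined and segments shorter
than `min_len` (500 bp) discarded. Candidate deletions are the base-level
subtraction of mutant segments from control segments, kept at ≥ `min_len`,
scored with read-equivalent counts (depth integral / nominal read length
100) and ranked by `(control + 1)/(mutant + 1)` with ties broken by control
count, then coordinate — a total, permutation-stable order. Identical
tracks yield zero calls by construction. Mutant-only segments (gains) are
reported separately and unranked. The screen sees only what is covered: a
deletion is recoverable exactly to the extent that the control track covers
it contiguously, so sparse panels fragment long deletions into their
covered pieces.

## Synthetic fixtures

The generators emulate the study conditions the package is built for:

* Exon lengths are lognormal with median 132 bp (σ = 0.6) — the typical
  RefSeq exon-length scale; intron lengths are 60 bp + exponential
  (mean 300); genes are laid non-overlapping with exponential intergenic
  gaps; ~90% of transcripts get a CDS span with UTR stubs.
* Fully conserved (score 1.0) runs are geometric with median ~5 bp,
  planted both inside exons and intergenically — conserved elements are an
  order of magnitude shorter than exons, which is what makes the 100-bp
  expansion consequential.
* All other positions receive background scores uniform in [0, 1) in
  variable-length runs, with ~5% of runs left unscored to exercise the
  score-absent code paths.
* SNVs are homozygous with per-base probability `0.02·(1 − score)`, so
  density falls linearly with conservation; INDELs are uniform and rare;
  ~60% of variants are labelled "known" to exercise subtraction.
* Coverage is Poisson around a nominal depth (default 50×) over targets
  with exponentially decaying 150-bp flanks. The mutant track shares the
  control's base array with engineered deletions zeroed, so with no
  deletions the two tracks are identical — deliberate, to make
  "identical input ⇒ zero calls" an exact property.

Each generator draws from its own `numpy` Generator seeded from
`(seed, stream-id)`; identical specs produce byte-identical files.

What the fixtures do **not** model: assembly gaps, mappability and GC
capture bias, duplicate reads, sequencing error in base calls, het
variants, linked variants, or partial/mosaic deletions. Tests passing on
these fixtures therefore demonstrate algorithmic correctness of the
interval algebra, the detectability formula, the triage funnel and the
screen — not robustness to real-data artifacts.

## Problem sizes and numerical choices

The default fixture is 3 × 100 kb contigs with 60 genes; the density
analysis uses a 10-kb single-contig fixture; the deletion screen is
validated on twenty 10-kb simulations with one engineered 1–5-kb deletion
each at 30–100× depth, placed with ≥ 600-bp margins so that both flanking
covered segments survive the length filter. These sizes keep the full
suite and the acceptance script in seconds while leaving every statistic
well away from small-sample degeneracy. Scores are validated to [0, 1] on
ingest; fractions are exact rational arithmetic over integer base counts
until the final division.
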