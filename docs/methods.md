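# Methods

This note documents the models and procedures `rasikit` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Read model and the filter cascade

Reads are modeled as `insert + 3′ adapter`, truncated to the sequencer's
44-nt read length; the 5′ adapter is normally consumed by the sequencing
primer but a remnant may survive at the read start.  The cascade runs in
the order of library construction: quality filter → 3′ clip → 5′ clip →
homopolymer trim → length filter.  Reads are canonicalized to the DNA
alphabet (U→T) before matching; `N` never matches anything.

**Quality.**  Sequencing providers rarely publish their low-quality
definition, so the filter is explicit and configurable: mean Phred ≥ 20
and N-fraction ≤ 0.1 by default.  Reads without qualities pass.

**Adapter clipping.**  The 3′ adapter is located by a semi-global
alignment of the adapter against every read suffix (match +1, mismatch
−1, gap −2).  Because everything downstream of the insert is adapter
material, an occurrence starting at offset *t* must explain the entire
suffix `read[t:]`, with the adapter free to run off the read end.  For
each offset the best-scoring alignment defines a score, an edit count
(substitutions + indels, minimized among maximal-score alignments) and an
overlap (adapter bases consumed, maximized among those).  An offset is
feasible when `overlap ≥ min_overlap` (default 6) and
`edits ≤ ⌊error_rate × overlap⌋` (default rate 0.2); the feasible offset
with the maximal score wins and ties break toward the longest insert.
These tolerances are conventional clipper defaults — the source protocol
allowed "exact or degenerated" adapters without quantifying the
degeneracy — and both are configurable.  The implementation computes all
per-offset scores in a single reversed free-start dynamic program (an
exact full-adapter occurrence short-circuits it); the test suite checks
its decisions against an exhaustive per-offset enumeration oracle.
After 3′ clipping, a 5′-adapter *suffix* occupying the insert prefix is
removed under the same criteria on the reversed sequences.

**Homopolymers.**  Terminal single-base runs longer than 12 nt are
removed, iteratively, until no terminal run exceeds the limit; a read
reduced to nothing is discarded.  Internal over-long runs are flagged but
the read is not split — the rule as stated trims, it does not cut.
Trimmed reads are re-checked against the length filter.

**Length.**  "Longer than 10 nt" is read strictly: the minimum kept
length is 11.  The same strict convention applies to the rasiRNA
annotation threshold ("longer than 15 nt" → ≥ 16).

**Collapse.**  Kept inserts collapse into unique tags; per-library count
maps merge by sequence across libraries.  Tag identifiers are assigned by
descending total count then sequence, so results are independent of read
order.  The accounting identity `raw = low_quality + no_adapter +
too_short + high_quality` is enforced structurally (reads emptied by
homopolymer trimming count as `too_short`).

## Annotation

The annotation criterion is 100% identity over the full tag length, so
the mapper is an exact substring search on both strands rather than a
seeded aligner — deterministic and criterion-faithful by construction.
Contamination precedence is rDNA (exact match) over tRNA (similarity):
the tRNA screen accepts a tag whose best infix alignment against any
tRNA reaches ≥ 95% full-length identity, computed as `1 − edits/length`
and rounded to 4 decimals before comparison, so a single mismatch in a
20-mer (19/20 = 0.95) passes.  The infix alignment uses the edlib
library; tests verify it against a full dynamic-programming oracle.
A tag is a rasiRNA iff it is non-contaminant, ≥ 16 nt and has at least
one perfect hit; its category set is the union over hit consensi, so
category percentages may intentionally sum above 100%.

The short-tandem-repeat finder reports maximal perfect arrays of
primitive units (unit length and minimum copy number configurable),
identified by their lexicographically smallest rotation.  Mismatch-
tolerant arrays are out of scope — the motif of interest is perfect.

## Clusters and expression

Hits on the same strand of the same consensus merge by single linkage
with a 1-nt overlap threshold (the clusters of interest are highly
overlapping, so the default is permissive; abutting intervals never
merge).  Components with ≥ 2 distinct tags are clusters; smaller ones are
reported separately as singletons, never dropped.  Strands never merge,
so every cluster is uni-strand by construction.

Counts normalize per library as `100 · c / N` with `N` the library's
high-quality reads — with no endogenous control known for small RNAs,
depth normalization is the only cross-library comparison available.
Computation is full precision; display rounding is separate and
reproduces the conventional printed forms: per-tag values print as a
×10⁻³ % mantissa truncated (not rounded) to 3 decimals, aggregates round
to 2 significant figures capped at 3 decimal places.

Differential abundance between two libraries is a two-sided Fisher's
exact test on `[[c₁, N₁−c₁], [c₂, N₂−c₂]]` — exact at the extreme
imbalances typical of these counts (a tag seen once in one library and
never elsewhere gives p ≈ 1).  Raw p-values are reported, with an
optional Benjamini–Hochberg column off by default.  The test equals
exhaustive hypergeometric enumeration; the suite verifies this on every
2×2 table with grand total ≤ 24 plus seeded larger tables.

Positional composition matrices are left-aligned over ragged sequences
with per-position depth tracked; each contributing column sums to 1
within 1e-9.

## qPCR, ChIP and densitometry

A standard curve is the least-squares line `Ct = slope·log₁₀ q + b` over
≥ 3 dilution points; efficiency is `E = 10^(−1/slope) − 1` and values
outside (0, 1.1] are flagged.  Quantities invert the line;
percent input is `100 · ip / (input / f)` with `f` the input fraction
assayed; enrichment divides a locus's percent input by the control
locus's, so the control is 1 identically.  Replicate Cts are averaged
before interpolation for the point estimate, while significance uses the
per-replicate percent-input values in a two-sided pooled-variance
Student's t-test (Welch available by flag; zero-variance cases use the
conventions p = 1 for equal means, p = 0 flagged degenerate, since the
statistic is undefined).  Mock (no-antibody) values are reported
alongside, not subtracted.

ΔCt quantification uses `2^(Ct_ref − Ct_target)`, i.e. perfect doubling;
an efficiency-corrected base `(1+E)` is available but off by default so
the standard formula is reproduced first.  Genomic copy number of a
repeat is the per-replicate `2^(Ct_single-copy − Ct_repeat)` summarized
as mean and min–max interval across replicates — the interval phrasing
("between X and Y copies") reflects replicate spread, not a parametric
confidence interval.

Densitometry follows the two-step convention: the reference protein (H3)
at the reference stage (E1) is set to 1 and other H3 volumes expressed
relative to it; each modification is divided by H3 at its own stage and
then by the same ratio at the reference stage.  All reference-stage
cells equal 1.  Note this procedure is not a projection: re-applying it
to an already-normalized table divides by the relative H3 column again,
so it is defined on raw band volumes only.

## The synthetic generator

The generator defines the conditions under which the pipeline is tested.
Defaults: three libraries (eggs 20,000; L2 25,000; pupae 15,000 reads —
small-RNA libraries at desk scale), a repeat library with a designated
2007-nt unclassified transposon consensus carrying a 7× `TGTCTGTT`
tandem block at one end (flanks chosen to break the periodicity so the
array is exactly 7 copies), and 46 planted rasiRNAs: cluster 1 with 37
members (33 × 36-mers and 4 pupae-specific 33-mers) spanning 87 nt,
cluster 2 with 9 members spanning 66 nt straddling the tandem block,
all on the plus strand.  Per-member per-stage counts follow a fixed
truth table (eggs-predominant, eggs+L2, L2-exclusive and pupae-exclusive
blocks) and are emitted exactly, not sampled, so recovery tests can
assert equality.  The remaining read budget is split into rDNA (12.3%)
and tRNA (2.3%) degradation products, homopolymer artifacts (1%),
low-quality reads (2%), adapter-less reads (1%), sub-length inserts (1%)
and uniform-random background (remainder, 18–40 nt).  Qualities are
constant Q37 except for the planted low-quality reads (Q8).  Sequencing
error is off by default and available as a per-base rate.

Member windows are redrawn if any planted sequence contains the
3′-adapter's 6-mer prefix, occurs more than once in the consensus, or
collides with another member — guaranteeing that a planted read can
never be mis-clipped or multiply mapped, for any seed.  A single seeded
generator drives all sampling, so outputs are byte-reproducible.

The default genome is 4,626,000 nt with 18 inserted consensus copies
(one copy per 257 kb, the density regime of a repeat-rich partial genome
assembly); degeneration applies point substitutions and optional
truncation of copies.

The qPCR design plants per-primer efficiencies (1.0, 0.95, 0.9, 0.85),
control-locus percent-input levels per antibody, a stage-dependent
enrichment truth table, a 1,800-copy repeat, and Gaussian Ct noise
(σ = 0.1 cycles by default, 0 for round-trip checks).

**What passing tests show — and what they do not.**  The generator emits
reads with exact adapters (or configurable uniform errors), uniform
background, and contaminants drawn from the same reference sets the
screen uses.  It does not emulate Illumina error profiles, ligation
bias, PCR duplication structure, or repeat polymorphism between genomic
copies.  Exact-recovery results therefore validate the pipeline's logic
(clipping decisions, accounting, mapping, clustering, normalization
algebra), not its robustness to real instrument noise; production-scale
library sizes (millions of reads) and genome-wide annotation statistics
are outside what the desk-scale scenario can reproduce.

## Numerical conventions and edge cases

Internal coordinates are 0-based half-open; report writers convert to
1-based inclusive.  Clipping ties break toward the longest insert;
cluster and tag orderings are fully determined (sorted by coordinates
and sequence), so identical inputs give byte-identical outputs.  Fisher
p-values are clipped into (0, 1]; hit intervals must be non-empty; copy
density, percent input and enrichment reject zero denominators rather
than returning infinities.  ORFs require both an initiator Met and a
terminating stop within the frame.
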