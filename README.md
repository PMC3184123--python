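# rasikit

Annotation and quantification of **repeat-associated small interfering RNAs
(rasiRNAs)** from insect small-RNA sequencing libraries, with the companion
ChIP-qPCR / qRT-PCR / densitometry quantification layer used to relate
rasiRNA expression to chromatin state.

rasiRNAs are a piRNA subclass derived from repetitive elements that silence
transposons.  In holometabolous insects such as *Spodoptera frugiperda*
they can be unusually long (33–36 nt), arise from one strand of a repeat
("uni-strand clusters"), and their abundance varies sharply across
developmental stages.  `rasikit` implements the complete desk side of such
a study for libraries sequenced at up to 44 nt:

1. **Read processing** — quality filter, 3′/5′ adapter identification and
   clipping by a semi-global dynamic-programming aligner (match +1,
   mismatch −1, gap −2; overlap ≥ 6 nt, edits ≤ ⌊0.2 × overlap⌋),
   trimming of terminal homopolymer runs > 12 nt, removal of sequences
   ≤ 10 nt, and redundancy collapse into unique tags with per-library
   copy counts.
2. **Repeat annotation** — perfect-match placement of tags (both strands,
   100% identity over the full tag length) on a repeat-consensus library
   (TIR / MITE / LINE / SSR / Helitron / unclassified), an rDNA screen by
   exact match and a tRNA screen at ≥ 95% full-length identity, perfect
   short-tandem-repeat detection, and genomic copy density.
3. **Clusters and expression** — single-linkage merging of overlapping
   hits per (consensus, strand) into uni-strand clusters; per-library
   normalization of counts as a percentage of high-quality reads
   (`100 · c / N`); cross-stage expression matrices; two-sided Fisher's
   exact tests of per-tag counts between libraries; positional
   nucleotide-composition matrices.
4. **Wet-lab quantification** — qPCR standard curves
   (`Ct = slope · log₁₀ q + b`, efficiency `E = 10^(−1/slope) − 1`),
   percent input, enrichment factors relative to a control locus (taken
   as 1), ΔCt relative quantification (`2^ΔCt`), repeat copy-number
   estimation against a single-copy gene, two-step Western densitometry
   normalization and Student's t-tests.
5. **Synthetic data** — a fully seeded generator producing every input
   with known ground truth: a repeat library whose designated 2007-nt
   transposon consensus carries a 7× `UGUCUGUU` tandem repeat, three
   stage-structured libraries with 46 planted rasiRNAs in two uni-strand
   clusters (37 and 9 members), contamination, artifacts, and qPCR/ChIP
   tables with planted efficiencies, enrichment factors and copy numbers.

## Worked example

```python
from rasikit import clip_adapters, normalize_percent, format_milli_percent
from rasikit.pipeline import recover_scenario

# adapter clipping: 36-nt insert followed by the 3' adapter
r = clip_adapters("TGAACGCTAGCGGTACGTTGCAGGCTTAGGCATCAA"
                  "ATCTCGTATGCCGTCTTCTGCTTG")
print(r.status, r.adapter3_start, r.adapter3_edits)
# kept 36 0

# per-library normalization: 167 copies among 5,405,284 high-quality reads
print(format_milli_percent(normalize_percent(167, 5_405_284)))
# 3.089            (i.e. 3.089 x 10^-3 % of the library)

# full pipeline on the default synthetic scenario
run = recover_scenario(seed=17)
for c in run["clusters"]:
    print(c.cluster_id, c.strand, c.member_count, c.span_length)
# cluster_1 + 37 87
# cluster_2 + 9 66
```

The two reported clusters are the planted uni-strand rasiRNA clusters: 37
members over 87 nt and 9 members over 66 nt of the transposon consensus,
recovered with exact membership and exact per-stage copy counts at zero
sequencing error.

A shell workflow is available through the `rasikit` console script
(`simulate`, `process`, `run-all`, `qpcr fit-curve|chip|delta-ct`,
`densito`); `rasikit run-all --seed 17 --out runs/demo` simulates the
default scenario and analyzes it end to end, writing a `manifest.json`
with per-stage read accounting.

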