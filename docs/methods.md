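# Methods

This note documents the models, rules and numerical choices behind
`asmqc`, and what its synthetic-data tests do and do not establish about
real sequencing data.

## Alignment representation and tallies

Every metric is computed from `AlignmentBlock`s: one aligned segment of a
query (contig, read or gene) on a target, with 0-based half-open
intervals and exact tallies (matches, mismatches, inserted/deleted bases,
gap-opening events). Tallies obey

```
matches + mismatches + del_bases == tend − tstart
matches + mismatches + ins_bases == qend − qstart
columns == matches + mismatches + ins_bases + del_bases
```

and are validated on construction. For minus-strand blocks the query
interval is on the original (forward) query and the target interval is
always forward.

PAF input is handled in three fidelity tiers: a `cg:Z` CIGAR with `=`/`X`
ops gives exact tallies; an `NM:i` tag lets mismatches be separated from
indels using the interval arithmetic (only the *net* indel difference is
recoverable, so balanced insertion/deletion pairs inside one block are
attributed to mismatches — exact for blocks produced by most aligners'
per-block edit distances); bare 12-column PAF is accepted but flagged
`lossy`, with the residue-match column as the match count. Evaluation of
lossy blocks is possible but identity/rate numbers then undercount
substitutions; supplying `minimap2 -c` output avoids this.

## Chain selection (the 1-to-1 alignment)

A contig's alignment blocks are first filtered by block identity
(default ≥ 95%, lowerable to 85 for very raw assemblies, where strict
filtering both hides sequence and inflates apparent misassembly counts)
and length (≥ 500 b), then the subset maximizing total matched bases
subject to non-overlapping query intervals is selected by weighted
interval scheduling (O(n log n)); overlaps up to 50 b are tolerated, as
aligners commonly emit small block overlaps at break ends. This plays the
role that 1-to-1 alignment filtering plays in whole-genome comparison
tools: repeated reference regions cannot be double-counted into identity,
and each contig position votes once.

## Misassembly classification and Na50

Adjacent blocks of a chain define a junction, classified in priority
order: different target sequence → *translocation*; different strand →
*inversion*; otherwise a *relocation* when |reference gap − query gap| >
1 kb, with the reference gap computed respecting strand (on `-` the
reference runs backwards along the contig). The 1 kb threshold is the
conventional boundary between local and extensive misassemblies. The
junction coordinate is the query end of the left block. Na50 splits each
contig at its junction coordinates and recomputes N50 over the fragments;
Na50 ≤ N50 always, with equality exactly when no contig was split.

Only the three extensive classes are implemented — no local/fragmented
subcategories — because downstream comparison consumes the aggregate
count and Na50.

## Rate denominators

Identity is 100·Σmatches/Σcolumns over all chained blocks. SNPs/kb counts
mismatched columns and indels/kb counts gap-opening *events* (not gap
bases), both normalized per kb of aligned reference (Σ target spans).
Per-aligned-reference-kb was chosen over per-assembly-kb or
per-reference-kb so that uncovered reference and unaligned contig
sequence cannot dilute the error rates; event-counting for indels makes
the rate insensitive to whether an aligner reports one 3-base gap or
three 1-base gaps only at the event level. These denominator choices are
configuration-free and stated here because published tables rarely define
them.

## Gene reconstruction

A gene counts as reconstructed when its best single-contig chain covers
≥ 90% of the gene length with chain identity ≥ 90%. "Accuracy" is read
as chain alignment identity (matches/columns). The chain is restricted to
one contig deliberately: gene counts are then a proxy for contiguity, and
a gene split across two contigs fails. Curation applies the identical
rule gene-vs-reference, so an assembly identical to the reference always
reconstructs exactly the curated set. Secondary hits are ignored (best
chain only).

The built-in aligner locates candidate regions by exact 15-mer anchors
(~64 probe k-mers per query, clustered, expanded by half the query
length), then computes an optimal edit-distance semi-global alignment per
region on both strands with edlib, keeping the best. The
dynamic-programming area is capped at 1e8 cells; beyond desk scale users
supply PAF from a production aligner.

## Subsampling

`random_subsample` draws reads in a seeded random permutation until the
base quota Q = depth × genome size is reached, so the achieved total
differs from Q by less than one read.

`emulate_subsample` additionally matches a target length histogram
(default 1 kb bins; base-fraction quotas rather than read-count quotas,
because depth is a base quantity). Per-bin quotas Q·f_b are filled from
the longest bin downward — long reads are the scarce resource, and
filling them first minimizes unfixable shortfall. Within a bin, reads are
consumed in seeded-shuffled order; the boundary read is kept only when
its overshoot does not exceed the shortfall it closes (closest approach),
bounding each bin's signed deviation by half a read. Any remaining global
shortfall is topped up one read at a time from whichever open bin is
furthest below its target. Consequences, verified by the tests: achieved
depth within 1% of target under an ample source; L1 histogram distance
(Σ_b |achieved − target base fraction|) < 0.02; and the source maximum
read length is a hard ceiling on the emulated subset — a subsample can
never contain reads longer than the deepest dataset provides.

## Homomer counting

Occurrence (sliding-window, step 1) semantics: a run of length r ≥ k
contributes r − k + 1 occurrences of the k-homomer. This matches the
default of the standard oligonucleotide-frequency counters (cross-checked
against Biostrings in the test suite). N breaks runs; counting is
case-insensitive and soft-masked bases count. Genome-wide counts are
per-sequence sums — no windows span contig boundaries. Rates are
occurrences per base of sequence; ratio tables divide by a baseline
chromosome's rate, and the mitochondrial-excess statistic is the minimum,
over k ∈ {3..7} and nuclear chromosomes, of the percent excess of the
baseline's rate.

## Simulation

**References** are i.i.d. base draws at a per-chromosome GC fraction
(A,T and G,C symmetric). Homopolymer enrichment repeatedly copies a
random base onto its right neighbour — length-preserving, GC-neutral in
expectation — until the 5-homomer occurrence rate reaches the requested
multiple of the i.i.d. expectation Σ_b p_b^5. A GC-0.17 chromosome with
enrichment ~1.5 reproduces the qualitative signature of a yeast
mitochondrial genome: AT-rich, homopolymer-dense, with ≥ 30% homomer
excess over nuclear-like chromosomes at every k in 3–7 (the excess from
the GC skew alone is already far larger than 30%).

**Reads** draw lengths from a log-normal truncated to [min, max]
(defaults μ = 9.0, σ = 0.5 on the log scale, max 56 kb: mean ≈ 9 kb,
right-skewed, matching a typical long-read run) and origins uniformly
(chromosome ∝ length, strand 50/50). Per template base: deletion with
probability d (multiplied by `hp_del_boost` inside homopolymer runs of
length ≥ 5, emulating systematic homomer collapse); otherwise emission,
substituted with probability s; after each emitted base one random base
is inserted with probability i. With s = i = d = 0.023 the expected
truth-alignment identity is (1−s)(1−d)/(1+i) ≈ 93.3%, i.e. a ~93% read
like the early-chemistry long-read datasets this toolkit profiles. Truth
PAF blocks carry each read's error-free origin and exact tallies.

**Corrupted assemblies** start from per-chromosome backbone contigs and
carve dedicated two-segment chimeric contigs off chromosome tails for
each requested structural event, so the expected classification is exact
by construction: translocation joins tails of two chromosomes, inversion
joins a segment to its reverse-complemented neighbour, relocation skips
`gap` (default 5 kb) reference bases at the junction. Point errors use
the same engine as reads (indel events split evenly between single-base
insertions and deletions), and `drop_fraction` removes a central chunk of
each backbone (splitting it into two contigs — a contiguity loss, not a
misassembly). The truth object records injected SNP/indel totals and
every breakpoint with its expected class and junction coordinate.

## What the synthetic tests do and do not show

The generator emulates the *statistical* features the metrics respond to:
length distributions, uniform random point errors, homopolymer-biased
deletions, GC skew, and clean structural events at known coordinates. It
does not emulate coverage bias, chimeric reads, quality-score structure,
repeat-induced mis-alignment ambiguity, or the error spectrum of any
particular basecaller or assembler. Passing the recovery tests therefore
establishes that the *measurement machinery* is correct (the metrics
recover what was injected, exactly for counts and within sampling error
for rates), not that any particular real assembly will be measured
without aligner-induced artefacts — on real data the alignment step, done
externally, contributes its own noise.

## Problem sizes and tolerances

The test suite and acceptance study use 0.2–1 Mb references, 31X read
sets over 0.5 Mb, and 40-gene sets — sizes chosen so every stage,
including the quadratic-DP oracle comparisons, completes in seconds while
keeping sampling error well inside the asserted bands (e.g. injected
1/kb rates are recovered within 10% relative error, where the binomial
sampling error at 1 Mb is ~3%). Determinism is absolute: all randomness
flows through explicit integer seeds into per-call NumPy generators, with
no global state; identical inputs and seed give byte-identical outputs.

## Known limitations

* NM-only PAF blocks cannot distinguish balanced indel pairs from
  mismatches; CIGAR input is exact.
* The misassembly classifier reports the first applicable class per
  junction; a junction that is simultaneously inverted and relocated
  counts once, as an inversion.
* `reference_coverage` counts a reference base covered regardless of how
  many contigs cover it; redundant assemblies are not penalized (that
  signal shows up in total bases instead).
* The built-in gene aligner requires one exact 15-mer anchor; genes
  diverged beyond ~93% identity over every 15-mer window would be missed
  — irrelevant at the 90% identity threshold used for scoring, but a
  reason the aligner is not a general-purpose mapper.
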