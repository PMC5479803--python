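# asmqc

Reference-based quality assessment for long-read genome assemblies, built
for the kind of study where several assembly pipelines are run on Oxford
Nanopore and PacBio reads of a well-characterized genome (such as
*Saccharomyces cerevisiae* S288C) and compared on a common footing.

Comparing assemblies across *platforms* is only meaningful when the input
read sets are comparable: the same fold-coverage **and** a similar
read-length distribution, since contig continuity depends strongly on read
length. `asmqc` therefore provides, in one toolkit:

* **Read-set profiling** — total bases, read count, mean and longest read,
  N50, fold-coverage depth, and binned length histograms.
* **Subsampling** — plain random subsampling to a target depth, and
  *emulating* subsampling that matches both a target depth and a target
  read-length histogram (so a deep PacBio dataset can be cut down to look
  like a 31X nanopore dataset, bin by bin).
* **Assembly evaluation** — the standard metric row against a trusted
  reference: assembly bases, contig count, N50, reference coverage, SNPs
  and indels per aligned-reference kb, average identity, extensive
  misassembly count, and **Na50** (the N50 after breaking contigs at
  misassembly junctions). Contigs shorter than 1 kb are excluded before
  any metric.
* **Gene completeness** — a gene is *reconstructed* if a single contig
  covers ≥ 90% of its length at ≥ 90% alignment identity; the same rule
  against the reference curates the gene set first.
* **Homopolymer profiling** — occurrence counts of k-homomers (AAAAA, …)
  with per-chromosome normalized rates, baseline-ratio tables (how
  homopolymer-rich a low-GC mitochondrial genome is relative to nuclear
  chromosomes), assembly-vs-reference deficiency tables (how many homomers
  an assembler collapsed — the characteristic systematic error of nanopore
  data), and GC content.
* **Simulation with exact truth** — synthetic references with controllable
  GC and homopolymer structure, long reads with a truncated log-normal
  length model and a substitution/insertion/deletion error model
  (optionally homopolymer-boosted deletions), and corrupted assemblies
  with known injected SNP/indel rates and misassembly events. Truth is
  emitted as PAF, so the whole evaluation stack runs without an external
  aligner.

## Definitions used throughout

* **depth (X)** — total bases divided by genome size; "31X" is 31-fold.
* **N50** — the length *L* at which the cumulative sum of lengths, sorted
  descending, first reaches half the total.
* **Na50** — N50 recomputed after splitting contigs at detected
  misassembly breakpoints.
* **misassembly (extensive)** — a junction between adjacent alignment
  blocks of one contig that disagree by reference sequence
  (*translocation*), orientation (*inversion*), or by a > 1 kb gap/overlap
  discrepancy between contig and reference (*relocation*).
* **identity** — 100 × matched columns / alignment columns over the
  selected 1-to-1 chain (the chain maximizes matched bases under
  non-overlapping query intervals).
* **homomer** — a homopolymer k-mer; counting uses overlapping sliding
  windows, so a run of length *r* ≥ *k* counts *r* − *k* + 1 times.

All coordinates are 0-based half-open (PAF convention).

## Worked example

```python
from asmqc import (make_reference, corrupt_assembly, evaluate, EventSpec,
                   simulate_reads, profile, ErrorProfile)

ref = make_reference([300_000, 200_000], gc=0.38, seed=11,
                     names=["chrA", "chrB"])
reads, truth = simulate_reads(ref, depth=31,
                              errors=ErrorProfile(0.023, 0.023, 0.023),
                              seed=12)
prof = profile(reads, genome_size=500_000)
print(f"reads: {prof.n_reads}  bases: {prof.total_bases:,}  "
      f"mean: {prof.mean_len:,.0f}  N50: {prof.n50:,}  depth: {prof.depth_label}")

contigs, sim_truth, blocks = corrupt_assembly(
    ref, snp_rate=0.001, indel_rate=0.001,
    events=["translocation", "inversion", EventSpec("relocation", gap=5000)],
    seed=13)
rep = evaluate(contigs, blocks, {r.id: len(r) for r in ref})
print(f"contigs: {rep.n_contigs}  N50: {rep.n50:,}  coverage: "
      f"{rep.reference_coverage:.1f}%  identity: {rep.identity:.2f}%")
print(f"SNPs/kb: {rep.snps_per_kb:.2f}  indels/kb: {rep.indels_per_kb:.2f}  "
      f"misassemblies: {rep.n_misassemblies}  Na50: {rep.na50:,}")
```

prints

```
reads: 1662  bases: 15,500,142  mean: 9,326  N50: 10,718  depth: 31X
contigs: 5  N50: 110,002  coverage: 99.0%  identity: 99.80%
SNPs/kb: 1.01  indels/kb: 0.95  misassemblies: 3  Na50: 110,002
```

The simulated 31X read set has a right-skewed length distribution with a
~9.3 kb mean, like a real long-read run. The corrupted "assembly" carries
1 SNP and 1 indel event per kb by construction, and the evaluator recovers
rates of 1.01 and 0.95 per kb, 99.80% identity (≈ 100 − 0.2% injected
error), and exactly the three injected misassemblies, one of each kind.

The same operations are available from the shell:

```sh
asmqc simulate ref --lengths 300000,200000 --gc 0.38 --seed 11 --out ref.fa
asmqc simulate reads --reference ref.fa --depth 31 --seed 12 --out reads.fq
asmqc stats reads.fq --genome-size 500000
asmqc simulate assembly --reference ref.fa --events translocation,inversion \
      --snp-rate 0.001 --seed 13 --out asm.fa
asmqc eval --assembly asm.fa --alignments asm.fa.truth.paf --reference ref.fa
```

Every subcommand writes a JSON run manifest (parameters, seed, input
checksums, version) next to its outputs; replaying a manifest's parameters
reproduces deterministic outputs byte-identically. For real data, supply
an assembly-to-reference PAF from any aligner (e.g. `minimap2 -c` for
extended CIGARs) to `asmqc eval`, and FASTQ/FASTA read sets to
`stats`/`subsample`/`emulate`.

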