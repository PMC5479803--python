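"""Reference-based assembly evaluation.

Produces the standard metric row for a draft assembly aligned to a
trusted reference: total bases, contig count, N50, reference coverage,
SNP and indel rates per aligned-reference kb, average identity,
misassembly count, and Na50 (N50 after breaking contigs at misassembly
junctions).

The evaluation works from per-contig alignment blocks (PAF). For each
contig, a 1-to-1 chain is selected by weighted interval scheduling on
query coordinates, maximizing total matched bases; adjacent chain links
that disagree in chromosome, orientation, or by a large gap/overlap
discrepancy are flagged as extensive misassemblies (translocation,
inversion, relocation respectively).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import readstats
from .seqio import AlignmentBlock, ReadRecord


@dataclass(frozen=True)
class EvalConfig:
    """Thresholds for contig and alignment filtering and breakpoint calls.

    min_contig: contigs shorter than this are dropped before any metric.
    min_block_identity: percent identity below which a block is ignored
        (lower it to ~85 for very raw, uncorrected assemblies).
    min_block_len: minimum query span of a retained block.
    misassembly_gap: gap/overlap discrepancy (bases) between query and
        reference beyond which a junction is a relocation.
    """

    min_contig: int = 1000
    min_block_identity: float = 95.0
    min_block_len: int = 500
    misassembly_gap: int = 1000
    chain_overlap_tolerance: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.min_block_identity <= 100):
            raise ValueError("min_block_identity must be in (0, 100]")
        for name in ("min_contig", "min_block_len", "misassembly_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class MisassemblyBreakpoint:
    contig_id: str
    query_pos: int  # junction coordinate on the contig
    kind: str  # relocation | translocation | inversion


@dataclass
class AssemblyEvalReport:
    total_bases: int
    n_contigs: int
    n50: int
    reference_coverage: float
    snps_per_kb: float
    indels_per_kb: float
    identity: float
    n_misassemblies: int
    na50: int
    genes_found: int | None = None
    breakpoints: list[MisassemblyBreakpoint] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "total_bases": self.total_bases,
            "n_contigs": self.n_contigs,
            "n50": self.n50,
            "reference_coverage": self.reference_coverage,
            "snps_per_kb": self.snps_per_kb,
            "indels_per_kb": self.indels_per_kb,
            "identity": self.identity,
            "n_misassemblies": self.n_misassemblies,
            "na50": self.na50,
            "genes_found": self.genes_found,
        }

    # column order mirrors the usual assembly-comparison table layout
    TSV_COLUMNS = (
        "total_bases", "n_contigs", "n50", "reference_coverage",
        "snps_per_kb", "indels_per_kb", "identity", "n_misassemblies",
        "na50", "genes_found",
    )

    def to_tsv(self) -> str:
        d = self.to_dict()
        header = "\t".join(self.TSV_COLUMNS)
        row = "\t".join(
            "" if d[c] is None else (f"{d[c]:.4g}" if isinstance(d[c], float) else str(d[c]))
            for c in self.TSV_COLUMNS
        )
        return header + "\n" + row + "\n"


def filter_contigs(
    assembly: Sequence[ReadRecord], min_contig: int = 1000
) -> list[ReadRecord]:
    """Drop contigs shorter than ``min_contig``; applied before any metric."""
    kept = [c for c in assembly if len(c) >= min_contig]
    if not kept:
        raise ValueError(f"no contigs of length >= {min_contig} remain")
    return kept


def chain_blocks(
    blocks: Sequence[AlignmentBlock], cfg: EvalConfig = EvalConfig()
) -> list[AlignmentBlock]:
    """Select the 1-to-1 alignment chain of one contig.

    Keeps the subset of blocks maximizing total matches subject to query
    intervals being non-overlapping (overlaps up to
    ``cfg.chain_overlap_tolerance`` bases are tolerated), by weighted
    interval scheduling on query coordinates. Returns the chain in query
    order; an empty list means the contig is unaligned.
    """
    cand = [
        b
        for b in blocks
        if b.identity >= cfg.min_block_identity and b.query_span >= cfg.min_block_len
    ]
    if not cand:
        return []
    cand.sort(key=lambda b: (b.qend, b.qstart))
    ends = [b.qend for b in cand]
    tol = cfg.chain_overlap_tolerance
    n = len(cand)
    best = [0.0] * (n + 1)  # best[i]: max matches using first i blocks
    take_prev = [0] * n
    for i, b in enumerate(cand):
        # last block j (by qend) compatible with b: qend_j <= qstart_i + tol
        j = bisect.bisect_right(ends, b.qstart + tol, hi=i)
        with_i = best[j] + b.matches
        if with_i > best[i]:
            best[i + 1] = with_i
            take_prev[i] = j
        else:
            best[i + 1] = best[i]
            take_prev[i] = -1
    chain: list[AlignmentBlock] = []
    i = n
    while i > 0:
        if best[i] == best[i - 1]:
            i -= 1
        else:
            chain.append(cand[i - 1])
            i = take_prev[i - 1]
    chain.reverse()
    chain.sort(key=lambda b: b.qstart)
    return chain


def detect_misassemblies(
    chain: Sequence[AlignmentBlock], cfg: EvalConfig = EvalConfig()
) -> list[MisassemblyBreakpoint]:
    """Flag extensive misassembly junctions between adjacent chain links.

    Priority per junction: translocation (different reference sequence),
    then inversion (different strand), then relocation (query gap and
    reference gap disagree by more than ``cfg.misassembly_gap``). The
    reference gap respects strand: on '-' the reference runs backwards
    along the contig.
    """
    out: list[MisassemblyBreakpoint] = []
    for prev, nxt in zip(chain, chain[1:]):
        pos = prev.qend
        if prev.target_id != nxt.target_id:
            out.append(MisassemblyBreakpoint(prev.query_id, pos, "translocation"))
        elif prev.strand != nxt.strand:
            out.append(MisassemblyBreakpoint(prev.query_id, pos, "inversion"))
        else:
            query_gap = nxt.qstart - prev.qend
            if prev.strand == "+":
                ref_gap = nxt.tstart - prev.tend
            else:
                ref_gap = prev.tstart - nxt.tend
            if abs(ref_gap - query_gap) > cfg.misassembly_gap:
                out.append(MisassemblyBreakpoint(prev.query_id, pos, "relocation"))
    return out


def na50(
    contigs: Sequence[ReadRecord], breakpoints: Iterable[MisassemblyBreakpoint]
) -> int:
    """N50 after splitting each contig at its misassembly junctions."""
    by_contig: dict[str, list[int]] = {}
    for bp in breakpoints:
        by_contig.setdefault(bp.contig_id, []).append(bp.query_pos)
    fragments: list[int] = []
    for c in contigs:
        cuts = sorted(set(by_contig.get(c.id, [])))
        bounds = [0] + [p for p in cuts if 0 < p < len(c)] + [len(c)]
        fragments.extend(b - a for a, b in zip(bounds, bounds[1:]))
    return readstats.n50(fragments)


def reference_coverage(
    chains: Iterable[Sequence[AlignmentBlock]], reference_lengths: Mapping[str, int]
) -> float:
    """Percent of reference bases covered by at least one chained block."""
    by_target: dict[str, list[tuple[int, int]]] = {}
    for chain in chains:
        for b in chain:
            by_target.setdefault(b.target_id, []).append((b.tstart, b.tend))
    covered = 0
    for iv in by_target.values():
        iv.sort()
        cur_s, cur_e = iv[0]
        for s, e in iv[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    total = sum(reference_lengths.values())
    return 100.0 * covered / total


def identity_and_variant_rates(
    chains: Iterable[Sequence[AlignmentBlock]],
) -> tuple[float, float, float]:
    """(identity %, SNPs/kb, indel events/kb) over all chained blocks.

    Identity is 100 * sum(matches) / sum(columns); rates are normalized
    per kb of aligned reference (sum of target spans).
    """
    matches = mismatches = columns = events = ref_bases = 0
    for chain in chains:
        for b in chain:
            matches += b.matches
            mismatches += b.mismatches
            columns += b.columns
            events += b.ins_events + b.del_events
            ref_bases += b.target_span
    if ref_bases == 0:
        raise ValueError("no aligned reference bases; cannot compute rates")
    kb = ref_bases / 1000.0
    return 100.0 * matches / columns, mismatches / kb, events / kb


def evaluate(
    assembly: Sequence[ReadRecord],
    alignments: Sequence[AlignmentBlock],
    reference_lengths: Mapping[str, int],
    genes_found: int | None = None,
    cfg: EvalConfig = EvalConfig(),
) -> AssemblyEvalReport:
    """Full metric row for one assembly against one reference."""
    contigs = filter_contigs(assembly, cfg.min_contig)
    keep_ids = {c.id for c in contigs}
    by_contig: dict[str, list[AlignmentBlock]] = {c.id: [] for c in contigs}
    for b in alignments:
        if b.query_id in keep_ids:
            by_contig[b.query_id].append(b)

    chains = {cid: chain_blocks(bl, cfg) for cid, bl in by_contig.items()}
    breakpoints: list[MisassemblyBreakpoint] = []
    for cid in sorted(chains):
        breakpoints.extend(detect_misassemblies(chains[cid], cfg))

    lengths = [len(c) for c in contigs]
    identity, snps_kb, indels_kb = identity_and_variant_rates(chains.values())
    return AssemblyEvalReport(
        total_bases=sum(lengths),
        n_contigs=len(contigs),
        n50=readstats.n50(lengths),
        reference_coverage=reference_coverage(chains.values(), reference_lengths),
        snps_per_kb=snps_kb,
        indels_per_kb=indels_kb,
        identity=identity,
        n_misassemblies=len(breakpoints),
        na50=na50(contigs, breakpoints),
        genes_found=genes_found,
        breakpoints=breakpoints,
    )
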