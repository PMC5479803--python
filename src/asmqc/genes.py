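"""Gene-set curation and gene-reconstruction completeness.

A gene is *reconstructed* in an assembly if a single contig carries an
alignment chain covering at least 90% of the gene's length with at least
90% alignment identity; the same rule against the reference curates the
gene set in the first place (genes that do not map cleanly to their own
reference are excluded from scoring). Both directions share one
chain-and-threshold engine, so curation on the reference and assessment
on an identical assembly give identical gene sets.

A built-in small-scale semi-global aligner (exact edit-distance DP via
edlib, candidate regions pre-located by 15-mer anchors) lets the module
run without an external aligner at gene scale; at genome scale users
supply PAF from any aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib

from .asmeval import EvalConfig, chain_blocks
from .seqio import AlignmentBlock, ReadRecord, tallies_from_cigar

ANCHOR_K = 15
MAX_DP_AREA = 10**8


@dataclass(frozen=True)
class GeneAssessment:
    gene_id: str
    gene_len: int
    best_contig: str | None
    covered_frac: float
    chain_identity: float
    reconstructed: bool


def _chain_cfg(min_identity: float) -> EvalConfig:
    # gene-scale chaining: no minimum block length, block identity gate at
    # the gene identity threshold so sub-threshold fragments cannot vote
    return EvalConfig(
        min_contig=1,
        min_block_identity=min_identity,
        min_block_len=1,
        misassembly_gap=1000,
    )


def _best_single_target_chain(
    blocks: Sequence[AlignmentBlock], min_identity: float
) -> tuple[str | None, list[AlignmentBlock]]:
    """Best chain (by total matches) restricted to one target sequence."""
    cfg = _chain_cfg(min_identity)
    by_target: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_target.setdefault(b.target_id, []).append(b)
    best_id, best_chain, best_matches = None, [], -1
    for tid in sorted(by_target):
        chain = chain_blocks(by_target[tid], cfg)
        m = sum(b.matches for b in chain)
        if m > best_matches:
            best_id, best_chain, best_matches = tid, chain, m
    return best_id, best_chain


def _covered_query_bases(chain: Sequence[AlignmentBlock]) -> int:
    """Union of chained query intervals (chain may overlap by tolerance)."""
    covered, cur_end = 0, -1
    for b in sorted(chain, key=lambda b: b.qstart):
        s, e = max(b.qstart, cur_end), b.qend
        if e > s:
            covered += e - s
        cur_end = max(cur_end, e)
    return covered


def assess_gene(
    gene_id: str,
    gene_len: int,
    blocks: Sequence[AlignmentBlock],
    min_len_frac: float = 0.90,
    min_identity: float = 90.0,
) -> GeneAssessment:
    """Apply the chain-and-threshold reconstruction rule to one gene."""
    tid, chain = _best_single_target_chain(blocks, min_identity)
    if not chain:
        return GeneAssessment(gene_id, gene_len, None, 0.0, 0.0, False)
    covered = _covered_query_bases(chain) / gene_len
    columns = sum(b.columns for b in chain)
    ident = 100.0 * sum(b.matches for b in chain) / columns
    ok = covered >= min_len_frac and ident >= min_identity
    return GeneAssessment(gene_id, gene_len, tid, covered, ident, ok)


def curate_gene_set(
    gene_alignments_to_reference: Sequence[AlignmentBlock],
    genes: Sequence[ReadRecord],
    min_len_frac: float = 0.90,
    min_identity: float = 90.0,
) -> set[str]:
    """Genes whose best single-chromosome chain on the reference covers
    >= min_len_frac of their length at >= min_identity percent identity.
    Genes with no alignment at all are silently excluded.
    """
    by_gene: dict[str, list[AlignmentBlock]] = {}
    for b in gene_alignments_to_reference:
        by_gene.setdefault(b.query_id, []).append(b)
    kept: set[str] = set()
    for g in genes:
        a = assess_gene(g.id, len(g), by_gene.get(g.id, []), min_len_frac, min_identity)
        if a.reconstructed:
            kept.add(g.id)
    return kept


def assess_reconstruction(
    gene_alignments_to_assembly: Sequence[AlignmentBlock],
    curated: set[str],
    gene_lengths: Mapping[str, int],
    min_len_frac: float = 0.90,
    min_identity: float = 90.0,
) -> tuple[dict[str, GeneAssessment], int]:
    """Score every curated gene against an assembly.

    Returns per-gene assessments and the number of reconstructed genes.
    The chain is restricted to the single best contig: a gene split
    across contigs does not count as reconstructed.
    """
    by_gene: dict[str, list[AlignmentBlock]] = {}
    for b in gene_alignments_to_assembly:
        if b.query_id in curated:
            by_gene.setdefault(b.query_id, []).append(b)
    out: dict[str, GeneAssessment] = {}
    for gid in sorted(curated):
        out[gid] = assess_gene(
            gid, gene_lengths[gid], by_gene.get(gid, []), min_len_frac, min_identity
        )
    return out, sum(a.reconstructed for a in out.values())


def _anchor_regions(query: str, target: str, margin: int) -> list[tuple[int, int]]:
    """Candidate target regions sharing an exact 15-mer with the query."""
    k = ANCHOR_K
    if len(query) < k:  # too short to anchor: scan the whole target
        return [(0, len(target))]
    step = max(1, (len(query) - k) // 64)  # <= ~64 probe k-mers
    probes = {query[i : i + k] for i in range(0, len(query) - k + 1, step)}
    hits: list[int] = []
    for p in probes:
        start = target.find(p)
        while start != -1:
            hits.append(start)
            start = target.find(p, start + 1)
    if not hits:
        return []
    hits.sort()
    regions: list[tuple[int, int]] = []
    cur_s = cur_e = hits[0]
    for h in hits[1:]:
        if h - cur_e > len(query):
            regions.append((cur_s, cur_e))
            cur_s = cur_e = h
        else:
            cur_e = h
    regions.append((cur_s, cur_e))
    return [
        (max(0, s - margin), min(len(target), e + ANCHOR_K + margin))
        for s, e in regions
    ]


def align_semi_global(
    query: ReadRecord, target: ReadRecord
) -> AlignmentBlock | None:
    """Optimal edit-distance semi-global (infix) alignment of a short
    query within a long target, both strands, with exact tallies.

    Candidate regions are pre-located by exact 15-mer anchors; the
    dynamic-programming area is bounded (error beyond 1e8 cells — use an
    external aligner for such inputs). Returns None when no anchor hits.
    """
    qseq, tseq = query.sequence, target.sequence
    margin = len(qseq) // 2 + 100
    best: tuple[int, str, int, int, str] | None = None  # (dist, strand, rs, re, cigar)
    for strand, qs in (("+", qseq), ("-", query.reverse_complement().sequence)):
        for rs, re_ in _anchor_regions(qs, tseq, margin):
            if len(qs) * (re_ - rs) > MAX_DP_AREA:
                raise ValueError(
                    "alignment area exceeds the built-in aligner's bound; "
                    "align externally and supply PAF"
                )
            res = edlib.align(qs, tseq[rs:re_], mode="HW", task="path")
            if res["editDistance"] < 0:
                continue
            loc = res["locations"][0]
            cand = (res["editDistance"], strand, rs + loc[0], rs + loc[1] + 1, res["cigar"])
            if best is None or cand[0] < best[0]:
                best = cand
    if best is None:
        return None
    dist, strand, ts, te, cigar = best
    t = tallies_from_cigar(cigar)
    block = AlignmentBlock(
        query.id, len(qseq), 0, len(qseq), strand,
        target.id, len(tseq), ts, te,
        t["matches"], t["mismatches"], t["ins_bases"], t["del_bases"],
        t["ins_events"], t["del_events"],
    )
    block.validate()
    return block


def align_genes(
    genes: Sequence[ReadRecord], targets: Sequence[ReadRecord]
) -> list[AlignmentBlock]:
    """Align each gene to every target sequence with the built-in aligner,
    keeping each gene's best hit per target.
    """
    blocks: list[AlignmentBlock] = []
    for g in genes:
        for t in targets:
            b = align_semi_global(g, t)
            if b is not None:
                blocks.append(b)
    return blocks
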