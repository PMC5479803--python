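"""Assembly evaluation: chaining, misassembly calls, Na50, coverage, rates."""

from itertools import combinations

import numpy as np
import pytest

from asmqc import (
    AlignmentBlock,
    EvalConfig,
    MisassemblyBreakpoint,
    ReadRecord,
    chain_blocks,
    detect_misassemblies,
    evaluate,
    filter_contigs,
    identity_and_variant_rates,
    na50,
    reference_coverage,
)
from asmqc.readstats import n50 as plain_n50


def perfect_block(qid, qs, qe, tid="t", ts=None, te=None, strand="+",
                  qlen=100_000, tlen=1_000_000, mismatches=0):
    span = qe - qs
    ts = qs if ts is None else ts
    te = ts + span if te is None else te
    b = AlignmentBlock(qid, qlen, qs, qe, strand, tid, tlen, ts, te,
                       span - mismatches, mismatches)
    b.validate()
    return b


class TestFilterContigs:
    def test_length_threshold(self):
        contigs = [ReadRecord("a", "A" * 500), ReadRecord("b", "A" * 1500)]
        assert [c.id for c in filter_contigs(contigs, 1000)] == ["b"]

    def test_min_one_is_identity(self, rng):
        contigs = [ReadRecord(f"c{i}", "A" * int(L))
                   for i, L in enumerate(rng.integers(1, 5000, 50))]
        assert filter_contigs(contigs, 1) == contigs

    def test_all_removed_is_error(self):
        with pytest.raises(ValueError):
            filter_contigs([ReadRecord("a", "A" * 10)], 1000)

    def test_matches_naive_filter(self, rng):
        for _ in range(20):
            lengths = rng.integers(1, 3000, size=30)
            contigs = [ReadRecord(f"c{i}", "A" * int(L))
                       for i, L in enumerate(lengths)]
            cut = int(rng.integers(1, 2500))
            naive = [c for c in contigs if len(c) >= cut]
            if naive:
                assert filter_contigs(contigs, cut) == naive


def brute_force_chain_matches(blocks, tol):
    """Max total matches over all subsets with query overlaps <= tol."""
    best = 0
    for r in range(1, len(blocks) + 1):
        for sub in combinations(blocks, r):
            ordered = sorted(sub, key=lambda b: b.qstart)
            if all(b2.qstart >= b1.qend - tol
                   for b1, b2 in zip(ordered, ordered[1:])):
                best = max(best, sum(b.matches for b in ordered))
    return best


class TestChainBlocks:
    CFG = EvalConfig(min_block_identity=1e-9, min_block_len=1)

    def test_disjoint_blocks_both_kept(self):
        blocks = [perfect_block("c", 0, 100), perfect_block("c", 200, 300)]
        assert len(chain_blocks(blocks, self.CFG)) == 2

    def test_overlapping_keeps_heavier(self):
        b1 = perfect_block("c", 0, 900)
        b2 = perfect_block("c", 0, 800, ts=5000)
        chain = chain_blocks([b2, b1], self.CFG)
        assert chain == [b1]

    def test_identity_filter_applies(self):
        noisy = perfect_block("c", 0, 1000, mismatches=200)  # 80% identity
        assert chain_blocks([noisy], EvalConfig(min_block_identity=95,
                                                min_block_len=1)) == []

    def test_matches_exhaustive_search(self, rng):
        """Weighted interval scheduling equals brute force on <= 12 blocks."""
        for trial in range(60):
            n = int(rng.integers(1, 13))
            blocks = []
            for _ in range(n):
                qs = int(rng.integers(0, 5000))
                span = int(rng.integers(10, 2000))
                blocks.append(perfect_block("c", qs, qs + span,
                                            ts=int(rng.integers(0, 50_000))))
            chain = chain_blocks(blocks, self.CFG)
            got = sum(b.matches for b in chain)
            # the chain itself must be feasible
            for b1, b2 in zip(chain, chain[1:]):
                assert b2.qstart >= b1.qend - self.CFG.chain_overlap_tolerance
            assert got == brute_force_chain_matches(
                blocks, self.CFG.chain_overlap_tolerance)


class TestDetectMisassemblies:
    def test_translocation(self):
        chain = [perfect_block("c", 0, 1000, tid="chr1"),
                 perfect_block("c", 1000, 2000, tid="chr2")]
        (bp,) = detect_misassemblies(chain)
        assert bp.kind == "translocation" and bp.query_pos == 1000

    def test_inversion(self):
        chain = [perfect_block("c", 0, 1000, strand="+"),
                 perfect_block("c", 1000, 2000, ts=2000, strand="-")]
        (bp,) = detect_misassemblies(chain)
        assert bp.kind == "inversion"

    def test_relocation_from_reference_gap(self):
        chain = [perfect_block("c", 0, 10_000, ts=0),
                 perfect_block("c", 10_000, 18_000, ts=12_000)]
        (bp,) = detect_misassemblies(chain)
        assert bp.kind == "relocation"

    def test_small_gap_is_collinear(self):
        chain = [perfect_block("c", 0, 10_000, ts=0),
                 perfect_block("c", 10_000, 18_000, ts=10_500)]
        assert detect_misassemblies(chain) == []

    def test_minus_strand_collinear_chain_is_clean(self):
        # contig runs backwards along the reference: t-intervals descend
        chain = [perfect_block("c", 0, 1000, ts=9000, strand="-"),
                 perfect_block("c", 1000, 2000, ts=8000, strand="-")]
        assert detect_misassemblies(chain) == []

    def test_minus_strand_relocation(self):
        chain = [perfect_block("c", 0, 1000, ts=9000, strand="-"),
                 perfect_block("c", 1000, 2000, ts=3000, strand="-")]
        (bp,) = detect_misassemblies(chain)
        assert bp.kind == "relocation"


def naive_na50(contig_lengths, breakpoints_by_contig):
    frags = []
    for cid, L in contig_lengths.items():
        cuts = sorted(set(breakpoints_by_contig.get(cid, [])))
        prev = 0
        for c in cuts + [L]:
            frags.append(c - prev)
            prev = c
    return plain_n50(frags)


class TestNa50:
    def test_single_cut(self):
        contigs = [ReadRecord("c", "A" * 100_000)]
        bps = [MisassemblyBreakpoint("c", 40_000, "relocation")]
        assert na50(contigs, bps) == 60_000

    def test_no_breakpoints_is_n50(self, rng):
        contigs = [ReadRecord(f"c{i}", "A" * int(L))
                   for i, L in enumerate(rng.integers(1000, 99_000, 20))]
        assert na50(contigs, []) == plain_n50([len(c) for c in contigs])

    def test_matches_naive_split_oracle(self, rng):
        for _ in range(50):
            contigs = [ReadRecord(f"c{i}", "A" * int(L))
                       for i, L in enumerate(rng.integers(1000, 50_000, 10))]
            bps = []
            by_contig = {}
            for c in contigs:
                for _ in range(int(rng.integers(0, 4))):
                    pos = int(rng.integers(1, len(c)))
                    bps.append(MisassemblyBreakpoint(c.id, pos, "relocation"))
                    by_contig.setdefault(c.id, []).append(pos)
            got = na50(contigs, bps)
            want = naive_na50({c.id: len(c) for c in contigs}, by_contig)
            assert got == want
            assert got <= plain_n50([len(c) for c in contigs])


class TestReferenceCoverage:
    def test_overlapping_blocks_union(self):
        chains = [[perfect_block("a", 0, 50, ts=0)],
                  [perfect_block("b", 0, 50, ts=25)]]
        assert reference_coverage(chains, {"t": 100}) == pytest.approx(75.0)

    def test_empty_and_full(self):
        assert reference_coverage([], {"t": 100}) == 0.0
        chains = [[perfect_block("a", 0, 100, ts=0, tlen=100)]]
        assert reference_coverage(chains, {"t": 100}) == pytest.approx(100.0)

    def test_matches_boolean_mask_oracle(self, rng):
        for _ in range(30):
            tlen = 2000
            chains = []
            mask = np.zeros(tlen, dtype=bool)
            for _ in range(int(rng.integers(1, 15))):
                s = int(rng.integers(0, tlen - 10))
                e = s + int(rng.integers(1, tlen - s))
                mask[s:e] = True
                chains.append([perfect_block("q", 0, e - s, ts=s, tlen=tlen,
                                             qlen=tlen)])
            got = reference_coverage(chains, {"t": tlen})
            assert got == pytest.approx(100.0 * mask.sum() / tlen)


class TestIdentityAndRates:
    def test_worked_example(self):
        b = AlignmentBlock("c", 2000, 0, 995, "+", "t", 2000, 0, 995,
                           990, 5, 5, 0, 5, 0)
        # 990 matches / 1000 columns; 5 SNPs and 5 indel events per 0.995 kb
        ident, snps, indels = identity_and_variant_rates([[b]])
        assert ident == pytest.approx(99.0)
        assert snps == pytest.approx(5 / 0.995, rel=1e-6)
        assert indels == pytest.approx(5 / 0.995, rel=1e-6)

    def test_perfect_alignment(self):
        ident, snps, indels = identity_and_variant_rates(
            [[perfect_block("c", 0, 1000)]])
        assert (ident, snps, indels) == (100.0, 0.0, 0.0)

    def test_zero_aligned_bases_is_error(self):
        with pytest.raises(ValueError):
            identity_and_variant_rates([[]])


class TestEvaluate:
    def test_self_alignment_is_clean(self):
        contigs = [ReadRecord("chr1", "A" * 50_000),
                   ReadRecord("chr2", "C" * 30_000)]
        blocks = [perfect_block("chr1", 0, 50_000, tid="chr1", qlen=50_000,
                                tlen=50_000),
                  perfect_block("chr2", 0, 30_000, tid="chr2", qlen=30_000,
                                tlen=30_000)]
        rep = evaluate(contigs, blocks, {"chr1": 50_000, "chr2": 30_000})
        assert rep.reference_coverage == pytest.approx(100.0)
        assert rep.identity == pytest.approx(100.0)
        assert rep.n_misassemblies == 0
        assert rep.na50 == rep.n50

    def test_sub_1kb_contig_not_counted(self):
        contigs = [ReadRecord("big", "A" * 12_000), ReadRecord("tiny", "A" * 800)]
        blocks = [perfect_block("big", 0, 12_000, qlen=12_000, tlen=12_000)]
        rep = evaluate(contigs, blocks, {"t": 12_000})
        assert rep.n_contigs == 1
        assert rep.total_bases == 12_000

    def test_raising_identity_threshold_never_raises_coverage(self, rng):
        contigs = [ReadRecord("c", "A" * 20_000)]
        blocks = [perfect_block("c", 15_000, 20_000, qlen=20_000, ts=15_000)]
        for _ in range(10):
            qs = int(rng.integers(0, 15_000))
            span = int(rng.integers(600, 4000))
            mism = int(span * rng.uniform(0, 0.2))
            blocks.append(perfect_block("c", qs, qs + span, qlen=20_000,
                                        ts=qs, mismatches=mism))
        cov = []
        for ident in (80.0, 90.0, 95.0, 99.0):
            cfg = EvalConfig(min_block_identity=ident)
            rep = evaluate(contigs, blocks, {"t": 1_000_000}, cfg=cfg)
            cov.append(rep.reference_coverage)
        assert all(a >= b for a, b in zip(cov, cov[1:]))
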