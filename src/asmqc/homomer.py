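"""Homopolymer (homomer) occurrence counting and GC content.

A k-homomer is a run of k identical bases, e.g. AAAAA for k = 5.
Counting is occurrence-based: every length-k sliding window consisting
of one repeated base counts once, so a run of length r >= k contributes
r - k + 1 occurrences. This matches the usual oligonucleotide-frequency
convention in genomics toolkits. N breaks runs and never matches.

The per-chromosome normalized rate (occurrences / chromosome length)
supports two comparisons: chromosome-vs-baseline ratio tables (how much
more homopolymer-dense a mitochondrion-like chromosome is than the
nuclear ones) and assembly-vs-reference deficiency tables (how many
homomers an assembler lost).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import ReadRecord

BASES = "ACGT"


@dataclass(frozen=True)
class HomomerProfile:
    seq_id: str
    seq_len: int
    k: int
    counts: Mapping[str, int]  # base -> occurrence count

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def rate(self) -> float:
        """Occurrences per base of sequence."""
        return self.total / self.seq_len


def _run_lengths(seq: str, base: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord(base)
    if not arr.any():
        return np.empty(0, dtype=np.int64)
    padded = np.concatenate(([False], arr, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return (edges[1::2] - edges[0::2]).astype(np.int64)


def count_homomers(seq: ReadRecord | str, k: int, seq_id: str = "") -> HomomerProfile:
    """Occurrence counts of A^k, C^k, G^k, T^k in one sequence."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(seq, ReadRecord):
        seq_id, seq = seq.id, seq.sequence
    seq = seq.upper()
    counts = {}
    for b in BASES:
        runs = _run_lengths(seq, b)
        counts[b] = int(np.maximum(runs - k + 1, 0).sum())
    return HomomerProfile(seq_id, len(seq), k, counts)


def gc_content(seq: ReadRecord | str) -> float:
    """(G+C)/(A+C+G+T); N excluded from both numerator and denominator."""
    if isinstance(seq, ReadRecord):
        seq = seq.sequence
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    gc = int(((arr == ord("G")) | (arr == ord("C"))).sum())
    acgt = int(np.isin(arr, [ord(b) for b in BASES]).sum())
    if acgt == 0:
        raise ValueError("sequence has no unambiguous bases")
    return gc / acgt


def homomer_ratio_table(
    profiles: Sequence[HomomerProfile], baseline_id: str
) -> dict[str, float]:
    """Per-sequence homomer rate divided by the baseline sequence's rate."""
    by_id = {p.seq_id: p for p in profiles}
    if baseline_id not in by_id:
        raise ValueError(f"baseline {baseline_id!r} not among profiles")
    base_rate = by_id[baseline_id].rate
    if base_rate == 0:
        raise ValueError("baseline homomer rate is zero")
    return {p.seq_id: p.rate / base_rate for p in profiles}


def homomer_deficiency(
    assembly: Sequence[ReadRecord], reference: Sequence[ReadRecord], k: int
) -> dict[str, dict[str, float]]:
    """Per-word homomer occurrence totals in assembly vs reference.

    Counts are per-sequence then summed (no cross-contig windows).
    Returns {word: {assembly, reference, ratio}}; ratio is inf when the
    word is absent from the reference but present in the assembly.
    """
    asm = {b: 0 for b in BASES}
    ref = {b: 0 for b in BASES}
    for rec in assembly:
        for b, c in count_homomers(rec, k).counts.items():
            asm[b] += c
    for rec in reference:
        for b, c in count_homomers(rec, k).counts.items():
            ref[b] += c
    out = {}
    for b in BASES:
        word = b * k
        ratio = asm[b] / ref[b] if ref[b] else (float("inf") if asm[b] else 1.0)
        out[word] = {"assembly": asm[b], "reference": ref[b], "ratio": ratio}
    return out


def mito_excess(
    genome: Sequence[ReadRecord],
    baseline_id: str,
    ks: Iterable[int] = (3, 4, 5, 6, 7),
) -> float:
    """Minimum percent homomer excess of the baseline chromosome over
    every other chromosome, across k values.

    100 * (rate_k(baseline) / rate_k(chrom) - 1), minimized over k and
    chromosomes. Chromosomes with a zero rate at some k are excluded
    from that k's comparison.
    """
    if len(genome) < 2:
        raise ValueError("need at least two chromosomes")
    ids = [r.id for r in genome]
    if baseline_id not in ids:
        raise ValueError(f"baseline {baseline_id!r} not in genome")
    worst = float("inf")
    for k in ks:
        profiles = {r.id: count_homomers(r, k) for r in genome}
        base_rate = profiles[baseline_id].rate
        for rid, p in profiles.items():
            if rid == baseline_id:
                continue
            if p.rate == 0:
                continue
            worst = min(worst, 100.0 * (base_rate / p.rate - 1.0))
    if worst == float("inf"):
        raise ValueError("no chromosome had a nonzero homomer rate")
    return worst
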