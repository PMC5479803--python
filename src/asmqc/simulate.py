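"""Synthetic data with known truth: references, long reads, assemblies.

Three generators, all deterministic given their seed:

* ``make_reference`` — chromosomes with controllable GC content and
  homopolymer enrichment, including low-GC homopolymer-rich
  mitochondrion-like chromosomes.
* ``simulate_reads`` — long reads with a truncated log-normal length
  model and a platform-style error model (substitutions, insertions,
  deletions, with deletions optionally boosted inside homopolymer runs,
  mimicking the homomer-collapsing behaviour of nanopore basecalling).
  Emits a truth PAF with each read's error-free origin and exact
  match/mismatch/indel tallies.
* ``corrupt_assembly`` — an "assembly" derived from the reference with
  known injected SNP/indel rates, dropped regions, and structural
  misassembly events (translocations, inversions, relocations), plus
  the exact piecewise truth alignment.

Because truth is emitted as PAF, the evaluation modules are testable
end-to-end without any external aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import AlignmentBlock, ReadRecord

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base error rates for read simulation.

    hp_del_boost multiplies the deletion rate inside homopolymer runs of
    length >= hp_min, emulating systematic homomer loss.
    """

    sub_rate: float = 0.023
    ins_rate: float = 0.023
    del_rate: float = 0.023
    hp_del_boost: float = 1.0
    hp_min: int = 5

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must be in [0, 1)")
        if self.sub_rate + self.ins_rate + self.del_rate >= 0.5:
            raise ValueError("total error rate must be < 0.5")
        if self.hp_del_boost < 1:
            raise ValueError("hp_del_boost must be >= 1")


PERFECT_PROFILE = ErrorProfile(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class LengthModel:
    """Truncated log-normal read-length model.

    Defaults give a right-skewed distribution with mean about 9 kb and a
    hard maximum near 56 kb, typical of a long-read yeast dataset.
    """

    mu: float = 9.0
    sigma: float = 0.5
    min_len: int = 100
    max_len: int = 56000

    def __post_init__(self) -> None:
        if self.max_len < self.min_len:
            raise ValueError("max_len < min_len")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            draw = rng.lognormal(self.mu, self.sigma, size=n - filled)
            ok = draw[(draw >= self.min_len) & (draw <= self.max_len)]
            out[filled : filled + ok.size] = ok.astype(np.int64)
            filled += ok.size
        return out


@dataclass(frozen=True)
class EventSpec:
    """One structural misassembly to inject: translocation, inversion,
    or relocation (with a reference gap of ``gap`` bases)."""

    kind: str
    gap: int = 5000
    size: int = 30000

    def __post_init__(self) -> None:
        if self.kind not in ("translocation", "inversion", "relocation"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class SimTruth:
    """Ground truth for a corrupted assembly."""

    snps: int
    indel_events: int
    breakpoints: list[tuple[str, int, str]]  # (contig_id, query_pos, kind)
    dropped_bases: int


def _decode(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    lut = np.zeros(128, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def _run_length_at(codes: np.ndarray) -> np.ndarray:
    """Length of the maximal homopolymer run containing each position."""
    n = codes.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    boundaries = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    lens = ends - starts
    return np.repeat(lens, lens)


def _homomer_rate(codes: np.ndarray, k: int) -> float:
    boundaries = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [codes.size]))
    lens = ends - starts
    return float(np.maximum(lens - k + 1, 0).sum()) / codes.size


def make_reference(
    chrom_lengths: Sequence[int],
    gc: Sequence[float] | float = 0.38,
    hp_enrichment: Sequence[float] | float = 1.0,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> list[ReadRecord]:
    """Random chromosomes at given GC, optionally homopolymer-enriched.

    Enrichment stochastically extends existing runs (copying a base onto
    its neighbour, keeping length fixed) until the 5-homomer occurrence
    rate reaches hp_enrichment times the i.i.d. expectation for that GC.
    """
    n = len(chrom_lengths)
    gcs = [gc] * n if np.isscalar(gc) else list(gc)
    enr = [hp_enrichment] * n if np.isscalar(hp_enrichment) else list(hp_enrichment)
    if names is None:
        names = [f"chr{i + 1}" for i in range(n)]
    rng = np.random.default_rng(seed)
    out = []
    for name, length, g, e in zip(names, chrom_lengths, gcs, enr):
        if not 0 < g < 1:
            raise ValueError(f"{name}: gc must be in (0, 1)")
        p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
        codes = rng.choice(4, size=length, p=p).astype(np.uint8)
        if e > 1.0:
            target = e * float((p**5).sum())
            for _ in range(1000):
                if _homomer_rate(codes, 5) >= target:
                    break
                pos = rng.integers(0, length - 1, size=max(length // 200, 1))
                codes[pos + 1] = codes[pos]
            else:
                raise ValueError(
                    f"{name}: could not reach 5-homomer enrichment {e}"
                )
        out.append(ReadRecord(name, _decode(codes)))
    return out


def _apply_errors(
    codes: np.ndarray,
    rng: np.random.Generator,
    sub_rate: float,
    ins_rate: float,
    del_p: np.ndarray | float,
) -> tuple[np.ndarray, dict[str, int]]:
    """Mutate a sequence, returning the read codes and exact tallies.

    Model, per template base: deleted with probability del_p (possibly
    position-dependent); otherwise emitted, substituted with probability
    sub_rate; after each emitted base, one random base is inserted with
    probability ins_rate.
    """
    n = codes.size
    keep = rng.random(n) >= del_p
    del_bases = int(n - keep.sum())
    padded = np.concatenate(([True], keep, [True]))
    del_events = int((np.diff(padded.astype(np.int8)) == -1).sum())

    kept = codes[keep].copy()
    nk = kept.size
    sub_mask = rng.random(nk) < sub_rate
    mismatches = int(sub_mask.sum())
    kept[sub_mask] = (
        kept[sub_mask] + rng.integers(1, 4, size=mismatches).astype(np.uint8)
    ) % 4

    ins_mask = rng.random(nk) < ins_rate
    ins_positions = np.flatnonzero(ins_mask)
    ins_bases = int(ins_positions.size)
    if ins_bases:
        values = rng.integers(0, 4, size=ins_bases).astype(np.uint8)
        read = np.insert(kept, ins_positions + 1, values)
    else:
        read = kept
    tallies = {
        "matches": nk - mismatches,
        "mismatches": mismatches,
        "ins_bases": ins_bases,
        "del_bases": del_bases,
        "ins_events": ins_bases,  # single-base inserts, one per slot
        "del_events": del_events,
    }
    return read, tallies


def simulate_reads(
    reference: Sequence[ReadRecord],
    depth: float,
    length_model: LengthModel = LengthModel(),
    errors: ErrorProfile = ErrorProfile(),
    seed: int = 0,
) -> tuple[list[ReadRecord], list[AlignmentBlock]]:
    """Draw reads from uniform origins until total bases >= depth x
    reference length; return reads plus the truth PAF blocks recording
    each read's error-free origin with exact tallies.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    chrom_codes = [_encode(r.sequence) for r in reference]
    chrom_runs = [_run_length_at(c) for c in chrom_codes]
    lens = np.array([len(r) for r in reference], dtype=np.int64)
    weights = lens / lens.sum()
    quota = depth * lens.sum()

    reads: list[ReadRecord] = []
    blocks: list[AlignmentBlock] = []
    total = 0
    i = 0
    while total < quota:
        L = int(length_model.sample(rng, 1)[0])
        ci = int(rng.choice(len(reference), p=weights))
        clen = int(lens[ci])
        L = min(L, clen)
        start = int(rng.integers(0, clen - L + 1))
        template = chrom_codes[ci][start : start + L]
        if errors.hp_del_boost > 1.0:
            runs = chrom_runs[ci][start : start + L]
            del_p = np.where(
                runs >= errors.hp_min,
                min(errors.del_rate * errors.hp_del_boost, 0.95),
                errors.del_rate,
            )
        else:
            del_p = errors.del_rate
        strand = "+" if rng.random() < 0.5 else "-"
        oriented = template if strand == "+" else _revcomp_codes(template)
        read_codes, t = _apply_errors(
            oriented, rng, errors.sub_rate, errors.ins_rate, del_p
        )
        if read_codes.size == 0:
            continue
        rid = f"read{i}"
        i += 1
        reads.append(ReadRecord(rid, _decode(read_codes), "I" * read_codes.size))
        block = AlignmentBlock(
            rid, read_codes.size, 0, read_codes.size, strand,
            reference[ci].id, clen, start, start + L,
            t["matches"], t["mismatches"], t["ins_bases"], t["del_bases"],
            t["ins_events"], t["del_events"],
        )
        block.validate()
        blocks.append(block)
        total += read_codes.size
    return reads, blocks


def corrupt_assembly(
    reference: Sequence[ReadRecord],
    snp_rate: float = 0.0,
    indel_rate: float = 0.0,
    events: Sequence[EventSpec | str] = (),
    drop_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[ReadRecord], SimTruth, list[AlignmentBlock]]:
    """Build an assembly-like contig set from a reference with known
    corruption: point SNPs, single-base indel events, dropped segments,
    and structural misassemblies.

    Each structural event becomes a dedicated chimeric contig made of
    two segments carved off chromosome backbones, so the expected
    misassembly classification under the evaluation rules is exact:
    translocation joins two chromosomes, inversion joins a segment to
    its reverse-complemented neighbour, relocation skips ``gap``
    reference bases between adjacent segments.
    """
    events = [EventSpec(e) if isinstance(e, str) else e for e in events]
    rng = np.random.default_rng(seed)
    chrom_codes = {r.id: _encode(r.sequence) for r in reference}
    chrom_len = {r.id: len(r) for r in reference}
    # remaining backbone interval per chromosome; events carve from the tail
    remaining = {r.id: [0, len(r)] for r in reference}
    ids = [r.id for r in reference]

    # plan: list of contigs; each contig is a list of
    # (chrom, tstart, tend, strand) segments in query order
    plan: list[list[tuple[str, int, int, str]]] = []
    breakpoint_kinds: list[str] = []  # kind of the junction in plan order

    def carve(chrom: str, size: int) -> tuple[int, int]:
        lo, hi = remaining[chrom]
        if hi - lo - size < 1000:  # keep at least a 1 kb backbone
            raise ValueError(
                f"{chrom}: not enough sequence to carve a {size} b event "
                "segment without overlapping another event"
            )
        remaining[chrom][1] = hi - size
        return hi - size, hi

    for j, ev in enumerate(events):
        if ev.kind == "translocation":
            ca, cb = ids[j % len(ids)], ids[(j + 1) % len(ids)]
            if ca == cb:
                raise ValueError("translocation needs two chromosomes")
            s1 = carve(ca, ev.size)
            s2 = carve(cb, ev.size)
            plan.append([(ca, *s1, "+"), (cb, *s2, "+")])
        elif ev.kind == "inversion":
            c = ids[j % len(ids)]
            s2 = carve(c, ev.size)
            s1 = carve(c, ev.size)
            plan.append([(c, *s1, "+"), (c, *s2, "-")])
        else:  # relocation
            c = ids[j % len(ids)]
            s2 = carve(c, ev.size)
            remaining[c][1] -= ev.gap  # skipped reference bases at the junction
            s1 = carve(c, ev.size)
            plan.append([(c, *s1, "+"), (c, *s2, "+")])
        breakpoint_kinds.append(ev.kind)

    # backbones, with an optional central drop on each chromosome
    dropped = 0
    for r in reference:
        lo, hi = remaining[r.id]
        if drop_fraction > 0:
            d = int(drop_fraction * (hi - lo))
            mid = (lo + hi) // 2
            a, b = mid - d // 2, mid - d // 2 + d
            dropped += d
            plan.append([(r.id, lo, a, "+")])
            plan.append([(r.id, b, hi, "+")])
        else:
            plan.append([(r.id, lo, hi, "+")])

    contigs: list[ReadRecord] = []
    blocks: list[AlignmentBlock] = []
    truth_bps: list[tuple[str, int, str]] = []
    snps = indel_events = 0

    for idx, segments in enumerate(plan):
        cid = f"contig{idx + 1}"
        parts: list[np.ndarray] = []
        seg_tallies = []
        for chrom, ts, te, strand in segments:
            template = chrom_codes[chrom][ts:te]
            oriented = template if strand == "+" else _revcomp_codes(template)
            mutated, t = _apply_errors(
                oriented, rng, snp_rate, indel_rate / 2.0, indel_rate / 2.0
            )
            parts.append(mutated)
            seg_tallies.append((chrom, ts, te, strand, mutated.size, t))
            snps += t["mismatches"]
            indel_events += t["ins_events"] + t["del_events"]
        seq = np.concatenate(parts)
        contigs.append(ReadRecord(cid, _decode(seq)))
        qoff = 0
        for k, (chrom, ts, te, strand, qlen, t) in enumerate(seg_tallies):
            block = AlignmentBlock(
                cid, seq.size, qoff, qoff + qlen, strand,
                chrom, chrom_len[chrom], ts, te,
                t["matches"], t["mismatches"], t["ins_bases"], t["del_bases"],
                t["ins_events"], t["del_events"],
            )
            block.validate()
            blocks.append(block)
            qoff += qlen
            if k < len(seg_tallies) - 1 and idx < len(breakpoint_kinds):
                truth_bps.append((cid, qoff, breakpoint_kinds[idx]))

    truth = SimTruth(
        snps=snps,
        indel_events=indel_events,
        breakpoints=truth_bps,
        dropped_bases=dropped,
    )
    return contigs, truth, blocks
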