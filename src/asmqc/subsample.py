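"""Depth-targeted read subsampling, plain and length-distribution matched.

Two selection procedures:

* ``random_subsample`` draws reads in seeded uniform-random order until a
  base quota (target depth x genome size) is met — the usual way a deeper
  dataset is cut down to a comparison depth.

* ``emulate_subsample`` additionally matches a target read-length
  histogram, so that a subsample of one platform's reads emulates both
  the depth *and* the length distribution of another platform's dataset.
  Per-bin base quotas are filled from the longest bins first (long reads
  are scarcest); the boundary read of each bin is kept only when its
  overshoot is no larger than the shortfall it closes. Any remaining
  global shortfall (from exhausted or under-filled bins) is topped up
  one read at a time from whichever bin is furthest below its target,
  until the global quota is met or the source runs out.

Both are deterministic given the seed; there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .readstats import LengthProfile, length_histogram
from .seqio import ReadRecord


@dataclass(frozen=True)
class SubsampleSpec:
    target_depth: float
    genome_size: int
    seed: int
    bin_width: int = 1000
    target_profile: LengthProfile | None = None

    def __post_init__(self) -> None:
        if self.target_depth <= 0:
            raise ValueError("target_depth must be positive")
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")

    @property
    def quota(self) -> int:
        return int(round(self.target_depth * self.genome_size))


@dataclass
class MatchReport:
    """How well an emulated subsample hit its per-bin base quotas."""

    bin_width: int
    target_fraction: np.ndarray
    achieved_fraction: np.ndarray
    achieved_bases: int
    quota: int
    exhausted: bool = False

    @property
    def l1_distance(self) -> float:
        """Sum over bins of |achieved - target| base fractions."""
        return float(np.abs(self.achieved_fraction - self.target_fraction).sum())

    def to_dict(self) -> dict:
        return {
            "bin_width": self.bin_width,
            "target_fraction": self.target_fraction.tolist(),
            "achieved_fraction": self.achieved_fraction.tolist(),
            "achieved_bases": self.achieved_bases,
            "quota": self.quota,
            "exhausted": self.exhausted,
            "l1_distance": self.l1_distance,
        }


def random_subsample(
    reads: Sequence[ReadRecord], spec: SubsampleSpec
) -> list[ReadRecord]:
    """Seeded uniform subsample to a base quota.

    Reads are taken in a seeded random order without replacement, stopping
    at the first read whose inclusion reaches the quota; the result is
    returned in source order. The achieved total differs from the quota by
    less than the longest selected read.
    """
    quota = spec.quota
    total = sum(len(r) for r in reads)
    if total < quota:
        raise ValueError(
            f"source holds {total} bases (depth "
            f"{total / spec.genome_size:.2f}X), quota is {quota}"
        )
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(reads))
    chosen: list[int] = []
    acc = 0
    for i in order:
        chosen.append(int(i))
        acc += len(reads[i])
        if acc >= quota:
            break
    return [reads[i] for i in sorted(chosen)]


def emulate_subsample(
    source: Sequence[ReadRecord], spec: SubsampleSpec
) -> tuple[list[ReadRecord], MatchReport]:
    """Subsample matching both a depth and a read-length histogram."""
    if spec.target_profile is None:
        raise ValueError("emulate_subsample requires spec.target_profile")
    quota = spec.quota
    target = spec.target_profile
    w = target.bin_width

    lengths = np.array([len(r) for r in source], dtype=np.int64)
    bin_of = lengths // w
    nbins = max(int(bin_of.max()) + 1, target.n_bins)

    tfrac = np.zeros(nbins)
    tfrac[: target.n_bins] = target.base_fraction_per_bin

    rng = np.random.default_rng(spec.seed)
    # per-bin seeded-shuffled queues of source read indices
    queues: dict[int, list[int]] = {}
    for b in range(nbins):
        idx = np.flatnonzero(bin_of == b)
        if idx.size:
            queues[b] = [int(i) for i in rng.permutation(idx)]

    bin_quota = tfrac * quota
    taken_bases = np.zeros(nbins)
    chosen: list[int] = []
    achieved = 0

    def take(b: int) -> None:
        nonlocal achieved
        i = queues[b].pop()
        chosen.append(i)
        taken_bases[b] += lengths[i]
        achieved += int(lengths[i])

    def fill_bin(b: int, goal: float) -> None:
        # closest approach: the boundary read is kept only when its
        # overshoot does not exceed the shortfall it closes
        q = queues.get(b)
        while q and taken_bases[b] < goal:
            L = int(lengths[q[-1]])
            if taken_bases[b] + L - goal > goal - taken_bases[b]:
                break
            take(b)

    for b in sorted(range(nbins), reverse=True):
        fill_bin(b, bin_quota[b])

    # top up any global shortfall from the most under-target open bin
    while achieved < quota:
        open_bins = [b for b, q in queues.items() if q]
        if not open_bins:
            break
        deficit = bin_quota[np.array(open_bins)] - taken_bases[np.array(open_bins)]
        take(open_bins[int(np.argmax(deficit))])

    afrac = (
        taken_bases / taken_bases.sum() if achieved else np.zeros(nbins)
    )
    report = MatchReport(
        bin_width=w,
        target_fraction=tfrac,
        achieved_fraction=afrac,
        achieved_bases=achieved,
        quota=quota,
        exhausted=achieved < quota,
    )
    return [source[i] for i in sorted(chosen)], report
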