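"""Read-set summary statistics and binned length histograms.

Profiles a set of long reads the way sequencing datasets are usually
tabulated: total bases, read count, mean and longest read, N50, and
fold-coverage depth relative to a genome size. Length histograms count
both reads and bases per fixed-width bin, the quantity that
distribution-matched subsampling targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import ReadRecord


@dataclass(frozen=True)
class ReadSetProfile:
    total_bases: int
    n_reads: int
    mean_len: float
    longest: int
    n50: int
    genome_size: int
    depth: float

    @property
    def depth_label(self) -> str:
        """Depth rounded half-up to an integer fold, e.g. '31X'."""
        return f"{int(np.floor(self.depth + 0.5))}X"


@dataclass(frozen=True)
class LengthProfile:
    """Binned read-length histogram; bin i covers [i*w, (i+1)*w)."""

    bin_width: int
    reads_per_bin: np.ndarray
    bases_per_bin: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.reads_per_bin)

    @property
    def total_bases(self) -> int:
        return int(self.bases_per_bin.sum())

    @property
    def base_fraction_per_bin(self) -> np.ndarray:
        return self.bases_per_bin / self.bases_per_bin.sum()

    def to_dict(self) -> dict:
        return {
            "bin_width": self.bin_width,
            "reads_per_bin": [int(x) for x in self.reads_per_bin],
            "bases_per_bin": [int(x) for x in self.bases_per_bin],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LengthProfile":
        return cls(
            int(d["bin_width"]),
            np.asarray(d["reads_per_bin"], dtype=np.int64),
            np.asarray(d["bases_per_bin"], dtype=np.int64),
        )


def n50(lengths: Sequence[int]) -> int:
    """N50: the length at which the descending cumulative sum first
    reaches at least half of the total.
    """
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("n50 of an empty length set is undefined")
    if (arr < 1).any():
        raise ValueError("all lengths must be >= 1")
    arr = np.sort(arr)[::-1]
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, csum[-1] / 2.0))
    return int(arr[idx])


def profile(reads: Sequence[ReadRecord], genome_size: int) -> ReadSetProfile:
    """Summary statistics for a read set at a given genome size."""
    if not reads:
        raise ValueError("cannot profile an empty read set")
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    lengths = np.array([len(r) for r in reads], dtype=np.int64)
    total = int(lengths.sum())
    return ReadSetProfile(
        total_bases=total,
        n_reads=len(reads),
        mean_len=total / len(reads),
        longest=int(lengths.max()),
        n50=n50(lengths),
        genome_size=genome_size,
        depth=total / genome_size,
    )


def length_histogram(
    reads: Sequence[ReadRecord] | Sequence[int], bin_width: int = 1000
) -> LengthProfile:
    """Bin read lengths at fixed width; a read of length L goes to bin
    floor(L / bin_width). Trailing empty bins are trimmed. Accepts either
    ReadRecords or raw lengths.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if len(reads) == 0:
        raise ValueError("cannot histogram an empty read set")
    first = reads[0]
    lengths = np.asarray(
        [len(r) for r in reads] if isinstance(first, ReadRecord) else reads,
        dtype=np.int64,
    )
    idx = lengths // bin_width
    nbins = int(idx.max()) + 1
    reads_per_bin = np.bincount(idx, minlength=nbins)
    bases_per_bin = np.bincount(idx, weights=lengths, minlength=nbins).astype(np.int64)
    return LengthProfile(bin_width, reads_per_bin, bases_per_bin)
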