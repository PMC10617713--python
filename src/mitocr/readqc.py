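"""Read filtering and summary statistics for long-read QC.

Mean read quality is computed in error-probability space (the convention of
long-read QC tools): per-base Phred scores are converted to error
probabilities, averaged, and converted back. Filtering thresholds are
inclusive on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqio import Read


@dataclass
class ReadStats:
    """Summary statistics over a read set (Table-1-style rows)."""

    total_reads: int
    total_bases: int
    mean_length: float
    n50: int
    min_length: int
    max_length: int

    def as_rows(self) -> list[dict]:
        return [
            {"statistic": "Number of reads", "value": self.total_reads},
            {"statistic": "Total sequence yield (bp)", "value": self.total_bases},
            {"statistic": "Average read length (bp)", "value": round(self.mean_length, 1)},
            {"statistic": "N50 read length (bp)", "value": self.n50},
            {"statistic": "Minimum read length (bp)", "value": self.min_length},
            {"statistic": "Maximum read length (bp)", "value": self.max_length},
        ]


def mean_quality(read: Read) -> float:
    """Phred-scaled mean of per-base error probabilities.

    ``-10 * log10(mean(10^(-q/10)))`` — a read of all-Q10 bases scores
    exactly 10; mixing high and low bases is dominated by the low ones.
    """
    if read.quality is None:
        raise ValueError(f"read {read.id!r} has no quality scores")
    if len(read.quality) == 0:
        raise ValueError(f"read {read.id!r} is empty")
    p = np.power(10.0, -read.quality / 10.0)
    return float(-10.0 * np.log10(p.mean()))


def filter_reads(
    reads: Iterable[Read],
    min_quality: float = 10.0,
    min_length: int = 1000,
    max_length: int | None = None,
) -> list[Read]:
    """Retain reads with mean quality >= min_quality and length in bounds.

    Both bounds are inclusive. Filtering is idempotent.
    """
    if min_quality < 0 or min_length < 0:
        raise ValueError("thresholds must be >= 0")
    out = []
    for r in reads:
        if len(r) < min_length:
            continue
        if max_length is not None and len(r) > max_length:
            continue
        if mean_quality(r) >= min_quality - 1e-9:  # inclusive despite float round-off
            out.append(r)
    return out


def read_stats(reads: Sequence[Read]) -> ReadStats:
    """Compute count/yield/mean/N50/min/max over a non-empty read set.

    N50 is the largest read length L such that reads of length >= L together
    contain at least half of all sequenced bases; it is always one of the
    observed lengths.
    """
    if not reads:
        raise ValueError("read_stats requires at least one read")
    lengths = np.sort(np.array([len(r) for r in reads]))[::-1]
    total = int(lengths.sum())
    cum = np.cumsum(lengths)
    n50 = int(lengths[np.searchsorted(cum, total / 2.0)])
    return ReadStats(
        total_reads=len(lengths),
        total_bases=total,
        mean_length=float(lengths.mean()),
        n50=n50,
        min_length=int(lengths[-1]),
        max_length=int(lengths[0]),
    )
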