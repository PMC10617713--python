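"""In-silico PCR: primer-site scanning on reads and product-length histograms.

Primer matching is substitution-only (Hamming distance, default up to 3
mismatches, no indels inside the primer site), so an exact brute-force oracle
is feasible; indel-tolerant anchoring for raw-read CR extraction lives in
:mod:`mitocr.crres` and is intentionally a different policy.

The product-length histogram uses 100 bp bins whose edges are congruent to
51 modulo 100, so bins read "...6751-6850, 6851-6950..." in inclusive label
terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqio import Read, revcomp


@dataclass
class Primer:
    name: str
    sequence: str  # 5' -> 3'

    def __post_init__(self) -> None:
        if len(self.sequence) < 10:
            raise ValueError(f"primer {self.name!r} shorter than 10 bases")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"primer {self.name!r} has ambiguous bases")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AmpliconHit:
    """One primer-delimited product on one read (0-based half-open)."""

    read_id: str
    start: int
    end: int
    strand: str  # strand of the forward primer on the read
    length: int
    mismatches_fwd: int
    mismatches_rev: int


@dataclass
class LengthHistogram:
    bin_width: int
    edges: np.ndarray  # left edges (0-based half-open bins: [edge, edge+width))
    counts: np.ndarray

    def labels(self) -> list[str]:
        return [f"{int(e)}-{int(e) + self.bin_width - 1}" for e in self.edges]


def _hamming_scan(seq_codes: np.ndarray, primer_codes: np.ndarray) -> np.ndarray:
    """Mismatch count of the primer at every start position (vectorized)."""
    n, m = len(seq_codes), len(primer_codes)
    if n < m:
        return np.empty(0, dtype=np.int64)
    mism = np.zeros(n - m + 1, dtype=np.int64)
    for j in range(m):
        mism += seq_codes[j : j + n - m + 1] != primer_codes[j]
    return mism


def _codes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8)


def find_primer_sites(
    sequence: str, primer: Primer, max_mismatch: int = 3
) -> list[tuple[int, str, int]]:
    """All (position, strand, mismatches) where the primer or its reverse
    complement matches with Hamming distance <= max_mismatch."""
    if max_mismatch >= len(primer) / 2:
        raise ValueError("max_mismatch must be < half the primer length")
    sc = _codes(sequence)
    hits = []
    for strand, pseq in (("+", primer.sequence), ("-", revcomp(primer.sequence))):
        mism = _hamming_scan(sc, _codes(pseq))
        for pos in np.nonzero(mism <= max_mismatch)[0]:
            hits.append((int(pos), strand, int(mism[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def amplicon_lengths(
    reads: Iterable[Read],
    forward: Primer,
    reverse: Primer,
    max_mismatch: int = 3,
    min_len: int = 100,
    max_len: int = 50000,
) -> list[AmpliconHit]:
    """Primer-delimited product lengths per read, primer sites included.

    A product is a convergently oriented pair: forward primer on one strand
    and reverse primer facing it downstream. Nested candidate pairs resolve
    to the innermost product (mutually nearest sites), mimicking the
    dominance of the shortest PCR product.
    """
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    out = []
    for read in reads:
        f_sites = find_primer_sites(read.sequence, forward, max_mismatch)
        r_sites = find_primer_sites(read.sequence, reverse, max_mismatch)
        # orientation 1: forward on +, reverse on - (product left->right)
        out.extend(
            _pair_convergent(read.id, f_sites, r_sites, len(forward), len(reverse),
                             "+", min_len, max_len)
        )
        # orientation 2: read is the bottom strand -- forward on -, reverse on +
        out.extend(
            _pair_convergent(read.id, r_sites, f_sites, len(reverse), len(forward),
                             "-", min_len, max_len, swap=True)
        )
    return out


def _pair_convergent(read_id, left_sites, right_sites, llen, rlen, fwd_strand,
                     min_len, max_len, swap=False):
    """Mutually-nearest convergent pairs: left primer on '+' before right
    primer on '-'. With ``swap`` the roles of forward/reverse are exchanged
    (read sequenced from the bottom strand)."""
    lefts = [h for h in left_sites if h[1] == "+"]
    rights = [h for h in right_sites if h[1] == "-"]
    hits = []
    for li, (lp, _s, lm) in enumerate(lefts):
        cands = [r for r in rights if r[0] >= lp + llen]
        if not cands:
            continue
        rp, _rs, rm = min(cands, key=lambda r: r[0])
        # mutual nearest: this right site's closest left must be lp
        closer_lefts = [l for l in lefts if lp < l[0] and l[0] + llen <= rp]
        if closer_lefts:
            continue
        end = rp + rlen
        length = end - lp
        if not (min_len <= length <= max_len):
            continue
        mf, mr = (rm, lm) if swap else (lm, rm)
        hits.append(AmpliconHit(read_id, lp, end, fwd_strand, length, mf, mr))
    return hits


def build_histogram(lengths: Sequence[int], bin_width: int = 100) -> LengthHistogram:
    """Histogram with bin edges congruent to 51 (mod bin_width is anchored the
    same way: the bin containing x starts at 51 + bin_width * k)."""
    if len(lengths) == 0:
        raise ValueError("no lengths to histogram")
    arr = np.asarray(lengths, dtype=np.int64)
    anchor = 51
    k = (arr - anchor) // bin_width
    kmin, kmax = int(k.min()), int(k.max())
    edges = anchor + bin_width * np.arange(kmin, kmax + 1)
    counts = np.bincount(k - kmin, minlength=kmax - kmin + 1)
    return LengthHistogram(bin_width, edges, counts)


def modal_bin(hist: LengthHistogram) -> tuple[int, int, int]:
    """(low, high, count) of the fullest bin, inclusive label terms; ties
    break toward the smaller bin."""
    i = int(np.argmax(hist.counts))  # argmax takes the first (smallest) on ties
    low = int(hist.edges[i])
    return low, low + hist.bin_width - 1, int(hist.counts[i])


def cr_tip_primers(cr_sequence: str, k: int = 25) -> tuple[Primer, Primer]:
    """Operationalize "the 5' and 3' tip of the CR" as its terminal k-mers.

    The forward primer is the first k bases of the CR; the reverse primer is
    the reverse complement of the last k bases, so the (primer-inclusive)
    product length of a perfect template equals the CR length.
    """
    if len(cr_sequence) < 2 * k:
        raise ValueError("CR shorter than two primer lengths")
    return (
        Primer("CR_tip5_F", cr_sequence[:k]),
        Primer("CR_tip3_R", revcomp(cr_sequence[-k:])),
    )
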