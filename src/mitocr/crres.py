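"""Resolve the control region from long reads.

Stages: (1) extract reads spanning the whole CR by locating two unique
anchor sequences drawn from the flanking coding sequence (edit-distance
matching, tolerant of raw-read indels — intentionally looser than the
Hamming rule used for in-silico PCR); (2) decompose each spanning read's CR
into motif arrays and take per-read copy counts; (3) per-motif modal counts
across reads; (4) reconstruct a consensus CR from a representative read
(counts equal to the modes, best mean quality) polished by majority vote —
per-phase voting across repeat copies, pairwise-alignment voting for unique
segments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np

from .readqc import mean_quality
from .repeats import Decomposition, Motif, RepeatArray, UniqueSegment, decompose
from .seqio import Read, revcomp, rotate

DEFAULT_ANCHOR_LEN = 25
DEFAULT_ANCHOR_MISMATCH = 5


@dataclass
class SpanningRead:
    """A read containing both CR anchors, re-oriented so the CR is on plus."""

    read_id: str
    sequence: str  # plus-oriented read sequence
    cr_start: int
    cr_end: int
    anchor_mismatches: tuple[int, int]
    mean_q: float
    flipped: bool = False
    copy_estimates: dict[str, int] = field(default_factory=dict)
    decomposition: Decomposition | None = None

    @property
    def cr_sequence(self) -> str:
        return self.sequence[self.cr_start : self.cr_end]


@dataclass
class CopyNumberEstimate:
    modal_counts: dict[str, int]
    support: dict[str, float]
    length_estimate: int


def cr_anchors(genome_sequence: str, cr_interval: tuple[int, int],
               k: int = DEFAULT_ANCHOR_LEN) -> tuple[str, str]:
    """Unique anchors from the coding sequence immediately flanking the CR."""
    s, e = cr_interval
    doubled = genome_sequence + genome_sequence
    return doubled[s - k : s], doubled[e : e + k]


def _best_hit(anchor: str, sequence: str, max_mismatch: int):
    res = edlib.align(anchor, sequence, mode="HW", task="locations", k=max_mismatch)
    if res["editDistance"] == -1:
        return None
    return res["editDistance"], res["locations"]


def extract_spanning_reads(
    reads: list[Read],
    anchor5: str,
    anchor3: str,
    max_mismatch: int = DEFAULT_ANCHOR_MISMATCH,
) -> list[SpanningRead]:
    """Reads containing both anchors convergently; minus-strand reads are
    reverse-complemented so every CR is reported in plus orientation."""
    if len(anchor5) < 20 or len(anchor3) < 20:
        raise ValueError("anchors must be at least 20 bp")
    if anchor5 in anchor3 or anchor3 in anchor5:
        raise ValueError("anchors overlap each other")
    out = []
    for read in reads:
        best = None
        for flipped, seq in ((False, read.sequence), (True, revcomp(read.sequence))):
            h5 = _best_hit(anchor5, seq, max_mismatch)
            h3 = _best_hit(anchor3, seq, max_mismatch)
            if h5 is None or h3 is None:
                continue
            d5, loc5 = h5
            d3, loc3 = h3
            # CR lies between the end of the 5' anchor and the start of the
            # 3' anchor; take the leftmost 5' hit and the rightmost 3' hit
            end5 = min(l[1] + 1 for l in loc5)
            start3 = max(l[0] for l in loc3)
            if end5 >= start3:
                continue
            cand = (d5 + d3, flipped, seq, end5, start3, d5, d3)
            if best is None or cand[0] < best[0]:
                best = cand
        if best is None:
            continue
        _, flipped, seq, end5, start3, d5, d3 = best
        mq = mean_quality(read) if read.quality is not None else 0.0
        out.append(
            SpanningRead(read.id, seq, end5, start3, (d5, d3), mq, flipped)
        )
    return out


def per_read_copy_numbers(
    spanning: SpanningRead, motifs: list[Motif], max_divergence: float = 0.2
) -> dict[str, int]:
    """Decompose the read's CR interval and count copies per motif."""
    cr = spanning.cr_sequence
    if not cr:
        spanning.copy_estimates = {m.id: 0 for m in motifs}
        return spanning.copy_estimates
    dec = decompose(cr, motifs, max_divergence)
    spanning.decomposition = dec
    counts = dec.copy_counts()
    _bridge_gaps(dec, motifs, counts, max_divergence)
    spanning.copy_estimates = {m.id: counts.get(m.id, 0) for m in motifs}
    return spanning.copy_estimates


def _bridge_gaps(
    dec: Decomposition, motifs: list[Motif], counts: dict[str, int], max_divergence: float
) -> None:
    """Credit short unique gaps flanked by arrays of the same motif.

    On raw reads an array occasionally fragments when consecutive copies
    exceed the per-copy tolerance; the dropped copies sit in a gap whose
    length is close to a multiple of the period. Counting them keeps
    per-read estimates unbiased without loosening the per-copy tolerance.
    """
    periods = {m.id: m.period for m in motifs}
    segs = dec.segments
    for i in range(1, len(segs) - 1):
        seg = segs[i]
        if isinstance(seg, RepeatArray):
            continue
        left, right = segs[i - 1], segs[i + 1]
        if not (
            isinstance(left, RepeatArray)
            and isinstance(right, RepeatArray)
            and left.motif_id == right.motif_id
        ):
            continue
        p = periods[left.motif_id]
        g = seg.end - seg.start
        k = int(round(g / p))
        # only short gaps (a few dropped copies) are credited; long gaps are
        # genuine unique sequence even when flanked by one motif
        if 1 <= k <= 4 and abs(g - k * p) <= max(3, max_divergence * k * p):
            counts[left.motif_id] = counts.get(left.motif_id, 0) + k


def copy_number_mode(
    spanning_reads: list[SpanningRead], motifs: list[Motif], min_reads: int = 10
) -> CopyNumberEstimate:
    """Per-motif modal copy count across reads; ties break toward the
    smaller count. The CR length estimate combines modal counts with the
    unique-segment lengths of a representative read's decomposition."""
    estimated = [s for s in spanning_reads if s.copy_estimates]
    if len(estimated) < min_reads:
        raise ValueError(f"need at least {min_reads} spanning reads, got {len(estimated)}")
    modal, support = {}, {}
    for m in motifs:
        counter = Counter(s.copy_estimates[m.id] for s in estimated)
        top = max(counter.values())
        modal[m.id] = min(c for c, k in counter.items() if k == top)
        support[m.id] = top / len(estimated)
    rep = _representative(estimated, modal)
    unique_len = sum(
        u.end - u.start for u in rep.decomposition.unique_segments
    ) if rep.decomposition else 0
    length = unique_len + sum(modal[m.id] * m.period for m in motifs)
    return CopyNumberEstimate(modal, support, length)


def _l1(est: dict[str, int], modal: dict[str, int]) -> int:
    return sum(abs(est[k] - v) for k, v in modal.items())


def _representative(spanning: list[SpanningRead], modal: dict[str, int]) -> SpanningRead:
    matching = [s for s in spanning if s.copy_estimates == modal]
    pool = matching if matching else spanning
    if not matching:
        pool = sorted(pool, key=lambda s: (_l1(s.copy_estimates, modal), -s.mean_q, s.read_id))
        return pool[0]
    return sorted(pool, key=lambda s: (-s.mean_q, s.read_id))[0]


# ---------------------------------------------------------------------------
# Consensus polishing
# ---------------------------------------------------------------------------


def polish_consensus(template: str, others: list[str], rounds: int = 2) -> str:
    """Majority-vote polish of a template by pairwise alignment of supporting
    sequences (one vote per sequence per template column, plus insertion
    votes between columns). The template itself casts one vote."""
    cur = template
    for _ in range(rounds):
        nxt = _polish_once(cur, others)
        if nxt == cur:
            break
        cur = nxt
    return cur


_DEL = "-"


def _polish_once(template: str, others: list[str]) -> str:
    n = len(template)
    base_votes: list[Counter] = [Counter({template[i]: 1}) for i in range(n)]
    ins_votes: list[Counter] = [Counter() for _ in range(n + 1)]
    for other in others:
        res = edlib.align(other, template, mode="NW", task="path")
        t = q = 0
        cigar = res["cigar"]
        num = ""
        for ch in cigar:
            if ch.isdigit():
                num += ch
                continue
            k = int(num)
            num = ""
            if ch in "=X":
                for _ in range(k):
                    base_votes[t][other[q]] += 1
                    t += 1
                    q += 1
            elif ch == "D":  # consumes template only -> other lacks these bases
                for _ in range(k):
                    base_votes[t][_DEL] += 1
                    t += 1
            elif ch == "I":  # consumes other only -> insertion before column t
                ins_votes[t][other[q : q + k]] += 1
                q += k
    quorum = (len(others) + 1) / 2.0
    out = []
    for i in range(n + 1):
        if ins_votes[i]:
            s, k = ins_votes[i].most_common(1)[0]
            if k > quorum:
                out.append(s)
        if i < n:
            b, _k = base_votes[i].most_common(1)[0]
            if b != _DEL:
                out.append(b)
    return "".join(out)


def _clean_copies(arrays: list[tuple[RepeatArray, str]], period: int) -> list[str]:
    """Indel-free copies (length == period) in canonical rotation."""
    out = []
    for arr, seq in arrays:
        if not arr.copy_intervals:
            continue
        for s, e in arr.copy_intervals:
            if e - s == period:
                copy = seq[s - arr.start : e - arr.start]
                out.append(rotate(copy, (period - arr.phase) % period))
    return out


def _majority_motif(copies: list[str], fallback: str) -> str:
    if not copies:
        return fallback
    p = len(fallback)
    mat = np.frombuffer("".join(copies).encode(), dtype=np.uint8).reshape(len(copies), p)
    out = bytearray()
    for j in range(p):
        vals, counts = np.unique(mat[:, j], return_counts=True)
        out.append(int(vals[np.argmax(counts)]))
    return out.decode()


def reconstruct_cr(
    spanning_reads: list[SpanningRead],
    motifs: list[Motif],
    modal_counts: dict[str, int],
    max_support: int = 60,
) -> tuple[str, dict]:
    """Consensus CR: representative read, arrays rebuilt from per-phase
    majority motifs at modal copy numbers, unique segments polished by
    majority over the other mode-matching reads.

    Falls back (flagged) to the read closest in L1 distance on copy counts
    when no read matches the modes exactly.
    """
    estimated = [s for s in spanning_reads if s.decomposition is not None]
    if not estimated:
        raise ValueError("no decomposed spanning reads")
    # restrict to reads whose decomposition is unfragmented (one array per
    # motif): their segment lists are directly comparable slot-by-slot
    simple = [
        s for s in estimated
        if len(s.decomposition.arrays) == len(set(s.decomposition.structure()))
    ]
    pool = [s for s in simple if s.copy_estimates == modal_counts]
    fallback = not pool
    if fallback:
        rep = _representative(simple or estimated, modal_counts)
    else:
        rep = sorted(pool, key=lambda s: (-s.mean_q, s.read_id))[0]
    structure = rep.decomposition.structure()
    # copy counts do not matter for polishing unique segments or motif
    # consensus, so every unfragmented read with the same array layout votes
    peers = [
        s for s in simple
        if s is not rep
        and s.decomposition.structure() == structure
        and [type(seg).__name__ for seg in s.decomposition.segments]
        == [type(seg).__name__ for seg in rep.decomposition.segments]
    ][:max_support]
    motif_by_id = {m.id: m for m in motifs}
    polished_motif: dict[str, str] = {}
    for m in motifs:
        copy_pool = []
        for s in [rep] + peers:
            for arr in s.decomposition.arrays:
                if arr.motif_id == m.id:
                    copy_pool.append((arr, s.decomposition.segment_sequence(arr)))
        polished_motif[m.id] = _majority_motif(
            _clean_copies(copy_pool, m.period), m.consensus
        )
    parts = []
    segs = rep.decomposition.segments
    for idx, seg in enumerate(segs):
        if isinstance(seg, UniqueSegment):
            # fold any trailing-partial bases of the preceding array into
            # this segment: they are genuine sequence the modal-copy emission
            # below does not cover
            start = seg.start
            if idx > 0 and isinstance(segs[idx - 1], RepeatArray):
                prev = segs[idx - 1]
                # a partial counted as a copy is already covered by the modal
                # emission; only fold uncounted tail bases
                if prev.copy_intervals and int(prev.fractional + prev.lead_fraction + 0.5) == 0:
                    start = prev.copy_intervals[-1][1]
            template = rep.decomposition.parent[start : seg.end]
            others = []
            for s in peers:
                oseg = s.decomposition.segments[idx]
                ostart = oseg.start
                if idx > 0 and isinstance(s.decomposition.segments[idx - 1], RepeatArray):
                    oprev = s.decomposition.segments[idx - 1]
                    if oprev.copy_intervals and int(oprev.fractional + oprev.lead_fraction + 0.5) == 0:
                        ostart = oprev.copy_intervals[-1][1]
                others.append(s.decomposition.parent[ostart : oseg.end])
            parts.append(polish_consensus(template, others))
        else:
            m = motif_by_id[seg.motif_id]
            # anchor the frame at the array's left boundary: a leading
            # partial of l bases means the boundary copy starts l bases
            # earlier in motif phase
            lead = int(round(seg.lead_fraction * m.period))
            r = (seg.phase - lead) % m.period
            parts.append(rotate(polished_motif[m.id], r) * modal_counts[m.id])
    assembled = "".join(parts)
    # final round: vote the assembled consensus against whole-CR sequences of
    # the modal-count reads, which aligns copy-to-copy and cleans residual
    # junction wobble and unpolished indels
    voters = [s.cr_sequence for s in (pool if pool else [rep])][: max_support // 2]
    if voters:
        assembled = polish_consensus(assembled, voters, rounds=2)
    info = {
        "representative": rep.read_id,
        "fallback": fallback,
        "supporting_reads": len(peers) + 1,
    }
    return assembled, info
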