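"""Tandem-repeat motif discovery and sequence decomposition.

Discovery works on low-error sequence (an assembly or polished consensus):
for every candidate period p it computes the lag-p self-match profile and
keeps maximal windows whose match fraction reaches the purity threshold,
reporting the smallest period per window (multiples of an accepted period
are rejected) with a per-phase majority-vote consensus in canonical
(lexicographically smallest) rotation.

Decomposition tiles a sequence (assembly or raw read) left to right into
motif arrays and unique segments. Copies are aligned one at a time with
edit distance (edlib), so ONT-like indels are tolerated up to
``max_divergence`` per copy; an array terminates when two consecutive
candidate copies exceed the tolerance. The segments tile the input exactly.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import edlib
import numpy as np

from .seqio import rotate


@dataclass
class Motif:
    id: str
    consensus: str
    period: int = 0

    def __post_init__(self) -> None:
        self.consensus = canonical_rotation(self.consensus)
        self.period = len(self.consensus)


@dataclass
class RepeatArray:
    """A tandem array on a parent sequence.

    ``start``/``end`` include partial copies at either edge; ``fractional``
    is the trailing partial's covered fraction of the period and
    ``lead_fraction`` the leading one's (0 if none). When the tiling frame is
    rotated relative to the array boundary, one true copy appears as a
    leading plus a trailing partial, so the two are counted jointly.
    """

    start: int
    end: int
    motif_id: str
    copies: int
    fractional: float = 0.0
    lead_fraction: float = 0.0
    divergence: float = 0.0
    phase: int = 0  # rotation offset of the first copy relative to the canonical motif
    copy_intervals: list[tuple[int, int]] | None = None  # per integer copy, on the parent


@dataclass
class UniqueSegment:
    start: int
    end: int


@dataclass
class Decomposition:
    """Ordered arrays + unique segments tiling the parent sequence exactly."""

    parent: str
    segments: list[RepeatArray | UniqueSegment] = field(default_factory=list)

    @property
    def arrays(self) -> list[RepeatArray]:
        return [s for s in self.segments if isinstance(s, RepeatArray)]

    @property
    def unique_segments(self) -> list[UniqueSegment]:
        return [s for s in self.segments if isinstance(s, UniqueSegment)]

    def segment_sequence(self, seg: RepeatArray | UniqueSegment) -> str:
        return self.parent[seg.start : seg.end]

    def reconstruct(self) -> str:
        return "".join(self.segment_sequence(s) for s in self.segments)

    def copy_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a in self.arrays:
            out[a.motif_id] = out.get(a.motif_id, 0) + _counted_copies(a)
        return out

    def structure(self) -> tuple[str, ...]:
        return tuple(a.motif_id for a in self.arrays)


def _counted_copies(a: RepeatArray) -> int:
    # a partial counts when edge partials jointly cover >= half the period
    # (rounding half up, so an exactly-half partial counts)
    return a.copies + int(a.fractional + a.lead_fraction + 0.5)


def count_copies(decomposition: Decomposition, motif_id: str) -> int:
    """Total copies of a motif; a trailing partial counts iff it covers
    at least half the period."""
    return decomposition.copy_counts().get(motif_id, 0)


def canonical_rotation(s: str) -> str:
    return min(rotate(s, k) for k in range(len(s)))


# ---------------------------------------------------------------------------
# Discovery
# ---------------------------------------------------------------------------


def _lag_profile(codes: np.ndarray, p: int) -> np.ndarray:
    """Windowed (window = p) fraction of positions matching their +p partner;
    entry i covers positions [i, i+2p)."""
    m = (codes[:-p] == codes[p:]).astype(np.float64)
    if len(m) < p:
        return np.empty(0)
    c = np.cumsum(np.concatenate(([0.0], m)))
    return (c[p:] - c[:-p]) / p


def discover_motifs(
    sequence: str,
    min_period: int = 10,
    max_period: int = 100,
    min_copies: int = 3,
    purity: float = 0.8,
) -> list[Motif]:
    """Find tandem motifs as (period, consensus) pairs, smallest period first
    per repetitive window; motifs are labeled A, B, ... by window position."""
    if len(sequence) <= 2 * min_period:
        raise ValueError("sequence too short for the requested periods")
    codes = np.frombuffer(sequence.encode(), dtype=np.uint8)
    candidates: list[tuple[int, int, int]] = []  # (start, end, period)
    for p in range(min_period, max_period + 1):
        prof = _lag_profile(codes, p)
        if len(prof) == 0:
            continue
        ok = prof >= purity
        if not ok.any():
            continue
        idx = np.nonzero(ok)[0]
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        for a, b in zip(idx[starts], idx[ends]):
            region = (int(a), int(b) + 2 * p)
            if region[1] - region[0] >= min_copies * p:
                candidates.append((region[0], region[1], p))
    # smallest period first; reject periods that are multiples of an accepted
    # one over an overlapping window
    candidates.sort(key=lambda c: (c[2], c[0]))
    accepted: list[tuple[int, int, int]] = []
    for s, e, p in candidates:
        redundant = False
        for s0, e0, p0 in accepted:
            overlap = min(e, e0) - max(s, s0)
            if overlap > 0.5 * min(e - s, e0 - s0) and (p % p0 == 0 or p == p0):
                redundant = True
                break
        if not redundant:
            accepted.append((s, e, p))
    accepted.sort(key=lambda c: c[0])
    found: list[tuple[str, int]] = []  # (consensus, span)
    for s, e, p in accepted:
        cons = _phase_consensus(sequence, s, e, p)
        # reduce to the primitive root so a homopolymer or (XY)n stretch is
        # never reported at an inflated period
        root = (cons + cons).find(cons, 1)
        if root < len(cons):
            cons = cons[:root]
            if len(cons) < min_period:
                continue
        cons = canonical_rotation(cons)
        span = e - s
        # near-duplicate suppression: residual indels in a long array spawn
        # ghost motifs one base off the true period over short windows; keep
        # whichever variant has the larger supporting span
        merged = False
        for i, (c0, span0) in enumerate(found):
            if _rotated_distance(cons, c0) <= 0.25 * min(len(cons), len(c0)):
                if span > span0:
                    found[i] = (cons, span)
                merged = True
                break
        if not merged:
            found.append((cons, span))
    return [Motif(chr(ord("A") + i), c) for i, (c, _sp) in enumerate(found)]


def _rotated_distance(a: str, b: str) -> int:
    """Minimum edit distance between a and any rotation of b."""
    return min(
        edlib.align(a, rotate(b, k), mode="NW")["editDistance"] for k in range(len(b))
    )


def _phase_consensus(sequence: str, start: int, end: int, p: int) -> str:
    codes = np.frombuffer(sequence.encode(), dtype=np.uint8)[start:end]
    out = bytearray()
    for j in range(p):
        col = codes[j::p]
        vals, counts = np.unique(col, return_counts=True)
        out.append(int(vals[np.argmax(counts)]))
    return out.decode()


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------


def _ed(query: str, target: str, mode: str) -> tuple[int, int]:
    """(distance, end-in-target) of the best edlib alignment."""
    res = edlib.align(query, target, mode=mode, task="locations")
    loc = res["locations"][0]
    return res["editDistance"], (loc[1] + 1 if loc[1] is not None else len(target))


class _MotifMatcher:
    """Per-motif machinery: rotation matrix for fast phase picking."""

    def __init__(self, motif: Motif):
        self.motif = motif
        p = motif.period
        c = np.frombuffer(motif.consensus.encode(), dtype=np.uint8)
        self.rotations = np.stack([np.roll(c, -k) for k in range(p)])
        self.rotation_strings = [rotate(motif.consensus, k) for k in range(p)]

    def best_phase(self, window: str) -> int:
        """Rotation minimizing Hamming distance to the window's first period."""
        p = self.motif.period
        w = np.frombuffer(window[:p].encode(), dtype=np.uint8)
        if len(w) < p:
            return 0
        d = (self.rotations != w).sum(axis=1)
        return int(np.argmin(d))


def _periodicity_onset(sequence: str, q: int, p: int) -> int:
    """Refine a candidate array start to where lag-p self-similarity begins.

    The candidate detector fires up to ~p/2 early (its window straddles the
    flank/array boundary); snapping to the onset keeps boundary flank bases
    out of the first copy so copy counts are frame-accurate.
    """
    w = np.frombuffer(sequence[q : q + 3 * p].encode(), dtype=np.uint8)
    if len(w) < 2 * p:
        return q
    m = (w[:-p] == w[p:]).astype(np.int64)
    lim = min(p, len(m) - p)
    c = np.cumsum(np.concatenate(([0], m)))
    sums = c[p : p + lim + 1] - c[: lim + 1]
    slack = max(2, int(round(0.1 * p)))
    best = int(sums.max())
    onset = int(np.nonzero(sums >= best - slack)[0][0])
    return q + onset


def _walk_array(
    sequence: str, start: int, matcher: _MotifMatcher, max_divergence: float,
    floor: int = 0,
) -> RepeatArray | None:
    """Greedy copy-by-copy extension of an array starting near ``start``;
    never extends left of ``floor`` (already-tiled sequence)."""
    p = matcher.motif.period
    tol = max_divergence * p
    n = len(sequence)
    start = _periodicity_onset(sequence, start, p)
    # choose phase by Hamming, refine +-1 by edit distance
    r0 = matcher.best_phase(sequence[start : start + p])
    best = None
    for r in dict.fromkeys([r0, (r0 - 1) % p, (r0 + 1) % p]):
        d, _ = _ed(matcher.rotation_strings[r], sequence[start : start + p + 4], "SHW")
        if best is None or d < best[0]:
            best = (d, r)
    d0, phase = best
    if d0 > tol:
        return None
    P = matcher.rotation_strings[phase]
    pad = max(4, int(np.ceil(tol)))
    copies: list[tuple[int, int, int, bool]] = []  # (start, end, dist, bad)
    cursor = start
    while n - cursor >= p - pad and n - cursor >= p // 2 + 1:
        window = sequence[cursor : cursor + p + pad]
        d, end = _ed(P, window, "SHW")
        if d <= tol:
            copies.append((cursor, cursor + end, d, False))
            cursor += end
        else:
            if n - cursor < p:  # trailing region: leave it to the partial check
                break
            # keep the alignment's end so indel drift inside a divergent copy
            # does not desynchronize the following copies
            end = min(max(end, p - pad), p + pad)
            copies.append((cursor, cursor + end, d, True))
            cursor += end
            if len(copies) >= 2 and copies[-2][3]:
                # two consecutive bad copies terminate the array before them
                cursor = copies[-2][0]
                copies = copies[:-2]
                break
    while copies and copies[-1][3]:  # never end on a divergent copy
        cursor = copies[-1][0]
        copies = copies[:-1]
    if len(copies) < 2:
        return None
    # backward extension: the candidate detector can start mid-array when an
    # indel in the leading copy confuses phase detection; with the phase now
    # fixed, walk back copy-by-copy with length-flexible alignment
    head = copies[0][0]
    while head - floor >= p - pad:
        best_b = None
        for l in range(max(1, p - pad), min(head - floor, p + pad) + 1):
            d = edlib.align(P, sequence[head - l : head], mode="NW")["editDistance"]
            if best_b is None or d < best_b[0]:
                best_b = (d, l)
        if best_b is None or best_b[0] > tol:
            break
        d, l = best_b
        copies.insert(0, (head - l, head, d, False))
        head -= l
    # boundary copies that straddle the array edge can sneak under the
    # tolerance as junk-plus-partial chimeras; drop an edge copy whenever a
    # bare partial explains its window strictly better per aligned base
    while len(copies) > 2 and copies[0][2] > 0 and _edge_chimera(
        P, sequence, copies[0], "lead", max_divergence
    ):
        copies.pop(0)
    while len(copies) > 2 and copies[-1][2] > 0 and _edge_chimera(
        P, sequence, copies[-1], "trail", max_divergence
    ):
        copies.pop()
    # frame micro-shift: when the onset estimate is a base or two off, the
    # whole tiling is consistently shifted; re-anchor on the first copy
    h = copies[0][0]
    best_shift = None
    for delta in range(-3, 4):
        if h + delta < floor or h + delta + p > n:
            continue
        r2 = (phase + delta) % p
        d2 = edlib.align(
            matcher.rotation_strings[r2], sequence[h + delta : h + delta + p], mode="NW"
        )["editDistance"]
        key = (d2, abs(delta), delta)
        if best_shift is None or key < best_shift[0]:
            best_shift = (key, delta, r2, d2)
    if best_shift is not None and best_shift[1] != 0:
        _key, delta, r2, d2 = best_shift
        phase = r2
        P = matcher.rotation_strings[phase]
        copies = [(s + delta, e + delta, d, bad) for s, e, d, bad in copies]
        copies[0] = (copies[0][0], copies[0][1], d2, copies[0][3])
    array_end = copies[-1][1]
    # edge partial copies: longest prefix (trailing) / suffix (leading) of
    # the phased motif still within tolerance, indel-aware
    trail_len = _partial_len(
        P, sequence[array_end : array_end + p - 1], max_divergence, prefix=True
    )
    lead_len = _partial_len(
        P, sequence[max(floor, copies[0][0] - (p - 1)) : copies[0][0]], max_divergence,
        prefix=False,
    )
    # edge copies are frame-ambiguous against flanking sequence, so the
    # divergence estimate uses interior copies only
    interior = copies[1:-1] if len(copies) > 2 else copies
    div = float(np.mean([c[2] for c in interior]) / p)
    return RepeatArray(
        start=copies[0][0] - lead_len,
        end=array_end + trail_len,
        motif_id=matcher.motif.id,
        copies=len(copies),
        fractional=trail_len / p,
        lead_fraction=lead_len / p,
        divergence=div,
        phase=phase,
        copy_intervals=[(c[0], c[1]) for c in copies],
    )


def _edge_chimera(
    P: str, sequence: str, copy: tuple, side: str, max_divergence: float
) -> bool:
    """True when an edge copy is really flank junk glued to a partial copy:
    its best partial match leaves a complement that mismatches like random
    sequence (error fraction > 0.5), which genuine noisy copies never show."""
    c_start, c_end, _d_full, _bad = copy
    p = len(P)
    window = sequence[c_start:c_end]
    span = len(window)
    if side == "lead":  # partial = motif suffix at the window's right edge
        l_p = _partial_len(P, window, max_divergence, prefix=False)
        comp_q, comp_t = P[: p - l_p], window[: span - l_p]
    else:  # partial = motif prefix at the window's left edge
        l_p = _partial_len(P, window, max_divergence, prefix=True)
        comp_q, comp_t = P[l_p:], window[l_p:]
    if l_p == 0 or l_p >= span or not comp_t:
        return False
    d_c = edlib.align(comp_q, comp_t, mode="NW")["editDistance"]
    # genuine noisy complements sit near the read error rate; junk near 75%
    return d_c > 0.34 * max(len(comp_q), len(comp_t))


def _partial_len(P: str, window: str, max_divergence: float, prefix: bool) -> int:
    """Longest partial-copy match at an array edge: a prefix of the phased
    motif extending right, or a suffix extending left."""
    best, best_score = 0, 0.0
    for l in range(1, len(window) + 1):
        if prefix:
            q, t = P[:l], window[:l]
        else:
            q, t = P[-l:], window[-l:]
        d = edlib.align(q, t, mode="NW")["editDistance"]
        if d > max_divergence * l:
            continue
        # net credit: an edit forfeits 3 matched bases -- enough that random
        # flank (75% mismatch) never pays while true sequence at long-read
        # error rates still extends
        score = l - 3.0 * d
        if score > best_score:
            best, best_score = l, score
    return best


def decompose(
    sequence: str, motifs: list[Motif], max_divergence: float = 0.2
) -> Decomposition:
    """Greedy left-to-right tiling of a sequence into motif arrays and unique
    segments. Overlapping candidates resolve by longer genomic span, then
    smaller period; output segments are ordered by start coordinate."""
    if not motifs:
        raise ValueError("need at least one motif")
    n = len(sequence)
    matchers = [_MotifMatcher(m) for m in motifs]
    codes = np.frombuffer(sequence.encode(), dtype=np.uint8)
    # candidate array starts: positions with lag-p self-similarity >= 0.5
    cand: set[int] = set()
    for m in motifs:
        prof = _lag_profile(codes, m.period)
        cand.update(np.nonzero(prof >= 0.5)[0].tolist())
    cand_list = sorted(cand)
    segments: list[RepeatArray | UniqueSegment] = []
    unique_start = 0
    cursor = 0
    i = bisect.bisect_left(cand_list, cursor)
    while i < len(cand_list):
        q = cand_list[i]
        if q < cursor:
            i += 1
            continue
        attempts = [
            a
            for mt in matchers
            if (a := _walk_array(sequence, q, mt, max_divergence, floor=unique_start))
        ]
        if not attempts:
            i += 1
            continue
        attempts.sort(key=lambda a: (-(a.end - a.start), len(_motif_by_id(motifs, a.motif_id).consensus)))
        arr = attempts[0]
        if arr.start > unique_start:
            segments.append(UniqueSegment(unique_start, arr.start))
        segments.append(arr)
        cursor = arr.end
        unique_start = cursor
        i = bisect.bisect_left(cand_list, cursor)
    if unique_start < n:
        segments.append(UniqueSegment(unique_start, n))
    return Decomposition(sequence, segments)


def _motif_by_id(motifs: list[Motif], mid: str) -> Motif:
    return next(m for m in motifs if m.id == mid)
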