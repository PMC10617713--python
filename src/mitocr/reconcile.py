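"""Compare alternative circular assemblies and splice the final hybrid genome.

Two assemblies are first brought into register by rotating one to the offset
supported by the most shared unique 31-mer anchors, then globally aligned
(edlib). Discordant sites are reported per differing run (an indel run of k
bases is one site by default, configurable to per-base), each flagged when it
touches a homopolymer run (>= 3 of one base) in either assembly — the error
class long-read consensus sequences are prone to.

Repeat arrays are best compared as blocks (copy counts), not base-by-base:
callers can pass mask intervals (e.g. CR array coordinates from
:mod:`mitocr.repeats`) to restrict per-base discordance to unique sequence.

The hybrid splice takes the coding arc from one source and the CR arc from
another, with junctions at the midpoints of unique anchor sequences flanking
the CR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .seqio import rotate

ANCHOR_K = 31


@dataclass
class DiscordantSite:
    position: int  # on assembly a, strictly increasing
    type: str  # substitution / insertion / deletion (b relative to a)
    length: int
    homopolymer: bool


@dataclass
class AssemblyAlignment:
    a: str
    b_rotated: str
    rotation_offset: int
    cigar: str


@dataclass
class ReconcileReport:
    sites: list[DiscordantSite]
    rotation_offset: int
    aligned_length: int

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class HybridGenome:
    sequence: str
    provenance: list[tuple[int, int, str]]  # (start, end, "coding"|"cr")
    junctions: tuple[int, int]

    def __len__(self) -> int:
        return len(self.sequence)


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    doubled = seq + seq[: k - 1]
    for i in range(len(seq)):
        km = doubled[i : i + k]
        if km in seen or km in dup:
            dup.add(km)
            seen.pop(km, None)
        else:
            seen[km] = i
    return seen


def align_assemblies(
    a: str, b: str, k: int = ANCHOR_K, circular: bool = True
) -> AssemblyAlignment:
    """Rotate b to the offset supported by the most shared unique k-mers,
    then globally align. With ``circular=False`` (pre-cut, collinear
    sequences) no rotation is attempted."""
    if len(a) <= 1000 or len(b) <= 1000:
        raise ValueError("assemblies must be longer than 1 kb")
    if not circular:
        res = edlib.align(b, a, mode="NW", task="path")
        return AssemblyAlignment(a, b, 0, res["cigar"])
    ka, kb = _unique_kmers(a, k), _unique_kmers(b, k)
    shared = set(ka) & set(kb)
    if not shared:
        raise ValueError("no shared unique anchors; assemblies appear unrelated")
    # offset votes drift when the assemblies differ by indels, so anchor the
    # rotation at the origin: take the mode over the shared anchors nearest
    # a's position 0 and leave residual collinearity to the global alignment
    near_origin = sorted(shared, key=lambda km: ka[km])[:25]
    votes: dict[int, int] = {}
    for km in near_origin:
        off = (kb[km] - ka[km]) % len(b)
        votes[off] = votes.get(off, 0) + 1
    comp = max(sorted(votes), key=lambda o: votes[o])
    b_rot = rotate(b, comp)
    res = edlib.align(b_rot, a, mode="NW", task="path")
    # report the offset of b relative to a (rotate(a, offset) ~ b)
    return AssemblyAlignment(a, b_rot, (len(b) - comp) % len(b), res["cigar"])


def discordant_sites(
    alignment: AssemblyAlignment,
    per_base: bool = False,
    mask: list[tuple[int, int]] | None = None,
) -> ReconcileReport:
    """One site per differing column run (or per base with ``per_base``);
    runs inside ``mask`` intervals (coordinates on a) are dropped."""
    a, b = alignment.a, alignment.b_rotated
    events: list[tuple[int, str, int]] = []  # (pos on a, type, length)
    ta = tb = 0
    num = ""
    for ch in alignment.cigar:
        if ch.isdigit():
            num += ch
            continue
        k = int(num)
        num = ""
        if ch == "=":
            ta += k
            tb += k
        elif ch == "X":
            if per_base:
                events.extend((ta + i, "substitution", 1) for i in range(k))
            else:
                events.append((ta, "substitution", k))
            ta += k
            tb += k
        elif ch == "D":  # consumes a only: b lacks these bases
            if per_base:
                events.extend((ta + i, "deletion", 1) for i in range(k))
            else:
                events.append((ta, "deletion", k))
            ta += k
        elif ch == "I":  # consumes b only: extra bases in b
            events.append((ta, "insertion", k))
            tb += k
    sites = []
    for pos, typ, length in events:
        if mask and any(s <= pos < e for s, e in mask):
            continue
        span_a = a[max(0, pos - 4) : pos + length + 4]
        span_b = b[max(0, pos - 4) : pos + length + 4]
        hp = _touches_homopolymer(span_a) or _touches_homopolymer(span_b)
        sites.append(DiscordantSite(pos, typ, length, hp))
    return ReconcileReport(sites, alignment.rotation_offset, len(a))


def _touches_homopolymer(s: str, min_run: int = 3) -> bool:
    run = 1
    for i in range(1, len(s)):
        run = run + 1 if s[i] == s[i - 1] else 1
        if run >= min_run:
            return True
    return False


def _find_once(seq: str, anchor: str) -> int:
    """Start of the anchor on the circular sequence; must occur exactly once."""
    doubled = seq + seq[: len(anchor) - 1]
    hits = []
    i = doubled.find(anchor)
    while i != -1:
        if i < len(seq):
            hits.append(i)
        i = doubled.find(anchor, i + 1)
    if len(hits) != 1:
        raise ValueError(f"anchor occurs {len(hits)} times (must be exactly 1)")
    return hits[0]


def splice_hybrid(
    coding_source: str,
    cr_source: str,
    junction_anchors: tuple[str, str],
) -> HybridGenome:
    """Hybrid circular genome: coding arc from ``coding_source``, CR arc from
    ``cr_source``, junctions at the midpoints of the two unique anchors
    (anchor5 just before the CR, anchor3 just after it)."""
    a5, a3 = junction_anchors
    m5_c = _find_once(coding_source, a5) + len(a5) // 2
    m3_c = _find_once(coding_source, a3) + len(a3) // 2
    m5_r = _find_once(cr_source, a5) + len(a5) // 2
    m3_r = _find_once(cr_source, a3) + len(a3) // 2
    coding_arc = _arc(coding_source, m3_c, m5_c)
    cr_arc = _arc(cr_source, m5_r, m3_r)
    seq = coding_arc + cr_arc
    provenance = [
        (0, len(coding_arc), "coding"),
        (len(coding_arc), len(seq), "cr"),
    ]
    return HybridGenome(seq, provenance, (len(coding_arc), len(seq)))


def _arc(seq: str, start: int, end: int) -> str:
    if end <= start:
        end += len(seq)
    return (seq + seq)[start:end]
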