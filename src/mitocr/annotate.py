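"""Annotation transfer onto a circular assembly, gene order and codon usage.

Each reference gene is located on the target by local (infix) edit-distance
alignment on the doubled target (both strands), accepted above identity and
coverage thresholds tuned for transfer between congeneric mitogenomes.
Protein boundaries are refined to the best in-frame start/stop within a
small window. Stop-codon classification uses the vertebrate mitochondrial
genetic code (AGA/AGG are stops) and recognizes the incomplete stops "T" and
"TA" completed to TAA by polyadenylation.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .seqio import AnnotatedGenome, Feature, revcomp

MT_STOPS = {"TAA", "TAG", "AGA", "AGG"}
MT_STARTS = {"ATG", "ATA", "ATT", "ATC", "GTG"}


@dataclass
class GeneModel:
    name: str
    cls: str  # gene (protein) / rRNA / tRNA
    start: int
    end: int  # may exceed target length for origin-wrapping genes
    strand: str
    identity: float
    start_codon: str | None = None
    stop_codon: str | None = None
    stop_complete: bool | None = None

    def midpoint(self, L: int) -> float:
        return ((self.start + self.end) / 2.0) % L


def _gene_sequence(target: str, model: GeneModel) -> str:
    seq = (target + target)[model.start : model.end]
    return revcomp(seq) if model.strand == "-" else seq


def transfer_annotations(
    reference: AnnotatedGenome,
    target: str,
    min_identity: float = 0.6,
    min_coverage: float = 0.8,
    refine_window: int = 6,
) -> list[GeneModel]:
    """Transfer every non-CR feature of the reference onto the target."""
    L = len(target)
    longest = max((len(f) for f in reference.features if f.type != "CR"), default=0)
    if L < longest:
        raise ValueError("target genome shorter than the longest reference gene")
    doubled = target + target
    doubled_rc = revcomp(doubled)
    models = []
    for feat in reference.features:
        if feat.type == "CR":
            continue
        gseq = (reference.sequence + reference.sequence)[feat.start : feat.end]
        if feat.strand == "-":
            gseq = revcomp(gseq)
        best = None
        for strand, tgt in (("+", doubled), ("-", doubled_rc)):
            res = edlib.align(gseq, tgt, mode="HW", task="locations")
            d = res["editDistance"]
            if d < 0:
                continue
            if best is None or d < best[0]:
                best = (d, strand, res["locations"][0])
        if best is None:
            continue
        d, strand, (s, e) = best
        e += 1
        aln_len = e - s
        identity = 1.0 - d / max(len(gseq), aln_len)
        if identity < min_identity or aln_len < min_coverage * len(gseq):
            continue
        if strand == "-":  # map from reverse-complement coordinates
            s, e = len(doubled) - e, len(doubled) - s
        start, end = s % L, s % L + aln_len
        model = GeneModel(feat.name, feat.type, start, end, strand, identity)
        if feat.type == "gene":
            _refine_protein(model, target, refine_window)
        _assign_codons(model, target)
        models.append(model)
    models.sort(key=lambda m: m.midpoint(L))
    return models


def _refine_protein(model: GeneModel, target: str, window: int) -> None:
    """Shift the start to the best in-frame start codon within +-window bp,
    and the end to an in-frame stop (complete or incomplete) likewise."""
    L = len(target)
    doubled = target + target + target[:100]
    for off in sorted(range(-window, window + 1, 3), key=abs):
        if model.strand == "+":
            s = model.start + off
            codon = doubled[s : s + 3]
        else:
            e = model.end - off
            codon = revcomp(doubled[e - 3 : e])
        if codon in MT_STARTS:
            if model.strand == "+":
                model.start += off
            else:
                model.end -= off
            break
    for off in sorted(range(-window, window + 1), key=abs):
        cand = GeneModel(model.name, model.cls,
                         model.start, model.end + off if model.strand == "+" else model.end,
                         model.strand, model.identity)
        if model.strand == "-":
            cand.start = model.start - off
        if cand.end <= cand.start:
            continue
        seq = _gene_sequence(target, cand)
        if _stop_of(seq)[1] is not None:
            model.start, model.end = cand.start, cand.end
            break


def _stop_of(seq: str) -> tuple[str | None, bool | None]:
    """(stop codon or incomplete tail, complete?) for an ORF-oriented sequence."""
    rem = len(seq) % 3
    if rem == 0:
        last = seq[-3:]
        return (last, True) if last in MT_STOPS else (last, None)
    tail = seq[-rem:]
    if tail == "T" or tail == "TA":
        return tail, False
    return tail, None


def _assign_codons(model: GeneModel, target: str) -> None:
    if model.cls != "gene":
        return
    seq = _gene_sequence(target, model)
    if len(seq) < 6:
        raise ValueError(f"gene model {model.name} shorter than 6 bases")
    model.start_codon = seq[:3]
    model.stop_codon, model.stop_complete = _stop_of(seq)


def infer_cr_interval(models: list[GeneModel], genome_length: int) -> tuple[int, int]:
    """The CR as the maximal arc of the circle uncovered by gene models."""
    if not models:
        raise ValueError("no gene models")
    ivs = []
    for m in models:
        s, e = m.start % genome_length, m.end
        if e - s >= genome_length:
            raise ValueError("a gene model covers the whole genome")
        ivs.append((s, min(e, s + genome_length)))
    ivs.sort()
    # merge on the circle: unroll intervals crossing the origin
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if len(merged) > 1 and merged[-1][1] >= genome_length + merged[0][0]:
        merged[0][0] = merged[-1][0] - genome_length
        merged[0][1] = max(merged[0][1], merged[-1][1] - genome_length)
        merged.pop()
    best = None
    for i, (_s, e) in enumerate(merged):
        nxt = merged[(i + 1) % len(merged)][0]
        if i == len(merged) - 1:
            nxt += genome_length
        gap = nxt - e
        if best is None or gap > best[0]:
            best = (gap, e % genome_length)
    gap, start = best
    return start, start + gap


def gene_order(
    models: list[GeneModel], cr_interval: tuple[int, int], genome_length: int
) -> tuple[list[str], dict[str, bool]]:
    """Clockwise gene order from the origin, and per-gene adjacency to the CR
    arc (true iff no other feature lies between the gene and the CR)."""
    if len(models) < 2:
        raise ValueError("need at least two features to order")
    ordered = sorted(models, key=lambda m: m.midpoint(genome_length))
    names = [m.name for m in ordered]
    cr_mid = ((cr_interval[0] + cr_interval[1]) / 2.0) % genome_length
    ring = sorted(
        [(m.midpoint(genome_length), m.name) for m in models] + [(cr_mid, "CR")]
    )
    ring_names = [n for _pos, n in ring]
    i = ring_names.index("CR")
    adjacent = {ring_names[(i - 1) % len(ring)], ring_names[(i + 1) % len(ring)]}
    return names, {n: (n in adjacent) for n in names}


def codon_report(models: list[GeneModel], target: str) -> list[dict]:
    """Start/stop codon table for the protein genes."""
    rows = []
    for m in models:
        if m.cls != "gene":
            continue
        if m.start_codon is None:
            _assign_codons(m, target)
        rows.append(
            {
                "gene": m.name,
                "start_codon": m.start_codon,
                "stop_codon": m.stop_codon,
                "stop_complete": {True: "complete", False: "incomplete", None: "other"}[
                    m.stop_complete
                ],
            }
        )
    return rows
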