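"""Sequence containers and FASTA/FASTQ/GFF3 input/output.

All internal coordinates are 0-based half-open. The genome is circular with
the origin at position 0 of the assembled orientation; features that wrap the
origin carry ``end > genome length`` and are interpreted modulo the length.
GFF3 is written 1-based inclusive per the standard — the converters in this
module are the only place the coordinate shift happens.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SeqFormatError(ValueError):
    """Malformed record or non-IUPAC characters beyond {A,C,G,T,N}."""


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return sequence.translate(_COMPLEMENT)[::-1]


def rotate(sequence: str, offset: int) -> str:
    """Left-rotate a circular sequence by ``offset`` (taken modulo length)."""
    if not sequence:
        return sequence
    k = offset % len(sequence)
    return sequence[k:] + sequence[:k]


@dataclass
class Read:
    """A sequencing read: identifier, sequence, optional per-base Phred scores.

    ``truth`` optionally records simulation provenance (source molecule,
    coordinates, strand) and is never serialized into FASTQ.
    """

    id: str
    sequence: str
    quality: np.ndarray | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqFormatError("read id must be non-empty")
        if set(self.sequence) - VALID_BASES:
            bad = sorted(set(self.sequence) - VALID_BASES)
            raise SeqFormatError(f"non-IUPAC characters in {self.id!r}: {bad}")
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=np.int64)
            if len(self.quality) != len(self.sequence):
                raise SeqFormatError(
                    f"length mismatch in {self.id!r}: "
                    f"{len(self.sequence)} bases vs {len(self.quality)} quality scores"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Feature:
    """An annotated interval on a circular genome.

    ``end`` may exceed the genome length for features wrapping the origin.
    """

    name: str
    type: str  # gene / tRNA / rRNA / CR
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad interval for {self.name}: [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """Circular genome sequence with a feature table and a declared CR interval."""

    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    cr_interval: tuple[int, int] | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cr_sequence(self) -> str:
        if self.cr_interval is None:
            raise ValueError("no CR interval declared")
        s, e = self.cr_interval
        doubled = self.sequence + self.sequence
        return doubled[s:e]


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def _check_seq(rec_id: str, seq: str) -> str:
    seq = seq.upper()
    if set(seq) - VALID_BASES:
        bad = sorted(set(seq) - VALID_BASES)
        raise SeqFormatError(f"non-IUPAC characters in record {rec_id!r}: {bad}")
    return seq


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTA into an order-preserving list of (id, sequence)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, _check_seq(rec.id, str(rec.seq))))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[Read]:
    """Parse FASTQ (Phred+33) into Reads."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = np.array(rec.letter_annotations["phred_quality"], dtype=np.int64)
        out.append(Read(rec.id, _check_seq(rec.id, str(rec.seq)), qual))
    return out


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            if r.quality is None:
                raise SeqFormatError(f"read {r.id!r} has no quality scores")
            qline = "".join(chr(33 + int(q)) for q in r.quality)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qline}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_SOURCE = "mitocr"


def write_gff3(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write features 1-based inclusive.

    A feature wrapping the origin is emitted as two lines sharing an ID
    attribute, since GFF3 has no native circular syntax.
    """
    L = len(genome)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {L}\n")
        for i, f in enumerate(genome.features):
            attrs = f"ID={f.name};Name={f.name};feature_type={f.type}"
            if f.end <= L:
                fh.write(
                    f"{genome.id}\t{_GFF_SOURCE}\t{f.type}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
                )
            else:  # wraps the origin: two parts, shared ID
                fh.write(
                    f"{genome.id}\t{_GFF_SOURCE}\t{f.type}\t{f.start + 1}\t{L}\t.\t{f.strand}\t.\t{attrs};part=1\n"
                )
                fh.write(
                    f"{genome.id}\t{_GFF_SOURCE}\t{f.type}\t1\t{f.end - L}\t.\t{f.strand}\t.\t{attrs};part=2\n"
                )


def read_gff3(path: str | Path) -> tuple[str, int, list[Feature]]:
    """Read a GFF3 written by :func:`write_gff3`.

    Returns (sequence id, declared length, features); two-part wrapped
    features are reassembled by shared ID.
    """
    seqid = ""
    length = 0
    feats: dict[str, Feature] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                seqid, length = parts[1], int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise SeqFormatError(f"malformed GFF3 line: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";"))
            fid = attrs["ID"]
            start, end = int(cols[3]) - 1, int(cols[4])
            if fid in feats:  # second part of a wrapped feature
                feats[fid].end = feats[fid].start + (feats[fid].end - feats[fid].start) + end
            else:
                feats[fid] = Feature(attrs.get("Name", fid), cols[2], start, end, cols[6])
                order.append(fid)
    return seqid, length, [feats[k] for k in order]


# ---------------------------------------------------------------------------
# Plain TSV helpers (order-preserving, no quoting needed for our fields)
# ---------------------------------------------------------------------------


def write_tsv(rows: Sequence[dict], path: str | Path) -> None:
    rows = list(rows)
    with open(path, "w") as fh:
        if not rows:
            return
        cols = list(rows[0].keys())
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def read_tsv(path: str | Path) -> list[dict]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.rstrip("\n")]
    if not lines:
        return []
    cols = lines[0].split("\t")
    return [dict(zip(cols, ln.split("\t"))) for ln in lines[1:]]
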