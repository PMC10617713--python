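"""Synthetic mitogenomes with repeat-laden control regions, and read simulation.

The generator emulates the structure of a frog mitochondrial genome whose
control region (CR) carries two long tandem-repeat arrays: a circular genome
of a ~15.3 kb coding part (13 protein genes, 2 rRNAs, 22 tRNAs, with ND5
translocated next to the CR) followed by a ~6.9 kb CR composed of unique
flanks/spacers (standing in for TAS/CSB elements) and two motif arrays with
periods 40 and 22 bp at 24 and 203 copies. Per-molecule copy-number
heteroplasmy is modeled as symmetric integer jitter on each array's copy
count; reads carry an ONT-like indel-dominated error model with an extra
homopolymer-deletion channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import AnnotatedGenome, Feature, Read, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


def _is_primitive(motif: str) -> bool:
    """True iff no rotation of ``motif`` equals a shorter repetition."""
    return motif not in (motif + motif)[1:-1]


@dataclass
class CRSpec:
    """Control-region blueprint: unique flanks/spacers and tandem arrays.

    ``arrays`` is an ordered list of (motif sequence, copy count); ``spacers``
    holds the unique sequences between consecutive arrays (one fewer than
    arrays, or empty).
    """

    flank5: str
    flank3: str
    arrays: list[tuple[str, int]] = field(default_factory=list)
    spacers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.arrays and len(self.spacers) != len(self.arrays) - 1:
            raise SimulationError("need exactly len(arrays) - 1 spacers")
        for motif, copies in self.arrays:
            if copies < 1:
                raise SimulationError(f"copy count {copies} < 1")
            if not _is_primitive(motif):
                raise SimulationError(f"motif {motif!r} is not primitive")

    @property
    def motif_ids(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(len(self.arrays))]

    @property
    def unique_length(self) -> int:
        return len(self.flank5) + len(self.flank3) + sum(len(s) for s in self.spacers)

    @property
    def length(self) -> int:
        return self.unique_length + sum(len(m) * c for m, c in self.arrays)

    def render(self, copy_counts: dict[str, int] | None = None) -> str:
        """Concatenate the CR, optionally with per-array copy-count overrides."""
        parts = [self.flank5]
        for i, (motif, copies) in enumerate(self.arrays):
            mid = self.motif_ids[i]
            c = copies if copy_counts is None else copy_counts[mid]
            if c < 1:
                raise SimulationError(f"copy count for array {mid} below 1")
            parts.append(motif * c)
            if i < len(self.spacers):
                parts.append(self.spacers[i])
        parts.append(self.flank3)
        return "".join(parts)


@dataclass
class GenomeSpec:
    """Blueprint for a circular mitogenome: ordered coding blocks + CR."""

    coding_blocks: list[tuple[str, str, int, str]]  # (name, type, length bp, strand)
    cr_spec: CRSpec
    seed: int = 0

    def __post_init__(self) -> None:
        names = [b[0] for b in self.coding_blocks]
        if len(names) != len(set(names)):
            raise SimulationError("duplicate gene names in coding blocks")
        for name, _t, length, _s in self.coding_blocks:
            if length <= 0:
                raise SimulationError(f"zero-length block {name!r}")

    @property
    def coding_length(self) -> int:
        return sum(b[2] for b in self.coding_blocks)

    @property
    def total_length(self) -> int:
        return self.coding_length + self.cr_spec.length


# Default gene inventory: 13 protein genes, 2 rRNAs, 22 tRNAs; ND5 is placed
# last before the CR (the rearranged gene order of interest). Protein entries carry
# their start codon and stop (complete codon, or incomplete "T"/"TA" completed
# by polyadenylation). Lengths sum to 15,345 bp.
_PROTEIN_CODONS = {
    # name: (start codon, stop spec)
    "ND1": ("ATG", "T"),
    "ND2": ("ATT", "TAG"),
    "COX1": ("ATA", "TAA"),
    "COX2": ("ATG", "AGA"),
    "ATP8": ("ATG", "TAA"),
    "ATP6": ("ATG", "T"),
    "COX3": ("ATG", "T"),
    "ND3": ("ATG", "T"),
    "ND4L": ("ATC", "T"),
    "ND4": ("ATG", "T"),
    "ND5": ("ATG", "AGA"),
    "ND6": ("ATT", "AGG"),
    "CYTB": ("ATT", "AGA"),
}

DEFAULT_GENE_TABLE: list[tuple[str, str, int, str]] = [
    ("tRNA-Phe", "tRNA", 70, "+"),
    ("12S-rRNA", "rRNA", 935, "+"),
    ("tRNA-Val", "tRNA", 70, "+"),
    ("16S-rRNA", "rRNA", 1506, "+"),
    ("tRNA-Leu1", "tRNA", 70, "+"),
    ("ND1", "gene", 967, "+"),
    ("tRNA-Ile", "tRNA", 70, "+"),
    ("tRNA-Gln", "tRNA", 70, "-"),
    ("tRNA-Met", "tRNA", 70, "+"),
    ("ND2", "gene", 1038, "+"),
    ("tRNA-Trp", "tRNA", 70, "+"),
    ("tRNA-Ala", "tRNA", 70, "-"),
    ("tRNA-Asn", "tRNA", 70, "-"),
    ("tRNA-Cys", "tRNA", 70, "-"),
    ("tRNA-Tyr", "tRNA", 70, "-"),
    ("COX1", "gene", 1551, "+"),
    ("tRNA-Ser1", "tRNA", 70, "-"),
    ("tRNA-Asp", "tRNA", 70, "+"),
    ("COX2", "gene", 687, "+"),
    ("tRNA-Lys", "tRNA", 70, "+"),
    ("ATP8", "gene", 165, "+"),
    ("ATP6", "gene", 682, "+"),
    ("COX3", "gene", 784, "+"),
    ("tRNA-Gly", "tRNA", 70, "+"),
    ("ND3", "gene", 346, "+"),
    ("tRNA-Arg", "tRNA", 70, "+"),
    ("ND4L", "gene", 295, "+"),
    ("ND4", "gene", 1378, "+"),
    ("tRNA-His", "tRNA", 70, "+"),
    ("tRNA-Ser2", "tRNA", 70, "+"),
    ("tRNA-Leu2", "tRNA", 70, "+"),
    ("ND6", "gene", 519, "-"),
    ("tRNA-Glu", "tRNA", 70, "-"),
    ("CYTB", "gene", 1140, "+"),
    ("tRNA-Thr", "tRNA", 70, "+"),
    ("tRNA-Pro", "tRNA", 70, "-"),
    ("ND5", "gene", 1812, "+"),
]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def random_primitive_motif(rng: np.random.Generator, period: int) -> str:
    """A random motif whose period is unambiguous (no rotation is a shorter repetition)."""
    while True:
        m = _random_seq(rng, period)
        if _is_primitive(m):
            return m


def default_genome_spec(seed: int = 0) -> GenomeSpec:
    """The documented synthetic genome: 22,274 bp total, CR 6,929 bp.

    CR = 450 bp 5' flank + 40 bp x 24 (motif A) + 350 bp spacer +
    22 bp x 203 (motif B) + 703 bp 3' flank = 1,503 bp unique + 5,426 bp
    repeats.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC2]))
    cr = CRSpec(
        flank5=_random_seq(rng, 450),
        flank3=_random_seq(rng, 703),
        arrays=[
            (random_primitive_motif(rng, 40), 24),
            (random_primitive_motif(rng, 22), 203),
        ],
        spacers=[_random_seq(rng, 350)],
    )
    return GenomeSpec(coding_blocks=list(DEFAULT_GENE_TABLE), cr_spec=cr, seed=seed)


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "AGA", "AGG"}  # vertebrate mitochondrial code


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random sense codons (no in-frame stops of the vertebrate mt code)."""
    out = []
    while len(out) < n:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            out.append(c)
    return "".join(out)


def _protein_sequence(rng: np.random.Generator, name: str, length: int) -> str:
    start, stop = _PROTEIN_CODONS[name]
    rem = length % 3
    if rem == 0:
        if stop in ("T", "TA"):
            raise SimulationError(f"{name}: incomplete stop needs length % 3 != 0")
        body = _random_codons(rng, length // 3 - 2)
        return start + body + stop
    tail = "T" if rem == 1 else "TA"
    body = _random_codons(rng, length // 3 - 1)
    return start + body + tail


@dataclass
class SimulatedGenome(AnnotatedGenome):
    """An AnnotatedGenome that remembers its generating blueprint."""

    spec: GenomeSpec | None = None

    @property
    def cr_spec(self) -> CRSpec:
        return self.spec.cr_spec


def build_genome(spec: GenomeSpec) -> SimulatedGenome:
    """Materialize a circular genome and its feature table; deterministic in spec.seed."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x6E]))
    parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    for name, ftype, length, strand in spec.coding_blocks:
        if ftype == "gene":
            seq = _protein_sequence(rng, name, length)
        else:
            seq = _random_seq(rng, length)
        if strand == "-":
            seq = revcomp(seq)
        parts.append(seq)
        features.append(Feature(name, ftype, pos, pos + length, strand))
        pos += length
    cr_seq = spec.cr_spec.render()
    features.append(Feature("CR", "CR", pos, pos + len(cr_seq), "+"))
    parts.append(cr_seq)
    return SimulatedGenome(
        id="synthetic_mt",
        sequence="".join(parts),
        features=features,
        cr_interval=(pos, pos + len(cr_seq)),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Heteroplasmy and molecules
# ---------------------------------------------------------------------------


@dataclass
class HeteroplasmyModel:
    """Symmetric integer jitter on per-array copy counts.

    The offset is a difference of two Poisson draws with mean dispersion/2
    each (variance = dispersion); dispersion 0 means every molecule carries
    the blueprint's counts.
    """

    dispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")

    def draw_offset(self, rng: np.random.Generator) -> int:
        if self.dispersion == 0:
            return 0
        lam = self.dispersion / 2.0
        return int(rng.poisson(lam) - rng.poisson(lam))


@dataclass
class Molecule:
    """One mitochondrial molecule: full sequence + its true copy counts."""

    sequence: str
    copy_counts: dict[str, int]


def simulate_molecules(
    genome: SimulatedGenome, model: HeteroplasmyModel, n: int, seed: int = 0
) -> list[Molecule]:
    """Draw n molecules whose CR arrays are regenerated at jittered copy counts."""
    if n < 1:
        raise SimulationError("need n >= 1 molecules")
    spec = genome.spec
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x11]))
    coding = genome.sequence[: genome.cr_interval[0]]
    out = []
    for _ in range(n):
        counts = {}
        for mid, (_m, c) in zip(spec.cr_spec.motif_ids, spec.cr_spec.arrays):
            c_new = c + model.draw_offset(rng)
            if c_new < 1:
                raise SimulationError(f"jitter drove copy count of array {mid} below 1")
            counts[mid] = c_new
        out.append(Molecule(coding + spec.cr_spec.render(counts), counts))
    return out


# ---------------------------------------------------------------------------
# Error model and read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadSimParams:
    """Per-base error rates, an extra per-run homopolymer-deletion rate,
    read-length model and coverage target."""

    substitution: float = 0.02
    insertion: float = 0.02
    deletion: float = 0.04
    hp_deletion: float = 0.15  # per homopolymer run of length >= 3
    fixed_length: int | None = None  # exact read length; None -> lognormal
    lognormal: tuple[float, float] = (9.0, 0.4)  # (mu, sigma) of ln length
    min_length: int = 200
    coverage: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.substitution, self.insertion, self.deletion, self.hp_deletion):
            if not (0 <= r < 1):
                raise SimulationError("error rates must lie in [0, 1)")
        if self.coverage <= 0:
            raise SimulationError("coverage must be > 0")

    @property
    def total_error(self) -> float:
        return self.substitution + self.insertion + self.deletion

    @property
    def phred(self) -> int:
        if self.total_error <= 0:
            return 60
        return max(2, min(60, round(-10.0 * math.log10(self.total_error))))


def _homopolymer_runs(codes: np.ndarray, min_run: int = 3) -> list[tuple[int, int]]:
    """(start, end) of maximal runs of one base with length >= min_run."""
    if len(codes) == 0:
        return []
    change = np.nonzero(np.diff(codes))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(codes)]))
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_run]


def apply_errors(sequence: str, params: ReadSimParams, rng: np.random.Generator) -> str:
    """Apply substitutions, insertions, deletions and homopolymer deletions."""
    codes = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    n = len(codes)
    # map ACGT -> 0..3
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    b4 = lut[codes]
    keep = rng.random(n) >= params.deletion
    if params.hp_deletion > 0:
        for s, e in _homopolymer_runs(b4):
            if rng.random() < params.hp_deletion:
                keep[e - 1] = False
    sub = keep & (rng.random(n) < params.substitution)
    shift = rng.integers(1, 4, size=n).astype(np.uint8)
    b4 = np.where(sub, (b4 + shift) % 4, b4)
    kept = b4[keep]
    ins_mask = rng.random(len(kept)) < params.insertion
    if ins_mask.any():
        idx = np.nonzero(ins_mask)[0] + 1
        kept = np.insert(kept, idx, rng.integers(0, 4, size=len(idx)).astype(np.uint8))
    return _BASES[kept].tobytes().decode()


def _draw_length(params: ReadSimParams, rng: np.random.Generator, cap: int) -> int:
    if params.fixed_length is not None:
        return min(params.fixed_length, cap)
    mu, sigma = params.lognormal
    ln = int(rng.lognormal(mu, sigma))
    return max(params.min_length, min(ln, cap))


def _mean_length(params: ReadSimParams) -> float:
    if params.fixed_length is not None:
        return float(params.fixed_length)
    mu, sigma = params.lognormal
    return math.exp(mu + sigma**2 / 2.0)


def simulate_long_reads(molecules: list[Molecule], params: ReadSimParams) -> list[Read]:
    """Draw error-bearing long reads from circular molecules.

    Reads may cross the origin (emitted as contiguous sequence); strands are
    equiprobable. Truth metadata records source molecule, 0-based start/end on
    the molecule (end may exceed its length for origin-crossing reads) and
    strand, all before errors are applied.
    """
    if not molecules:
        raise SimulationError("no molecules to sequence")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x22]))
    genome_len = len(molecules[0].sequence)
    n_reads = max(1, math.ceil(params.coverage * genome_len / _mean_length(params)))
    return _emit_reads(
        [m.sequence for m in molecules], n_reads, params, rng, prefix="lr",
        truth_extra=[{"copy_counts": m.copy_counts} for m in molecules],
    )


def _emit_reads(templates, n_reads, params, rng, prefix, truth_extra=None, full_length=False):
    reads = []
    phred = params.phred
    for i in range(n_reads):
        mi = int(rng.integers(0, len(templates)))
        tpl = templates[mi]
        if full_length:
            start, length = 0, len(tpl)
        else:
            start = int(rng.integers(0, len(tpl)))
            length = _draw_length(params, rng, len(tpl))
        frag = (tpl + tpl)[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        err = apply_errors(frag, params, rng)
        truth = {"molecule": mi, "start": start, "end": start + length, "strand": strand}
        if truth_extra is not None:
            truth.update(truth_extra[mi])
        reads.append(
            Read(f"{prefix}{i:06d}", err, np.full(len(err), phred, dtype=np.int64), truth)
        )
    return reads


def simulate_short_reads(
    molecules: list[Molecule],
    read_len: int = 150,
    insert_mean: float = 450.0,
    insert_sd: float = 50.0,
    coverage: float = 50.0,
    error_rate: float = 0.002,
    seed: int = 0,
) -> list[Read]:
    """Paired-end short reads (R1 forward / R2 reverse of the same fragment)."""
    if read_len > insert_mean:
        raise SimulationError("insert size must be >= read length")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x33]))
    genome_len = len(molecules[0].sequence)
    n_pairs = max(1, math.ceil(coverage * genome_len / (2 * read_len)))
    params = ReadSimParams(substitution=error_rate, insertion=0.0, deletion=0.0,
                           hp_deletion=0.0, coverage=coverage, seed=seed)
    phred = params.phred
    reads = []
    for i in range(n_pairs):
        mi = int(rng.integers(0, len(molecules)))
        tpl = molecules[mi].sequence
        insert = max(read_len, int(round(rng.normal(insert_mean, insert_sd))))
        start = int(rng.integers(0, len(tpl)))
        frag = (tpl + tpl)[start : start + insert]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        r1, r2 = frag[:read_len], revcomp(frag[-read_len:])
        for mate, seq in (("1", r1), ("2", r2)):
            err = apply_errors(seq, params, rng)
            reads.append(
                Read(
                    f"sr{i:06d}/{mate}",
                    err,
                    np.full(len(err), phred, dtype=np.int64),
                    {"molecule": mi, "start": start, "end": start + insert,
                     "strand": strand, "mate": mate},
                )
            )
    return reads


def _locate_product(sequence: str, forward: str, reverse: str) -> tuple[int, int]:
    """Start/end (0-based, end may wrap) of the product delimited by an exact
    convergent primer pair on a circular sequence."""
    doubled = sequence + sequence
    L = len(sequence)
    f_hits = [i for i in _find_all(doubled, forward) if i < L]
    r_site = revcomp(reverse)
    r_hits = [i for i in _find_all(doubled, r_site) if i < L]
    if len(f_hits) != 1 or len(r_hits) != 1:
        raise SimulationError(
            f"primers must each hit exactly once (got {len(f_hits)} forward, {len(r_hits)} reverse)"
        )
    f, r = f_hits[0], r_hits[0]
    end = r + len(r_site)
    if end <= f:  # product wraps the origin
        end += L
    if end - f <= len(forward) + len(reverse):
        raise SimulationError("primers oriented divergently or product empty")
    return f, end


def simulate_amplicon_reads(
    molecules: list[Molecule] | SimulatedGenome,
    forward: str,
    reverse: str,
    params: ReadSimParams,
    n_reads: int | None = None,
    full_length: bool = True,
) -> list[Read]:
    """Reads drawn only from the primer-delimited product (primer-inclusive).

    ``molecules`` may be a single genome (treated as one homoplasmic
    molecule). Each primer must hit every molecule exactly once, convergently.
    With ``full_length`` every read covers the whole product, emulating
    amplicon reads surviving a length filter.
    """
    if isinstance(molecules, AnnotatedGenome):
        molecules = [Molecule(molecules.sequence, {})]
    products, extras = [], []
    for m in molecules:
        s, e = _locate_product(m.sequence, forward, reverse)
        products.append((m.sequence + m.sequence)[s:e])
        extras.append({"copy_counts": m.copy_counts, "product_length": e - s})
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x44]))
    if n_reads is None:
        mean_len = (
            float(np.mean([len(p) for p in products]))
            if full_length
            else _mean_length(params)
        )
        n_reads = max(1, math.ceil(params.coverage * len(molecules[0].sequence) / mean_len))
    return _emit_reads(products, n_reads, params, rng, prefix="amp",
                       truth_extra=extras, full_length=full_length)


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


# ---------------------------------------------------------------------------
# Draft-assembly emulation
# ---------------------------------------------------------------------------


def simulate_draft_assembly(
    genome: SimulatedGenome,
    n_errors: int = 15,
    hp_fraction: float = 0.6,
    seed: int = 0,
) -> tuple[str, list[tuple[int, str]]]:
    """A long-read-consensus-like variant of the genome: ``n_errors`` residual
    errors planted in the coding region, a ``hp_fraction`` of them single-base
    deletions inside homopolymer runs (>= 3), the rest substitutions.

    Returns the variant sequence and the planted (position, type) list.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x55]))
    coding_end = genome.cr_interval[0]
    codes = np.frombuffer(genome.sequence[:coding_end].encode(), dtype=np.uint8)
    runs = _homopolymer_runs(codes)
    n_hp = min(int(round(n_errors * hp_fraction)), len(runs))
    hp_sites = [runs[i][1] - 1 for i in rng.choice(len(runs), size=n_hp, replace=False)]
    taken = set(hp_sites)
    sub_sites: list[int] = []
    while len(sub_sites) < n_errors - n_hp:
        p = int(rng.integers(0, coding_end))
        # keep substitution sites clear of homopolymer runs and other edits so
        # each planted error is its own discordant site
        if p in taken or any(s - 1 <= p <= e for s, e in runs):
            continue
        taken.add(p)
        sub_sites.append(p)
    edits = sorted([(p, "deletion") for p in hp_sites] + [(p, "substitution") for p in sub_sites])
    seq = list(genome.sequence)
    for p, kind in reversed(edits):
        if kind == "deletion":
            del seq[p]
        else:
            old = seq[p]
            choices = [b for b in "ACGT" if b != old]
            seq[p] = choices[int(rng.integers(0, 3))]
    return "".join(seq), edits
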