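# Methods

## The problem

A circular mitogenome with a long, repeat-laden control region (CR) cannot be
finished from short reads: any repeat array longer than the read length
collapses to an arbitrary small copy number, and the assembly understates the
genome by several kilobases. Long reads span the CR but carry ~5–10%
indel-dominated errors, and the molecules themselves differ in repeat copy
number (heteroplasmy), so no single read is the answer. `mitocr` treats CR
resolution as a parameter-estimation problem — estimate each array's copy
number as a mode across spanning reads, then reconstruct the consensus
sequence at those modal counts — and splices the result onto a short-read
coding backbone.

## Synthetic genome and study conditions

The generator's defaults define the study conditions and are not tuned per
experiment:

| parameter | default | rationale |
|---|---|---|
| total genome | 22,274 bp | coding 15,345 bp + CR 6,929 bp |
| gene inventory | 13 proteins, 2 rRNAs, 22 tRNAs | vertebrate mitogenome complement; ND5 placed last before the CR (the rearrangement of interest) |
| CR composition | 450 bp flank + 40 bp × 24 + 350 bp spacer + 22 bp × 203 + 703 bp flank | 1,503 bp unique + 5,426 bp repeats = 6,929 bp |
| motif sequences | random, primitive | only the periods (40, 22 bp) are constrained; a motif is rejected if any rotation equals a shorter repetition, so the discovered period is unambiguous |
| heteroplasmy | per-array jitter = difference of two Poisson(d/2) draws, dispersion d = 1 | symmetric integer offsets; d = 0 gives identical molecules |
| long-read errors | 2% substitution, 2% insertion, 4% deletion per base + 15% per-run homopolymer deletion (runs ≥ 3) | deletion-dominated, homopolymer-biased, the ONT signature |
| read quality | constant Phred of the total error rate (Q11 at 8%) | simplest model satisfying the Q10 QC gate |
| long reads | 200 full-length amplicon reads spanning the CR ± 1 kb | a Flongle-scale amplicon experiment |
| short reads | 150 bp pairs, insert 450 ± 50, 30×, 0.2% substitutions | Illumina-like |
| draft-assembly errors | 15 residual coding errors, 60% homopolymer deletions | emulates the residual error of a polished long-read assembly |

Protein genes are generated as start codon + random sense codons + stop,
with the published start/stop assignments (ATA for COX1, ATT for ND2/ND6/CYTB,
ATC for ND4L; AGA/AGG stops; incomplete `T`/`TA` stops for ND1, ATP6, COX3,
ND3, ND4L, ND4) baked into the gene table, so annotation and codon reporting
are testable end to end.

The emulated short-read backbone keeps the coding sequence exact and
collapses the CR to 229 bp (flank tips + 2 copies of motif A + 1 of motif B)
— the structural artefact of assembling an unspanned repeat from 150 bp
reads.

What the simulation does **not** model: signal-level ONT behaviour,
chimeric/adapter reads, quality-score calibration, coverage bias,
context-dependent substitution spectra, and NUMTs. Passing tests therefore
demonstrate the *logic* of the pipeline under a faithful error geometry, not
performance on any particular real flow cell.

## Repeat discovery and decomposition

**Discovery** runs on low-error sequence (an assembly or a polished
consensus). For each candidate period p (10–100 bp) the lag-p self-match
profile is smoothed over one period; maximal windows above the purity
threshold (0.8) spanning ≥ `min_copies` periods are kept, smallest p first,
discarding multiples of an accepted period over the same window. The
consensus is a per-phase majority vote, reduced to its primitive root and
reported in canonical (lexicographically smallest) rotation. Two safeguards
matter in practice: near-duplicate suppression (a residual indel inside a
long array creates a ghost period p ± 1 window spanning ~3 periods; when two
motifs are within 25% edit distance under rotation, the larger-span one
wins), and the pipeline's draft stage requires 5 supporting copies, while
the library default stays at 3.

**Decomposition** tiles a sequence left to right. Candidate array starts are
positions whose lag-p self-similarity reaches 0.5; the start is snapped to
the onset of periodicity, the motif phase is chosen by Hamming scan plus
local edit-distance refinement, and copies are consumed one at a time with
edlib prefix alignments (per-copy tolerance 0.2 × period; a single divergent
copy is kept, two consecutive ones terminate the array). Three boundary
refinements keep counts frame-exact:

- *backward extension*: once the phase is known, walk back copy-by-copy with
  length-flexible alignment — the candidate detector may first fire mid-array
  when the leading copy contains an indel;
- *chimera rejection*: an edge copy is dropped when its best partial-copy
  match leaves a complement that mismatches like random sequence (> 34%
  errors) — genuine noisy copies never look like that;
- *joint edge partials*: leading and trailing partial copies are measured by
  penalized alignment (an edit forfeits 3 matched bases, so junk never pays)
  and counted jointly, rounded half-up. In a rotated tiling frame one true
  copy appears as two edge partials; the joint rule makes the count
  independent of the frame, and with no leading partial it reduces to the
  simple "trailing partial ≥ half a period counts" rule.

Array divergence is reported over interior copies; edge copies are
frame-ambiguous against flanking sequence.

An exhaustive dynamic-programming tiling oracle (maximum number of exact
rotated copies) backs the test suite on planted arrays up to 2 kb.

## Copy-number estimation and CR reconstruction

Spanning reads are those containing both 25 bp anchors drawn from the coding
sequence flanking the CR, matched by edit distance (≤ 5) so raw-read indels
do not cost recall; minus-strand reads are re-oriented. Each read's CR
interval is decomposed and counted; gaps between two arrays of the same
motif whose length is within tolerance of ≤ 4 periods are credited as copies
(array fragmentation at two consecutive bad copies otherwise biases counts
down). The per-motif estimate is the mode across reads, ties toward the
smaller count.

Reconstruction selects a representative read whose counts equal the modes
(preferring unfragmented decompositions, then highest mean quality, then
lexicographic id; if none matches, the closest read by L1 distance is used
and flagged). Arrays are rebuilt as `modal_count ×` the per-phase
majority-vote motif, pooled over the indel-free copies of up to 60
structure-matched reads, emitted in the frame anchored at the array's left
boundary. Unique segments are polished by pairwise-alignment voting (each
supporting read casts one vote per template column plus insertion votes
between columns; majority wins; two rounds). A final global polish of the
assembled CR against the modal-count reads cleans residual junction wobble.
Under the study conditions this lands within 0.1–0.5% edit distance of the
truth; the residual is dominated by deletions at positions where more than
half of the reads deleted the same base.

## In-silico PCR

Primer matching is substitution-only (Hamming, ≤ 3 mismatches, no indels in
the primer site) — deliberately stricter than the anchor matching above, and
cheap enough that a brute-force scan is the test oracle. Product lengths are
primer-inclusive; nested convergent pairs resolve to the innermost product,
mimicking short-product dominance in PCR. Histogram bins are 100 bp wide
with edges ≡ 51 (mod 100). Because deletions outnumber insertions 2:1,
measured product lengths shrink by ~2% in expectation, so the modal bin sits
one to two bins below the true CR length — a real and interpretable bias of
length measurement in raw reads, visible in the `04` analysis driver.

## Reconciliation and hybrid splicing

Assemblies are registered by rotating one to the offset supported by shared
unique 31-mers nearest the origin (global offset voting drifts when the
assemblies differ by indels), then globally aligned with edlib. A discordant
site is one run of differing columns (an indel run of k bases is one site;
per-base counting is a config toggle), flagged homopolymer when it touches a
run ≥ 3 of one base in either assembly. Coding regions are compared after
cutting both assemblies at the 31-mer ending at the CR boundary: aligning a
full genome against a collapsed-CR assembly scatters the ~6.7 kb CR gap
through repetitive sequence along tie-broken alignment paths. The hybrid
genome takes its coding arc from one source and its CR arc from the other,
with junctions at the midpoints of the two unique boundary anchors;
provenance is reported per arc and the splice is idempotent.

## Annotation transfer

Each reference gene is located on the doubled target (both strands) with
edlib infix alignment; hits above 60% identity and 80% coverage become gene
models — thresholds chosen for transfer between congeneric mitogenomes and
exposed as configuration. Protein boundaries are refined to the best
in-frame start/stop within ± 6 bp. Stops are classified under the vertebrate
mitochondrial code: complete TAA/TAG/AGA/AGG, or incomplete `T`/`TA` when the
model length is not a codon multiple (completed to TAA by polyadenylation).
The CR on a finished assembly is defined as the maximal arc uncovered by
gene models; gene order and CR adjacency are computed cyclically from
midpoints.

## Numerical and design notes

- All coordinates are 0-based half-open; the genome is circular with the
  origin at position 0, and features wrapping the origin carry end > length.
  GFF3 output is 1-based inclusive, wrapped features written as two lines
  sharing an ID.
- Every stochastic component takes a seed and derives its generator through
  a fixed `SeedSequence` tree; reruns are byte-identical, which the test
  suite asserts on whole output directories.
- Edit-distance work (decomposition, anchoring, polishing, alignment,
  transfer) is delegated to edlib; FASTA/FASTQ parsing to Biopython.
- Quality filtering averages error probabilities, not Phred values, and both
  QC thresholds are inclusive (with a 1e-9 epsilon against float round-off
  at exact boundaries).
- Problem sizes throughout (200 spanning reads, 64 molecules, 30× short
  reads, 2 kb oracle inputs) are chosen so the full study re-runs in seconds
  on a laptop while leaving the estimators' behaviour clearly measurable.

## Known limitations

- Copy-number modes are estimates of the *sampled molecule population's*
  mode; at small read counts (≲ 60) neighbouring counts can tie and the
  reported mode may differ by one from the blueprint — a sampling property,
  not an estimator bias.
- The reconstruction's residual error concentrates at array/unique junctions
  and at sites where a majority of reads share a deletion; it is bounded in
  testing, not zero.
- Motif discovery assumes a low-error substrate (assembly or polished
  draft); it is not designed to run directly on raw 8%-error reads, which is
  why the pipeline polishes a draft first.
- The short-read branch is emulated structurally (exact coding + collapsed
  CR) rather than assembled from the simulated short reads; short-read
  assembly itself is out of scope.
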