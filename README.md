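# mitocr — resolving repeat-laden mitochondrial control regions from long reads

Mitochondrial genomes are routinely assembled from short reads, but the
control region (CR, or D-loop) of many amphibians contains long tandem-repeat
arrays that no 150 bp read can span: short-read assemblers collapse the CR to
a few hundred bases and the true mitogenome length is lost. `mitocr`
implements, as a tested and fully simulated pipeline, the strategy that
recovers such a CR from noisy long reads:

1. **Simulate** a circular ~22 kb mitogenome (13 protein genes, 2 rRNAs,
   22 tRNAs, ND5 translocated next to the CR) whose 6,929 bp CR carries two
   tandem arrays — motif A (40 bp × 24) and motif B (22 bp × 203) — with
   per-molecule copy-number heteroplasmy and ONT-like indel-dominated read
   errors including homopolymer deletions.
2. **QC** reads (probability-space mean quality ≥ Q10, length ≥ 1 kb; N50 and
   yield statistics).
3. **Extract CR-spanning reads** by edit-distance anchoring on the unique
   flanks, re-orienting everything to the plus strand.
4. **Discover the repeat motifs** (lag-p self-similarity + per-phase majority
   consensus) on a read polished by its peers, then **decompose** each
   spanning read's CR into motif arrays and count copies per read.
5. Take per-motif **modal copy numbers** across reads (heteroplasmy makes a
   single read untrustworthy) and **reconstruct a consensus CR**:
   representative read + per-phase majority voting across repeat copies +
   pairwise-alignment polish of the unique segments.
6. **Verify by in-silico PCR**: the CR's terminal 25-mers act as a primer
   pair on the raw reads and the product lengths are histogrammed in 100 bp
   bins.
7. **Reconcile and splice**: count coding-region discordances (with
   homopolymer classification) between a long-read-style draft and the
   accurate short-read backbone, then build the final hybrid genome — coding
   arc from the backbone, CR arc from the long-read consensus.
8. **Annotate** the hybrid by homology transfer from the reference, check
   gene order (ND5 next to the CR) and start/stop codons under the vertebrate
   mitochondrial code (AGA/AGG stops, incomplete `T`/`TA` stops).

The statistical core is the per-read copy-number estimator: a spanning read
decomposes into arrays by greedy copy-by-copy edit-distance tiling (per-copy
divergence ≤ 0.2), and the population estimate is the mode over reads

&nbsp;&nbsp;&nbsp;&nbsp;n̂ₘ = mode { countₘ(read r) : r spans the CR },

with the reconstructed CR length L = Σₘ n̂ₘ·pₘ + (unique flank and spacer
lengths). At 8% read error and heteroplasmy dispersion 1, 200 spanning reads
recover (24, 203) exactly and the consensus CR sits within 0.5% edit distance
of the truth.

## Worked example

```bash
mitocr run-all --seed 1 --out scratch/demo
# or, as a library / analysis narrative:
python analysis/03_resolve_cr.py
```

prints (seed 1):

```
spanning long reads: 196
motif A: period 40 bp, modal copies 24 (support 0.418)
motif B: period 22 bp, modal copies 203 (support 0.372)
reconstructed CR: 6907 bp (representative amp000014, 61 supporting reads)
edit distance to the simulated truth: 22 / 6929 (0.32%)
```

That is: of 200 simulated amplicon reads, 196 contain both CR flanks; the
modal copy numbers across reads equal the generator's blueprint exactly even
though individual molecules jitter by ±1–2 copies; and the reconstructed CR
differs from the true 6,929 bp sequence by 22 edits (0.32%). The remaining
drivers add the QC table (`02`), the in-silico PCR histogram (`04` — note the
modal bin sits one bin *below* the true length because 4% deletions against
2% insertions shrink every raw-read measurement by ~2%), the 15
coding-region discordant sites, mostly homopolymer-adjacent, that justify
taking the coding arc from short reads (`05`), and the transferred annotation
with its 37-gene inventory and codon table (`06`).

Each stage is exposed both as a library module (`mitocr.mitosim`,
`mitocr.readqc`, `mitocr.epcr`, `mitocr.repeats`, `mitocr.crres`,
`mitocr.reconcile`, `mitocr.annotate`, `mitocr.pipeline`) and as a CLI verb
(`mitocr simulate|qc|epcr|repeats|resolve-cr|splice|run-all|report`).

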