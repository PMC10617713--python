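#!/usr/bin/env python
"""In-silico PCR on the raw spanning reads: the terminal 25-mers of the
reconstructed CR act as a primer pair, and the primer-delimited product
lengths are binned in 100 bp bins (edges at ...6751-6850, 6851-6950...).

The modal bin sits below the true 6,929 bp CR: with deletion-dominated
errors (4% deletion vs 2% insertion) every measured product shrinks by
about 2%, a bias inherent to length measurement in raw nanopore reads."""

import shutil
from pathlib import Path

from mitocr import pipeline

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = pipeline.RunConfig(
        seed=1, outdir=str(SCRATCH), stages=("simulate", "qc", "resolve_cr", "epcr")
    )
    state = pipeline.RunState()
    report = pipeline.run_pipeline(cfg, state).as_dict()
    RESULTS.mkdir(exist_ok=True)
    shutil.copy(SCRATCH / "epcr_histogram.tsv", RESULTS / "04_epcr_histogram.tsv")
    print(f"products measured: {report['ePCR products measured']} "
          f"(Hamming primer matching rejects reads with indels in a primer site)")
    print(f"modal bin: {report['ePCR modal bin (bp)']} bp "
          f"({report['ePCR modal bin count']} products)")
    true_len = state.genome.cr_interval[1] - state.genome.cr_interval[0]
    print(f"true CR length: {true_len} bp; expected measurement bias ~"
          f"{0.02 * true_len:.0f} bp shortening from the deletion excess")


if __name__ == "__main__":
    main()
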