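"""CR resolution: spanning-read extraction, copy-number modes, reconstruction."""

import numpy as np
import pytest

from mitocr import crres, mitosim
from mitocr.repeats import Motif
from mitocr.seqio import Read, revcomp


def _clean_params(**kw):
    base = dict(substitution=0, insertion=0, deletion=0, hp_deletion=0,
                coverage=1.0, seed=11)
    base.update(kw)
    return mitosim.ReadSimParams(**base)


def _spanning_setup(genome, n_mols=8, dispersion=0.0, n_reads=40, params=None, seed=11):
    mols = mitosim.simulate_molecules(
        genome, mitosim.HeteroplasmyModel(dispersion), n_mols, seed
    )
    cs, ce = genome.cr_interval
    g2 = genome.sequence * 2
    fwd = g2[cs - 400 : cs - 375]
    rev = revcomp(g2[ce + 375 : ce + 400])
    reads = mitosim.simulate_amplicon_reads(
        mols, fwd, rev, params or _clean_params(), n_reads=n_reads
    )
    a5, a3 = crres.cr_anchors(genome.sequence, genome.cr_interval)
    return reads, a5, a3


class TestExtractSpanningReads:
    def test_error_free_interval_equals_truth(self, default_genome):
        reads, a5, a3 = _spanning_setup(default_genome)
        spanning = crres.extract_spanning_reads(reads, a5, a3)
        assert len(spanning) == len(reads)  # recall 1.0 at zero error
        cr = default_genome.cr_sequence
        for s in spanning:
            assert s.cr_sequence == cr
            assert s.anchor_mismatches == (0, 0)

    def test_read_with_single_anchor_excluded(self, default_genome):
        a5, a3 = crres.cr_anchors(default_genome.sequence, default_genome.cr_interval)
        cs, _ = default_genome.cr_interval
        read = Read("half", default_genome.sequence[cs - 200 : cs + 500],
                    np.full(700, 20))
        assert crres.extract_spanning_reads([read], a5, a3) == []

    def test_minus_strand_reads_reported_in_plus(self, default_genome):
        reads, a5, a3 = _spanning_setup(default_genome)
        flipped = [Read(r.id, revcomp(r.sequence), r.quality[::-1]) for r in reads]
        spanning = crres.extract_spanning_reads(flipped, a5, a3)
        cr = default_genome.cr_sequence
        assert len(spanning) == len(reads)
        assert all(s.cr_sequence == cr for s in spanning)

    def test_short_anchor_rejected(self):
        with pytest.raises(ValueError):
            crres.extract_spanning_reads([], "ACGT", "A" * 25)


class TestCopyNumbers:
    def test_error_free_counts_exact(self, default_genome, true_motifs):
        reads, a5, a3 = _spanning_setup(default_genome, n_reads=5)
        spanning = crres.extract_spanning_reads(reads, a5, a3)
        for s in spanning:
            assert crres.per_read_copy_numbers(s, true_motifs) == {"A": 24, "B": 203}

    def test_empty_cr_interval_gives_zeros(self, true_motifs):
        s = crres.SpanningRead("r", "ACGT" * 100, 200, 200, (0, 0), 20.0)
        assert crres.per_read_copy_numbers(s, true_motifs) == {"A": 0, "B": 0}

    def test_mode_unanimous(self, true_motifs):
        spanning = []
        for i in range(50):
            s = crres.SpanningRead(f"r{i}", "", 0, 0, (0, 0), 20.0)
            s.copy_estimates = {"A": 24, "B": 203}
            spanning.append(s)
        est = crres.copy_number_mode(spanning, true_motifs)
        assert est.modal_counts == {"A": 24, "B": 203}
        assert est.support == {"A": 1.0, "B": 1.0}

    def test_mode_tie_breaks_to_smaller_count(self, true_motifs):
        spanning = []
        for i in range(60):
            s = crres.SpanningRead(f"r{i}", "", 0, 0, (0, 0), 20.0)
            s.copy_estimates = {"A": 24, "B": 203 if i < 30 else 202}
            spanning.append(s)
        est = crres.copy_number_mode(spanning, true_motifs)
        assert est.modal_counts["B"] == 202

    def test_too_few_reads_rejected(self, true_motifs):
        s = crres.SpanningRead("r", "", 0, 0, (0, 0), 20.0)
        s.copy_estimates = {"A": 24, "B": 203}
        with pytest.raises(ValueError):
            crres.copy_number_mode([s] * 5, true_motifs, min_reads=10)


class TestReconstruction:
    def test_error_free_reconstruction_is_exact(self, default_genome, true_motifs):
        reads, a5, a3 = _spanning_setup(default_genome, n_reads=15)
        spanning = crres.extract_spanning_reads(reads, a5, a3)
        for s in spanning:
            crres.per_read_copy_numbers(s, true_motifs)
        est = crres.copy_number_mode(spanning, true_motifs)
        cr, info = crres.reconstruct_cr(spanning, true_motifs, est.modal_counts)
        assert cr == default_genome.cr_sequence
        assert not info["fallback"]

    def test_length_arithmetic_with_modal_counts(self, default_genome, true_motifs):
        reads, a5, a3 = _spanning_setup(default_genome, n_reads=15)
        spanning = crres.extract_spanning_reads(reads, a5, a3)
        for s in spanning:
            crres.per_read_copy_numbers(s, true_motifs)
        est = crres.copy_number_mode(spanning, true_motifs)
        # 24 x 40 + 203 x 22 + 1,503 bp of unique sequence = 6,929;
        # the estimate may absorb a few flank bases at array boundaries
        assert abs(est.length_estimate - (24 * 40 + 203 * 22 + 1503)) <= 15
        cr, _ = crres.reconstruct_cr(spanning, true_motifs, est.modal_counts)
        assert len(cr) == 6929

    def test_strand_invariance_with_conjugated_anchors(self, default_genome, true_motifs):
        reads, a5, a3 = _spanning_setup(default_genome, n_reads=12)

        def reconstruct(rs, x5, x3):
            spanning = crres.extract_spanning_reads(rs, x5, x3)
            for s in spanning:
                crres.per_read_copy_numbers(s, true_motifs)
            est = crres.copy_number_mode(spanning, true_motifs)
            return crres.reconstruct_cr(spanning, true_motifs, est.modal_counts)[0]

        fwd_cr = reconstruct(reads, a5, a3)
        flipped = [Read(r.id, revcomp(r.sequence), r.quality[::-1]) for r in reads]
        # viewing the CR from the other strand swaps and conjugates anchors
        rev_cr = reconstruct(flipped, revcomp(a3), revcomp(a5))
        assert rev_cr == revcomp(fwd_cr)


@pytest.fixture(scope="module")
def noisy(default_genome, true_motifs):
    params = mitosim.ReadSimParams(seed=21, coverage=1.0)  # 8% default error
    reads, a5, a3 = _spanning_setup(
        default_genome, n_mols=30, dispersion=1.0, n_reads=60,
        params=params, seed=21,
    )
    spanning = crres.extract_spanning_reads(reads, a5, a3)
    truth = {r.id: r.truth["copy_counts"] for r in reads}
    for s in spanning:
        crres.per_read_copy_numbers(s, true_motifs)
    return spanning, truth


class TestNoisySimulation:
    """Parameter recovery under ONT-like error (smaller than the headline
    study: 60 reads) -- the full-scale run lives in the acceptance tests."""

    def test_modes_recover_sampled_truth(self, noisy, true_motifs):
        """The estimator recovers the modal copy numbers of the molecules
        actually sampled (which at this scale may differ by one from the
        blueprint counts -- heteroplasmy sampling noise, not estimator bias)."""
        from collections import Counter

        spanning, truth = noisy
        est = crres.copy_number_mode(spanning, true_motifs)
        for mid in ("A", "B"):
            counter = Counter(truth[s.read_id][mid] for s in spanning)
            top = max(counter.values())
            # at 60 reads neighbouring counts can tie; the estimate must be
            # a count whose true frequency is statistically indistinguishable
            # from the top (within 3 reads)
            assert counter.get(est.modal_counts[mid], 0) >= top - 3

    def test_per_read_mad_small(self, noisy):
        spanning, truth = noisy
        devs = sorted(abs(s.copy_estimates["B"] - truth[s.read_id]["B"]) for s in spanning)
        mad = devs[len(devs) // 2]
        assert mad <= 3

    def test_reconstruction_close_to_modal_molecule(self, noisy, default_genome, true_motifs):
        import edlib

        spanning, _ = noisy
        est = crres.copy_number_mode(spanning, true_motifs)
        cr, _info = crres.reconstruct_cr(spanning, true_motifs, est.modal_counts)
        # reference: the CR a molecule carrying the modal counts would have
        ref = default_genome.spec.cr_spec.render(est.modal_counts)
        d = edlib.align(cr, ref, mode="NW")["editDistance"]
        assert d <= 0.005 * len(ref)
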