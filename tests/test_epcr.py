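"""In-silico PCR: primer matching, product lengths, histograms."""

import numpy as np
import pytest

from mitocr import epcr
from mitocr.seqio import Read, revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rand_seq(rng, n):
    return BASES[rng.integers(0, 4, n)].tobytes().decode()


def _brute_force_sites(sequence, primer, max_mismatch):
    hits = []
    for strand, pseq in (("+", primer.sequence), ("-", revcomp(primer.sequence))):
        for i in range(len(sequence) - len(pseq) + 1):
            mm = sum(a != b for a, b in zip(sequence[i : i + len(pseq)], pseq))
            if mm <= max_mismatch:
                hits.append((i, strand, mm))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


class TestFindPrimerSites:
    def test_exact_plus_strand_hit(self, rng):
        primer = epcr.Primer("p", "ACGTACGTACGTACGTACGT")
        seq = _rand_seq(rng, 50) + primer.sequence + _rand_seq(rng, 50)
        hits = [h for h in epcr.find_primer_sites(seq, primer, 0) if h[1] == "+"]
        assert (50, "+", 0) in hits

    def test_reverse_complement_hit(self, rng):
        primer = epcr.Primer("p", "ACGTACGTCCGGTTAAACGT")
        seq = _rand_seq(rng, 30) + revcomp(primer.sequence) + _rand_seq(rng, 30)
        hits = [h for h in epcr.find_primer_sites(seq, primer, 0) if h[1] == "-"]
        assert (30, "-", 0) in hits

    def test_equals_bruteforce_hamming_scan(self, rng):
        primer = epcr.Primer("p", _rand_seq(rng, 12))
        for _ in range(1000):
            seq = _rand_seq(rng, int(rng.integers(20, 120)))
            assert epcr.find_primer_sites(seq, primer, 3) == _brute_force_sites(
                seq, primer, 3
            )

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            epcr.Primer("p", "ACGTACGTA")

    def test_excessive_mismatch_budget_rejected(self):
        primer = epcr.Primer("p", "ACGTACGTAC")
        with pytest.raises(ValueError):
            epcr.find_primer_sites("ACGT" * 10, primer, 5)


class TestAmpliconLengths:
    def _primers(self):
        return (
            epcr.Primer("F", "ACGTTGCAACGGTTAACCGG"),
            epcr.Primer("R", "TTCCGGAATTGGCCAATTGG"),
        )

    def test_simple_product_arithmetic(self, rng):
        f, r = self._primers()
        middle = _rand_seq(rng, 60)
        read = Read("x", f.sequence + middle + revcomp(r.sequence))
        hits = epcr.amplicon_lengths([read], f, r, 0, min_len=10, max_len=1000)
        assert len(hits) == 1
        assert hits[0].length == 100
        assert (hits[0].start, hits[0].end) == (0, 100)

    def test_forward_primer_alone_yields_nothing(self, rng):
        f, r = self._primers()
        read = Read("x", _rand_seq(rng, 40) + f.sequence + _rand_seq(rng, 40))
        assert epcr.amplicon_lengths([read], f, r, 0, 10, 1000) == []

    def test_simulated_amplicons_yield_true_product_length(self, study_run):
        _cfg, state, _report = study_run
        from mitocr import mitosim

        cs, ce = state.genome.cr_interval
        g2 = state.genome.sequence * 2
        fwd = g2[cs - 300 : cs - 275]
        rev = revcomp(g2[ce + 275 : ce + 300])
        params = mitosim.ReadSimParams(
            substitution=0, insertion=0, deletion=0, hp_deletion=0, coverage=0.5, seed=6
        )
        reads = mitosim.simulate_amplicon_reads(state.genome, fwd, rev, params)
        hits = epcr.amplicon_lengths(
            reads, epcr.Primer("F", fwd), epcr.Primer("R", rev), 0, 1000, 30000
        )
        assert len(hits) == len(reads)
        for h in hits:
            assert h.length == 600 + (ce - cs)

    def test_strand_symmetry(self, rng):
        f, r = self._primers()
        reads = []
        for i in range(30):
            middle = _rand_seq(rng, int(rng.integers(20, 200)))
            reads.append(Read(f"r{i}", f.sequence + middle + revcomp(r.sequence)))
        fwd_lengths = sorted(h.length for h in epcr.amplicon_lengths(reads, f, r, 0, 10, 1000))
        flipped = [Read(x.id, revcomp(x.sequence)) for x in reads]
        rev_lengths = sorted(h.length for h in epcr.amplicon_lengths(flipped, f, r, 0, 10, 1000))
        assert fwd_lengths == rev_lengths


class TestHistogram:
    def test_bin_labels_match_convention(self):
        hist = epcr.build_histogram([6900] * 10)
        assert hist.labels() == ["6851-6950"]
        assert epcr.modal_bin(hist) == (6851, 6950, 10)

    def test_counts_conserved(self, rng):
        lengths = rng.integers(100, 10000, size=500)
        hist = epcr.build_histogram(list(lengths))
        assert int(hist.counts.sum()) == 500

    def test_modal_tie_breaks_to_smaller_bin(self):
        hist = epcr.build_histogram([100] * 5 + [300] * 5)
        low, high, count = epcr.modal_bin(hist)
        assert (low, high, count) == (51, 150, 5)

    def test_halving_bin_width_reaggregates(self, rng):
        lengths = list(rng.integers(500, 5000, size=400))
        coarse = epcr.build_histogram(lengths, 100)
        fine = epcr.build_histogram(lengths, 50)
        for edge, count in zip(coarse.edges, coarse.counts):
            fine_sum = sum(
                int(c) for e, c in zip(fine.edges, fine.counts) if edge <= e < edge + 100
            )
            assert fine_sum == int(count)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            epcr.build_histogram([])


def test_zero_error_zero_jitter_product_lengths_identical(default_genome):
    from mitocr import mitosim

    cs, ce = default_genome.cr_interval
    fwd, rev = epcr.cr_tip_primers(default_genome.cr_sequence)
    params = mitosim.ReadSimParams(
        substitution=0, insertion=0, deletion=0, hp_deletion=0, coverage=0.3, seed=7
    )
    mols = mitosim.simulate_molecules(default_genome, mitosim.HeteroplasmyModel(0.0), 4, 7)
    reads = mitosim.simulate_amplicon_reads(mols, fwd.sequence, rev.sequence, params)
    hits = epcr.amplicon_lengths(reads, fwd, rev, 0, 1000, 30000)
    lengths = {h.length for h in hits}
    assert lengths == {ce - cs}  # primer-inclusive product equals the CR length
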