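"""Synthetic genome construction and read simulation."""

import numpy as np
import pytest

from mitocr import mitosim
from mitocr.seqio import revcomp


class TestBuildGenome:
    def test_default_cr_is_6929_bp(self, default_spec):
        # 1,503 bp unique + 24 x 40 + 203 x 22
        assert default_spec.cr_spec.unique_length == 1503
        assert default_spec.cr_spec.length == 6929

    def test_default_total_is_22274_bp(self, default_genome):
        assert default_genome.spec.coding_length == 15345
        assert len(default_genome) == 22274

    def test_cr_feature_matches_interval(self, default_genome):
        cr = [f for f in default_genome.features if f.type == "CR"]
        assert len(cr) == 1
        assert (cr[0].start, cr[0].end) == default_genome.cr_interval

    def test_empty_arrays_cr_is_flanks_plus_spacers(self):
        cr = mitosim.CRSpec(flank5="ACGTACGTAC", flank3="TTGGCCAATT", arrays=[], spacers=[])
        assert cr.render() == "ACGTACGTAC" + "TTGGCCAATT"
        assert cr.length == 20

    def test_duplicate_gene_names_rejected(self, default_spec):
        blocks = list(default_spec.coding_blocks)
        blocks[0] = ("ND5", "tRNA", 70, "+")  # collides with the real ND5
        with pytest.raises(mitosim.SimulationError):
            mitosim.GenomeSpec(blocks, default_spec.cr_spec)

    def test_zero_length_block_rejected(self, default_spec):
        blocks = list(default_spec.coding_blocks) + [("extra", "tRNA", 0, "+")]
        with pytest.raises(mitosim.SimulationError):
            mitosim.GenomeSpec(blocks, default_spec.cr_spec)

    def test_deterministic_given_seed(self):
        g1 = mitosim.build_genome(mitosim.default_genome_spec(7))
        g2 = mitosim.build_genome(mitosim.default_genome_spec(7))
        assert g1.sequence == g2.sequence

    def test_nonperiodic_motifs_enforced(self):
        with pytest.raises(mitosim.SimulationError):
            mitosim.CRSpec(flank5="A" * 10, flank3="C" * 10, arrays=[("ACAC", 5)], spacers=[])


class TestHeteroplasmy:
    def test_dispersion_zero_molecules_identical(self, default_genome):
        mols = mitosim.simulate_molecules(
            default_genome, mitosim.HeteroplasmyModel(0.0), 5, seed=3
        )
        assert all(m.sequence == default_genome.sequence for m in mols)
        assert all(m.copy_counts == {"A": 24, "B": 203} for m in mols)

    def test_jitter_mean_matches_spec_counts(self, default_genome):
        mols = mitosim.simulate_molecules(
            default_genome, mitosim.HeteroplasmyModel(1.0), 1000, seed=3
        )
        counts = np.array([m.copy_counts["B"] for m in mols])
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 203) < 3 * se + 1e-9

    def test_zero_molecules_rejected(self, default_genome):
        with pytest.raises(mitosim.SimulationError):
            mitosim.simulate_molecules(default_genome, mitosim.HeteroplasmyModel(), 0)

    def test_jitter_below_one_copy_rejected(self, default_genome):
        spec = mitosim.default_genome_spec(1)
        spec.cr_spec.arrays[0] = (spec.cr_spec.arrays[0][0], 1)  # fragile array
        g = mitosim.build_genome(spec)
        with pytest.raises(mitosim.SimulationError):
            mitosim.simulate_molecules(g, mitosim.HeteroplasmyModel(25.0), 200, seed=0)


def _clean_params(**kw):
    base = dict(substitution=0, insertion=0, deletion=0, hp_deletion=0, seed=5)
    base.update(kw)
    return mitosim.ReadSimParams(**base)


class TestLongReads:
    def test_error_free_reads_are_exact_substrings(self, default_genome):
        mols = mitosim.simulate_molecules(default_genome, mitosim.HeteroplasmyModel(), 3, 1)
        reads = mitosim.simulate_long_reads(mols, _clean_params(coverage=1.0))
        for r in reads:
            t = r.truth
            frag = (mols[t["molecule"]].sequence * 2)[t["start"] : t["end"]]
            if t["strand"] == "-":
                frag = revcomp(frag)
            assert r.sequence == frag

    @pytest.mark.parametrize(
        "channel,rate",
        [("substitution", 0.02), ("insertion", 0.02), ("deletion", 0.04)],
    )
    def test_per_channel_error_rate_binomial(self, default_genome, channel, rate):
        """Each error channel in isolation admits an exact binomial check:
        substitutions via Hamming distance, indels via length change."""
        params = mitosim.ReadSimParams(
            **{"substitution": 0.0, "insertion": 0.0, "deletion": 0.0, channel: rate},
            hp_deletion=0.0, fixed_length=5000, coverage=5.0, seed=9,
        )
        mols = [mitosim.Molecule(default_genome.sequence, {})]
        reads = mitosim.simulate_long_reads(mols, params)
        total = events = 0
        for r in reads:
            t = r.truth
            frag = (mols[0].sequence * 2)[t["start"] : t["end"]]
            if t["strand"] == "-":
                frag = revcomp(frag)
            if channel == "substitution":
                events += sum(a != b for a, b in zip(r.sequence, frag))
            elif channel == "deletion":
                events += len(frag) - len(r.sequence)
            else:
                events += len(r.sequence) - len(frag)
            total += len(frag)
            if total > 1e5:
                break
        sigma = np.sqrt(rate * (1 - rate) / total)
        assert abs(events / total - rate) < 3 * sigma

    def test_fixed_length_reads_span_cr_from_upstream_starts(self, default_genome):
        cs, ce = default_genome.cr_interval
        params = _clean_params(fixed_length=20000, coverage=3.0)
        mols = [mitosim.Molecule(default_genome.sequence, {"A": 24, "B": 203})]
        reads = mitosim.simulate_long_reads(mols, params)
        for r in reads:
            start = r.truth["start"]
            if start <= cs - 2000 and r.truth["end"] >= ce:
                cr = default_genome.cr_sequence
                seq = r.sequence if r.truth["strand"] == "+" else revcomp(r.sequence)
                assert cr in seq

    def test_quality_encodes_configured_accuracy(self, default_genome):
        params = mitosim.ReadSimParams(
            substitution=0.05, insertion=0.02, deletion=0.03, coverage=0.1, seed=2
        )
        mols = [mitosim.Molecule(default_genome.sequence, {})]
        reads = mitosim.simulate_long_reads(mols, params)
        assert all(int(r.quality[0]) == 10 for r in reads)  # -10 log10(0.1)

    def test_invalid_rates_rejected(self):
        with pytest.raises(mitosim.SimulationError):
            mitosim.ReadSimParams(substitution=1.2)
        with pytest.raises(mitosim.SimulationError):
            mitosim.ReadSimParams(coverage=0)


class TestShortReads:
    def test_error_free_pairs_are_exact_150mers(self, default_genome):
        mols = [mitosim.Molecule(default_genome.sequence, {})]
        reads = mitosim.simulate_short_reads(mols, coverage=1.0, error_rate=0.0, seed=4)
        doubled = mols[0].sequence * 2
        for r in reads:
            assert len(r) == 150
            t = r.truth
            frag = doubled[t["start"] : t["end"]]
            if t["strand"] == "-":
                frag = revcomp(frag)
            expect = frag[:150] if t["mate"] == "1" else revcomp(frag[-150:])
            assert r.sequence == expect

    def test_coverage_arithmetic(self, default_genome):
        mols = [mitosim.Molecule(default_genome.sequence, {})]
        reads = mitosim.simulate_short_reads(mols, coverage=100.0, seed=4)
        total = sum(len(r) for r in reads)
        assert abs(total - 100 * 22274) <= 0.05 * 100 * 22274

    def test_insert_shorter_than_read_rejected(self, default_genome):
        mols = [mitosim.Molecule(default_genome.sequence, {})]
        with pytest.raises(mitosim.SimulationError):
            mitosim.simulate_short_reads(mols, read_len=300, insert_mean=200.0)


class TestAmpliconReads:
    def test_full_length_reads_equal_product_length(self, default_genome):
        cs, ce = default_genome.cr_interval
        g2 = default_genome.sequence * 2
        fwd = g2[cs - 500 : cs - 475]
        rev = revcomp(g2[ce + 475 : ce + 500])
        reads = mitosim.simulate_amplicon_reads(
            default_genome, fwd, rev, _clean_params(coverage=0.5)
        )
        expect = (ce + 500) - (cs - 500)
        assert all(len(r) == expect for r in reads)
        assert all(r.truth["product_length"] == expect for r in reads)

    def test_absent_primer_rejected(self, default_genome):
        with pytest.raises(mitosim.SimulationError):
            mitosim.simulate_amplicon_reads(
                default_genome, "T" * 25, "G" * 25, _clean_params()
            )

    def test_heteroplasmic_length_spread_mirrors_copy_jitter(self, default_genome):
        mols = mitosim.simulate_molecules(
            default_genome, mitosim.HeteroplasmyModel(2.0), 50, seed=8
        )
        cs, ce = default_genome.cr_interval
        g2 = default_genome.sequence * 2
        fwd = g2[cs - 500 : cs - 475]
        rev = revcomp(g2[ce + 475 : ce + 500])
        reads = mitosim.simulate_amplicon_reads(mols, fwd, rev, _clean_params(coverage=2.0))
        base = 1000 + 1503  # flanks outside CR + unique CR sequence
        for r in reads:
            cc = r.truth["copy_counts"]
            assert len(r) == base + 40 * cc["A"] + 22 * cc["B"]


class TestDraftAssembly:
    def test_planted_error_count_and_classes(self, default_genome):
        seq, edits = mitosim.simulate_draft_assembly(default_genome, 15, seed=3)
        assert len(edits) == 15
        dels = [e for e in edits if e[1] == "deletion"]
        assert len(dels) == 9  # 60% homopolymer deletions
        assert len(seq) == len(default_genome) - len(dels)
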