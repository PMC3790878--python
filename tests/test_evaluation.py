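"""Bray-Curtis metrics, fixtures and provenance alignments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgsim.coverage_model import CoverageProfile
from mgsim.error_model import count_error_types
from mgsim.evaluation import (
    bc_distance,
    coverage_compare,
    make_fixture,
    oracle_alignments,
    true_alignments,
)
from mgsim.simulator import (
    LengthModel,
    SimulationConfig,
    simulate,
)
from mgsim.error_model import ErrorModel


class TestBCDistance:
    def test_error_triples_from_single_genome_run(self):
        # simulated vs observed (ins, del, sub) shares of an Illumina
        # single-genome run agree to BC 0.00012
        x = (0.00498, 0.00985, 0.98518)
        y = (0.00489, 0.00997, 0.98514)
        assert round(bc_distance(x, y), 5) == 0.00012

    def test_error_triples_from_mock_metagenome_run(self):
        x = (0.0359, 0.0171, 0.9470)
        y = (0.0361, 0.0171, 0.9468)
        assert round(bc_distance(x, y), 4) == 0.0002

    def test_identity_and_disjointness(self):
        assert bc_distance((0.2, 0.8), (0.2, 0.8)) == 0.0
        assert bc_distance((1.0, 0.0), (0.0, 1.0)) == 1.0

    def test_scaling_invariance(self):
        assert bc_distance((1, 2, 3), (10, 20, 30)) == pytest.approx(0.0)

    def test_label_alignment(self):
        a = {"x": 0.5, "y": 0.5}
        b = {"y": 0.5, "x": 0.5}
        assert bc_distance(a, b) == pytest.approx(0.0)

    def test_mismatched_labels_rejected(self):
        with pytest.raises(ValueError, match="label"):
            bc_distance({"x": 1.0}, {"z": 1.0})

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            bc_distance((1, 2), (1, 2, 3))

    @settings(max_examples=200, deadline=None)
    @given(
        vecs=st.tuples(
            st.lists(st.floats(min_value=0, max_value=100), min_size=2, max_size=6),
            st.lists(st.floats(min_value=0, max_value=100), min_size=2, max_size=6),
        ).filter(lambda t: len(t[0]) == len(t[1]) and sum(t[0]) > 0 and sum(t[1]) > 0)
    )
    def test_semimetric_properties(self, vecs):
        x, y = (np.array(v) for v in vecs)
        d = bc_distance(x, y)
        assert 0.0 <= d <= 1.0 + 1e-12
        assert d == pytest.approx(bc_distance(y, x))
        # closed form on normalized inputs: half the L1 distance
        xn, yn = x / x.sum(), y / y.sum()
        assert d == pytest.approx(0.5 * np.abs(xn - yn).sum(), abs=1e-12)
        assert bc_distance(x, x) == pytest.approx(0.0)


class TestCoverageCompare:
    def prof(self, weights, gid="g"):
        w = np.asarray(weights, dtype=float)
        return CoverageProfile(gid, len(w) * 100, w)

    def test_identical_profiles(self):
        a = self.prof([1, 2, 3, 4])
        assert coverage_compare(a, self.prof([1, 2, 3, 4])) == pytest.approx((0.0, 1.0))

    def test_rescaled_profile(self):
        bc, r = coverage_compare(self.prof([1, 2, 3, 4]), self.prof([3, 6, 9, 12]))
        assert bc == pytest.approx(0.0)
        assert r == pytest.approx(1.0)

    def test_anticorrelated_profiles(self):
        bc, r = coverage_compare(self.prof([1, 9]), self.prof([9, 1]))
        assert bc == pytest.approx(0.8)
        assert r == pytest.approx(-1.0)

    def test_first_n_truncation(self):
        a = self.prof([1, 2, 3, 100])
        b = self.prof([1, 2, 3, 0.1])
        bc, r = coverage_compare(a, b, first_n_intervals=3)
        assert bc == pytest.approx(0.0)

    def test_mismatched_profiles_rejected(self):
        with pytest.raises(ValueError, match="genome"):
            coverage_compare(self.prof([1, 2]), self.prof([1, 2], gid="h"))


class TestMakeFixture:
    @pytest.mark.parametrize(
        "preset, n, top",
        [("LC", 2, 0.9), ("MC", 9, 0.25), ("HC", 11, 1 / 11)],
    )
    def test_presets(self, preset, n, top):
        fx = make_fixture(preset=preset, genome_length=2000, seed=1)
        assert len(fx.db) == n
        assert max(fx.composition.entries.values()) == pytest.approx(top)
        assert sum(fx.composition.entries.values()) == pytest.approx(1.0)

    def test_mc_has_five_levels_two_dominant(self):
        fx = make_fixture(preset="MC", genome_length=2000, seed=1)
        values = sorted(fx.composition.entries.values(), reverse=True)
        assert len({round(v, 9) for v in values}) == 5
        assert values[0] == values[1] == pytest.approx(0.25)

    def test_determinism(self):
        a = make_fixture(preset="LC", genome_length=3000, seed=33, bias=True)
        b = make_fixture(preset="LC", genome_length=3000, seed=33, bias=True)
        assert a.db.entries == b.db.entries
        for g in a.profiles:
            np.testing.assert_array_equal(a.profiles[g].weights,
                                          b.profiles[g].weights)

    def test_gc_content_is_respected(self):
        fx = make_fixture(n_genomes=1, genome_length=50_000, gc=0.3, seed=2)
        seq = next(iter(fx.db.entries.values()))
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.3, abs=0.01)


def simulated_reads(n=50, model=None, seed=4):
    fx = make_fixture(preset="LC", genome_length=4000, seed=21)
    cfg = SimulationConfig(total_reads=n, seed=seed,
                           length_model=LengthModel.fixed(60))
    return fx, list(simulate(fx.composition, fx.db, model, cfg))


class TestOracleAlignments:
    def test_alignment_matches_provenance(self):
        fx, reads = simulated_reads()
        for read, aln in zip(reads, oracle_alignments(reads)):
            assert aln.genome_id == read.genome_id
            assert aln.start == read.start
            assert aln.cigar == [("M", len(read.sequence))]
            assert aln.is_mapped

    def test_foreign_id_rejected(self):
        from mgsim.seq_io import ReadRecord

        with pytest.raises(ValueError, match="provenance"):
            list(oracle_alignments([ReadRecord("SRR000.1", "ACGT")]))


class TestTrueAlignments:
    def test_error_free_reads_are_all_match(self):
        fx, reads = simulated_reads()
        for read, aln in zip(reads, true_alignments(reads)):
            assert aln.cigar == [("M", 60)]
            assert aln.md == "60"
            assert aln.nm == 0

    def test_error_counts_round_trip_exactly(self):
        # harvesting CIGAR/MD from reconstructed alignments recovers the
        # injected error tallies with no slack
        model = ErrorModel.platform_default("454", n_cycles=80)
        fx, reads = simulated_reads(n=400, model=model)
        counts = count_error_types(true_alignments(reads))
        assert counts.ins == sum(r.n_ins for r in reads)
        assert counts.dels == sum(r.n_del for r in reads)
        assert counts.subs == sum(r.n_sub for r in reads)
        assert counts.pairs.sum() == counts.subs

    def test_cigar_query_length_matches_read(self):
        model = ErrorModel.platform_default("illumina", n_cycles=80)
        _, reads = simulated_reads(n=300, model=model, seed=6)
        for read, aln in zip(reads, true_alignments(reads)):
            assert aln.query_length() == len(read.sequence)
            assert aln.reference_length() == read.end - read.start
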