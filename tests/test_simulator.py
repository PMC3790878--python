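"""Read generation: allocation, fragments, error injection, determinism."""

import numpy as np
import pytest

from mgsim.composition import CommunityComposition
from mgsim.error_model import (
    DEFAULT_SUBMAT,
    ErrorModel,
    ErrorTypeProportions,
    QualityDistribution,
)
from mgsim.evaluation import make_fixture
from mgsim.seq_io import GenomeDB, revcomp
from mgsim.simulator import (
    LengthModel,
    SimulationConfig,
    allocate_reads,
    extract_fragment,
    inject_errors,
    sample_length,
    simulate,
    write_simulated_fastq,
)


class TestAllocateReads:
    def test_expected_counts_weight_abundance_by_size(self, rng):
        # abundances 0.4/0.6 with sizes 15 and 10 Mbp have equal expected
        # read numbers: 1 million each out of 2 million
        comp = CommunityComposition({"gA": 0.4, "gB": 0.6})
        mass = np.array([0.4 * 15e6, 0.6 * 10e6])
        p = mass / mass.sum()
        np.testing.assert_allclose(p, [0.5, 0.5])
        expected = 2_000_000 * p
        np.testing.assert_allclose(expected, [1_000_000, 1_000_000])

    def test_counts_sum_exactly(self, rng, tiny_db):
        comp = CommunityComposition({"gA": 0.3, "gB": 0.7})
        counts = allocate_reads(comp, tiny_db, 999, rng)
        assert sum(counts.values()) == 999

    def test_single_genome_is_deterministic(self, rng, tiny_db):
        comp = CommunityComposition({"gA": 1.0})
        assert allocate_reads(comp, tiny_db, 1234, rng) == {"gA": 1234}

    def test_realized_counts_near_expectation(self, rng):
        # abundances 0.5/0.5 at sizes 10 vs 20 Mbp: expected 1M vs 2M of 3M
        db = GenomeDB({"gA": "A" * 1000, "gB": "C" * 2000})
        comp = CommunityComposition({"gA": 0.5, "gB": 0.5})
        total = 300_000
        counts = allocate_reads(comp, db, total, rng)
        p = 1 / 3
        sigma = np.sqrt(total * p * (1 - p))
        assert abs(counts["gA"] - total * p) < 4 * sigma


class TestSampleLength:
    def test_fixed(self, rng):
        assert sample_length(LengthModel.fixed(75), rng) == 75

    def test_explicit_point_mass(self, rng):
        model = LengthModel.explicit([193], [1.0])
        assert sample_length(model, rng) == 193

    def test_normal_mean(self, rng):
        model = LengthModel.normal(250, 10, 60, 400)
        draws = model.sample_batch(10_000, rng)
        se = 10 / np.sqrt(10_000)
        assert abs(draws.mean() - 250) < 3 * se
        assert draws.min() >= 60 and draws.max() <= 400

    def test_empty_explicit_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            LengthModel.explicit([], [])


class TestExtractFragment:
    def test_forward(self):
        db = GenomeDB({"g": "ACGTACGT"})
        assert extract_fragment(db, "g", 2, 4, "+") == "GTAC"

    def test_reverse_complement(self):
        db = GenomeDB({"g": "AACCG"})
        assert extract_fragment(db, "g", 0, 5, "-") == "CGGTT"

    def test_out_of_bounds(self):
        db = GenomeDB({"g": "ACGTACGT"})
        with pytest.raises(ValueError, match="outside"):
            extract_fragment(db, "g", 6, 4, "+")


def model_with(p_ins, p_del, p_sub, q, n_cycles=200, platform="454"):
    return ErrorModel(
        platform=platform,
        qdist=QualityDistribution.point_mass(q, n_cycles),
        props=ErrorTypeProportions(p_ins, p_del, p_sub),
        submat=DEFAULT_SUBMAT[platform],
    )


class TestInjectErrors:
    def test_high_quality_means_no_errors(self, rng):
        # q=62 -> p ~ 6.3e-7; a thousand 100-mers stay essentially exact
        model = model_with(0.2, 0.15, 0.65, q=62)
        template = "ACGT" * 30
        exact = 0
        for _ in range(1000):
            res = inject_errors(template, model, rng, length=100)
            exact += res.sequence == template[:100]
        assert exact >= 999

    def test_forced_substitution_changes_every_base(self, rng):
        model = model_with(0.0, 0.0, 1.0, q=0)
        template = "ACGT" * 25
        res = inject_errors(template, model, rng, length=100)
        assert res.n_sub == 100
        assert all(a != b for a, b in zip(res.sequence, template))
        assert len(res.sequence) == 100

    def test_error_type_shares_match_proportions(self, rng):
        # 454 default proportions (0.2, 0.15, 0.65) recovered within 3
        # multinomial sigmas from the injected-error tallies
        model = model_with(0.2, 0.15, 0.65, q=13)  # p ~ 0.05
        template = "ACGTACGTAC" * 30
        tot = np.zeros(3)
        for _ in range(3000):
            res = inject_errors(template, model, rng, length=100)
            tot += (res.n_ins, res.n_del, res.n_sub)
        n = tot.sum()
        for share, p in zip(tot / n, (0.2, 0.15, 0.65)):
            assert abs(share - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_qualities_cover_every_emitted_base(self, rng):
        model = model_with(0.2, 0.15, 0.65, q=5)
        res = inject_errors("ACGT" * 40, model, rng, length=100)
        assert len(res.sequence) == 100
        assert len(res.qualities) == 100


def hc_setup(n_cycles=100):
    fx = make_fixture(preset="LC", genome_length=5000, seed=5)
    return fx.db, fx.composition


class TestSimulate:
    def test_error_free_reads_are_exact_substrings(self):
        db, comp = hc_setup()
        cfg = SimulationConfig(total_reads=100, seed=1,
                               length_model=LengthModel.fixed(60))
        for read in simulate(comp, db, None, cfg):
            genome = db.entries[read.genome_id]
            frag = genome[read.start : read.end]
            expected = revcomp(frag) if read.strand == "-" else frag
            assert read.sequence == expected

    def test_same_seed_gives_identical_fastq(self, tmp_path):
        db, comp = hc_setup()
        model = ErrorModel.platform_default("454", n_cycles=80)
        cfg = SimulationConfig(total_reads=300, seed=42,
                               length_model=LengthModel.fixed(70))
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        write_simulated_fastq(simulate(comp, db, model, cfg), p1)
        write_simulated_fastq(simulate(comp, db, model, cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_total_read_count_is_exact(self):
        db, comp = hc_setup()
        cfg = SimulationConfig(total_reads=501, seed=2,
                               length_model=LengthModel.fixed(40))
        assert sum(1 for _ in simulate(comp, db, None, cfg)) == 501

    def test_per_genome_counts_near_binomial(self, rng):
        db = GenomeDB({"gA": "ACGT" * 1500, "gB": "TTCA" * 1500})
        comp = CommunityComposition({"gA": 0.5, "gB": 0.5})
        cfg = SimulationConfig(total_reads=20_000, seed=9,
                               length_model=LengthModel.fixed(50))
        reads = list(simulate(comp, db, None, cfg))
        n_a = sum(r.genome_id == "gA" for r in reads)
        sigma = np.sqrt(20_000 * 0.25)
        assert abs(n_a - 10_000) < 4 * sigma

    def test_genome_shorter_than_read_rejected(self):
        db = GenomeDB({"g": "ACGT" * 10})
        comp = CommunityComposition({"g": 1.0})
        cfg = SimulationConfig(total_reads=10, seed=0,
                               length_model=LengthModel.fixed(100))
        with pytest.raises(ValueError, match="shorter than"):
            list(simulate(comp, db, None, cfg))

    def test_read_ids_carry_provenance(self):
        db, comp = hc_setup()
        cfg = SimulationConfig(total_reads=5, seed=3,
                               length_model=LengthModel.fixed(50))
        for read in simulate(comp, db, None, cfg):
            prefix, gid, lo, hi, strand, serial = read.read_id.split("|")
            assert prefix == "MGSIM" and gid == read.genome_id
            assert (int(lo), int(hi), strand) == (read.start, read.end, read.strand)


class TestPairedEnd:
    def make(self, seed=0, n=400):
        fx = make_fixture(n_genomes=2, genome_length=5000, seed=8)
        cfg = SimulationConfig(
            total_reads=n, seed=seed, paired=True,
            insert_mean=300, insert_sd=20,
            length_model=LengthModel.fixed(60),
        )
        return fx, list(simulate(fx.composition, fx.db, None, cfg))

    def test_pairs_count_as_two_reads(self):
        _, reads = self.make(n=400)
        assert len(reads) == 400
        assert sum(r.mate == 1 for r in reads) == 200
        assert sum(r.mate == 2 for r in reads) == 200

    def test_mates_share_serial_and_oppose_strands(self):
        _, reads = self.make()
        by_serial = {}
        for r in reads:
            serial = r.read_id.split("|")[-1].split("/")[0]
            by_serial.setdefault(serial, []).append(r)
        for pair in by_serial.values():
            assert len(pair) == 2
            r1, r2 = sorted(pair, key=lambda r: r.mate)
            assert r1.genome_id == r2.genome_id
            assert {r1.strand, r2.strand} == {"+", "-"}
            assert r1.read_id.endswith("/1") and r2.read_id.endswith("/2")

    def test_mate_span_respects_insert_model(self):
        fx, reads = self.make()
        spans = []
        by_serial = {}
        for r in reads:
            by_serial.setdefault(r.read_id.split("|")[-1].split("/")[0], []).append(r)
        for pair in by_serial.values():
            lo = min(r.start for r in pair)
            hi = max(r.end for r in pair)
            spans.append(hi - lo)
        spans = np.array(spans)
        se = 20 / np.sqrt(len(spans))
        assert abs(spans.mean() - 300) < 5 * se

    def test_mates_are_genome_substrings(self):
        fx, reads = self.make()
        for r in reads:
            genome = fx.db.entries[r.genome_id]
            frag = genome[r.start : r.end]
            expected = revcomp(frag) if r.strand == "-" else frag
            assert r.sequence == expected

    def test_odd_total_rejected(self):
        with pytest.raises(ValueError, match="even"):
            SimulationConfig(total_reads=11, paired=True,
                             insert_mean=300, insert_sd=10,
                             length_model=LengthModel.fixed(50))

    def test_insert_shorter_than_reads_rejected(self):
        with pytest.raises(ValueError, match="insert"):
            SimulationConfig(total_reads=10, paired=True,
                             insert_mean=80, insert_sd=5,
                             length_model=LengthModel.fixed(60))
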