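"""Read classification, G-score filtering, decontamination, abundance."""

import math

import pytest

from twobrad.enzyme import BCGI, canonicalize, reverse_complement
from twobrad.profiler import (
    REJECT,
    ProfileConfig,
    ReadSet,
    SpeciesHit,
    classify_reads,
    decontaminate,
    estimate_abundance,
    extract_read_tag,
    filter_candidates,
    g_score,
    host_fraction,
    profile_sample,
)
from twobrad.simulate import CommunitySpec, simulate_reads
from twobrad.tagdb import build_tag_db_from_sequences, species_specific_tags
from tests.conftest import plant_tag, random_dna


@pytest.fixture
def two_species_db(rng):
    genomes = {}
    for sp in ("spA", "spB"):
        pieces = []
        for _ in range(8):
            pieces.append(random_dna(rng, 80))
            pieces.append(plant_tag(rng))
        genomes[sp] = "".join(pieces)
    return build_tag_db_from_sequences(genomes, BCGI)


class TestExtractReadTag:
    def test_exact_length_read_is_canonicalized(self, rng):
        tag = plant_tag(rng)
        assert extract_read_tag(tag, BCGI) == canonicalize(tag)
        assert extract_read_tag(reverse_complement(tag), BCGI) == canonicalize(tag)

    def test_short_read_rejected(self, rng):
        assert extract_read_tag(random_dna(rng, 31), BCGI) is REJECT

    def test_n_in_read_rejected(self, rng):
        tag = plant_tag(rng)
        assert extract_read_tag("N" + tag[1:], BCGI) is REJECT

    def test_adapter_trailing_read_recovers_tag(self, rng):
        # window-scan oracle: the planted tag sits at offset 0 of a 36-mer
        for _ in range(20):
            tag = plant_tag(rng)
            read = tag + random_dna(rng, 4)
            result = extract_read_tag(read, BCGI)
            # ambiguous only if the adapter bases created a second pattern hit
            if result is not REJECT:
                assert result == canonicalize(tag)

    def test_ambiguous_double_site_rejected(self, rng):
        t1, t2 = plant_tag(rng), plant_tag(rng)
        read = t1 + t2  # two distinct candidate windows
        assert extract_read_tag(read, BCGI) is REJECT


class TestClassifyReads:
    def test_single_species_reads(self, two_species_db, rng):
        tags = sorted(species_specific_tags(two_species_db)["spA"])
        reads = [tags[i % len(tags)] for i in range(100)]
        result = classify_reads(ReadSet("s", reads), two_species_db)
        assert result.species_reads == {"spA": 100}
        assert result.unassigned_reads == result.shared_tag_reads == 0

    def test_host_takes_precedence(self, two_species_db, rng):
        tags_a = sorted(species_specific_tags(two_species_db)["spA"])
        host_reads = [random_dna(rng, 32) for _ in range(90)]
        host_tags = frozenset(canonicalize(r) for r in host_reads)
        reads = host_reads + tags_a[:1] * 10
        result = classify_reads(ReadSet("s", reads), two_species_db, host_tags)
        assert result.host_reads == 90
        assert result.species_reads == {"spA": 10}

    def test_unknown_tag_unassigned_and_conservation(self, two_species_db, rng):
        tags_a = sorted(species_specific_tags(two_species_db)["spA"])
        reads = tags_a[:3] + [random_dna(rng, 32) for _ in range(7)]
        result = classify_reads(ReadSet("s", reads), two_species_db)
        total = (result.host_reads + result.shared_tag_reads
                 + result.unassigned_reads + sum(result.species_reads.values()))
        assert total == result.total_reads == 10


class TestGScore:
    @pytest.mark.parametrize("reads,markers,expected", [
        (25, 1, 5.0),
        (0, 0, 0.0),
        (16, 4, 8.0),
    ])
    def test_values(self, reads, markers, expected):
        assert g_score(reads, markers) == pytest.approx(expected, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            g_score(-1, 2)

    def test_monotone_in_reads(self):
        scores = [g_score(s, 3) for s in range(1, 50)]
        assert scores == sorted(scores)


class TestFilterCandidates:
    def make_hit(self, sp, s, t):
        return SpeciesHit(species_id=sp, reads_assigned=s,
                          markers_detected=t, markers_total=100)

    def test_boundary_retained_below_discarded(self):
        # G values: sqrt(24.01)=4.9, sqrt(25)=5.0, sqrt(144)=12
        hits = [self.make_hit("a", 24, 1), self.make_hit("b", 25, 1),
                self.make_hit("c", 36, 4)]
        kept = filter_candidates(hits, 5.0)
        assert [h.species_id for h in kept] == ["b", "c"]

    def test_zero_threshold_keeps_all(self):
        hits = [self.make_hit("a", 0, 0)]
        assert filter_candidates(hits, 0.0) == hits

    def test_empty_input(self):
        assert filter_candidates([], 5.0) == []


class TestDecontaminate:
    def test_per_taxon_scaled_hand_arithmetic(self):
        # T=1000, N=100: D_i = 2 × 10 = 20; 50 − 20 = 30
        out = decontaminate({"x": 50}, {"x": 2}, 1000, 100,
                            mode="per_taxon_scaled")
        assert out == {"x": 30}

    def test_taxon_absent_from_control_unchanged(self):
        out = decontaminate({"x": 50, "y": 8}, {"x": 0}, 1000, 100)
        assert out == {"x": 50, "y": 8}

    def test_off_mode_identity(self):
        counts = {"x": 5, "y": 7}
        assert decontaminate(counts, None, 10, 0, mode="off") == counts

    def test_zeroed_taxa_dropped(self):
        out = decontaminate({"x": 10}, {"x": 5}, 1000, 100)
        assert out == {}

    def test_missing_control_errors(self):
        with pytest.raises(ValueError):
            decontaminate({"x": 1}, None, 10, 5)
        with pytest.raises(ValueError):
            decontaminate({"x": 1}, {"x": 1}, 10, 0)

    def test_literal_global_clips_at_zero(self):
        # D = 1000 × 10 = 10000 spread over the control's single taxon
        out = decontaminate({"x": 50, "y": 20}, {"x": 2}, 1000, 100,
                            mode="literal_global")
        assert out == {"y": 20}


class TestEstimateAbundance:
    def make_hit(self, sp, reads, markers):
        return SpeciesHit(species_id=sp, reads_assigned=reads,
                          markers_detected=min(reads, markers),
                          markers_total=markers)

    def test_coverage_normalization_closed_form(self):
        hits = [self.make_hit("a", 100, 1000), self.make_hit("b", 100, 500)]
        out = estimate_abundance(hits)
        assert out[0].relative_abundance == pytest.approx(1 / 3)
        assert out[1].relative_abundance == pytest.approx(2 / 3)

    def test_single_species_gets_one(self):
        out = estimate_abundance([self.make_hit("a", 7, 40)])
        assert out[0].relative_abundance == 1.0

    def test_equal_coverages_symmetric(self):
        hits = [self.make_hit(f"s{i}", 50, 200) for i in range(5)]
        out = estimate_abundance(hits)
        for h in out:
            assert h.relative_abundance == pytest.approx(0.2)

    def test_zero_marker_hit_rejected(self):
        bad = SpeciesHit(species_id="a", reads_assigned=5,
                         markers_detected=1, markers_total=0)
        with pytest.raises(ValueError):
            estimate_abundance([bad])


class TestProfileSample:
    def _genomes(self, rng, species, n_tags=8):
        genomes = {}
        for sp in species:
            pieces = []
            for _ in range(n_tags):
                pieces.append(random_dna(rng, 80))
                pieces.append(plant_tag(rng))
            genomes[sp] = "".join(pieces)
        return genomes

    def test_single_species_perfect_recovery(self, rng):
        genomes = self._genomes(rng, ["only"])
        db = build_tag_db_from_sequences(genomes, BCGI)
        spec = CommunitySpec({"only": 1.0}, n_reads=500, seed=3)
        readset, _ = simulate_reads(spec, genomes, BCGI)
        profile = profile_sample(readset, db)
        assert profile.abundances() == {"only": 1.0}
        assert profile.host_reads == 0

    def test_host_spike_invariance(self, rng):
        # appending host-tag reads to the identical microbial read list
        # must leave the microbial profile exactly unchanged
        genomes = self._genomes(rng, ["spA", "spB"])
        db = build_tag_db_from_sequences(genomes, BCGI)
        from twobrad.simulate import synth_host_genome
        _, host_tags = synth_host_genome(50_000, BCGI, seed=9)
        base = CommunitySpec({"spA": 0.5, "spB": 0.5}, n_reads=2000, seed=5)
        reads0, _ = simulate_reads(base, genomes, BCGI)
        host_list = sorted(host_tags)
        spike = [host_list[i % len(host_list)] for i in range(18_000)]
        reads9 = ReadSet("spiked", list(reads0.reads) + spike)
        p0 = profile_sample(reads0, db, host_tags)
        p9 = profile_sample(reads9, db, host_tags)
        assert p9.host_reads == 18_000
        assert p9.abundances() == p0.abundances()

    def test_read_accounting_and_abundance_sum(self, small_mock):
        db = build_tag_db_from_sequences(small_mock.genomes, BCGI)
        profile = profile_sample(small_mock.readset, db, small_mock.host_tags)
        assigned = profile.total_reads - profile.host_reads \
            - profile.shared_tag_reads - profile.unassigned_reads
        assert assigned >= 0
        assert sum(profile.abundances().values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_candidates_give_empty_profile(self, two_species_db, rng):
        reads = [random_dna(rng, 32) for _ in range(50)]
        profile = profile_sample(ReadSet("s", reads), two_species_db)
        assert profile.hits == []
        assert profile.unassigned_reads == 50

    def test_two_pass_never_shrinks_marker_pool(self, small_mock):
        db = build_tag_db_from_sequences(small_mock.genomes, BCGI)
        p1 = profile_sample(small_mock.readset, db, small_mock.host_tags,
                            config=ProfileConfig(two_pass=False))
        p2 = profile_sample(small_mock.readset, db, small_mock.host_tags)
        m1 = {h.species_id: h.markers_total for h in p1.hits}
        m2 = {h.species_id: h.markers_total for h in p2.hits}
        for sp in set(m1) & set(m2):
            assert m2[sp] >= m1[sp]

    def test_decontamination_end_to_end(self, rng):
        genomes = self._genomes(rng, ["spA", "contamX"])
        db = build_tag_db_from_sequences(genomes, BCGI)
        from twobrad.simulate import simulate_negative_control
        sample_spec = CommunitySpec({"spA": 0.7, "contamX": 0.3},
                                    n_reads=1000, seed=21)
        readset, _ = simulate_reads(sample_spec, genomes, BCGI)
        control = simulate_negative_control({"contamX": 1.0}, 100, genomes,
                                            BCGI, seed=22)
        with_ctrl = profile_sample(readset, db, control=control)
        without = profile_sample(readset, db)
        # contamX is heavily subtracted (T/N = 10 × its control counts)
        x_with = with_ctrl.abundances().get("contamX", 0.0)
        x_without = without.abundances()["contamX"]
        assert x_with < x_without

    def test_determinism(self, small_mock):
        db = build_tag_db_from_sequences(small_mock.genomes, BCGI)
        p1 = profile_sample(small_mock.readset, db, small_mock.host_tags)
        p2 = profile_sample(small_mock.readset, db, small_mock.host_tags)
        assert p1.abundances() == p2.abundances()


class TestHostFraction:
    def test_basic(self):
        assert host_fraction(90, 100) == pytest.approx(0.9)
        assert host_fraction(0, 50) == 0.0

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            host_fraction(0, 0)

    def test_simulated_99pct_spike(self, rng):
        genomes = {}
        pieces = []
        for _ in range(10):
            pieces.append(random_dna(rng, 80))
            pieces.append(plant_tag(rng))
        genomes["spA"] = "".join(pieces)
        db = build_tag_db_from_sequences(genomes, BCGI)
        from twobrad.simulate import synth_host_genome
        _, host_tags = synth_host_genome(100_000, BCGI, seed=17)
        spec = CommunitySpec({"spA": 1.0}, n_reads=100_000,
                             host_fraction=0.99, seed=13)
        readset, _ = simulate_reads(spec, genomes, BCGI, host_tags=host_tags)
        profile = profile_sample(readset, db, host_tags)
        assert host_fraction(profile) == pytest.approx(0.99, abs=0.005)
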