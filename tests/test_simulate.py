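"""Synthetic locus, cohort and read generation: determinism and statistics."""

import math

import pytest

from peachfls import (
    Individual,
    SimulationConfig,
    generate_cohort,
    generate_locus,
    simulate_reads,
)
from peachfls.locus import ConfigurationError, DiploidGenotype
from peachfls.simulate import (
    EXON2_FLANK,
    EXON2_INSERT,
    EXON2_REF_DOWNSTREAM,
    INTRON1_FLANK,
    INTRON1_INSERT_PREFIX,
    parse_genotype_label,
)


class TestGenerateLocus:
    def test_same_seed_is_byte_identical(self):
        cfg = SimulationConfig(seed=42, locus_length=1000)
        a = generate_locus(cfg)
        b = generate_locus(cfg)
        assert a.locus.sequence == b.locus.sequence
        assert [s.insert_seq for s in a.sites] == [s.insert_seq for s in b.sites]

    def test_variant_allele_is_309_longer(self, published_fixture):
        f1 = published_fixture.allele_sequence("F1")
        f3 = published_fixture.allele_sequence("F3")
        assert len(f3) == len(f1) + 309

    def test_published_fragments_reproduce_printed_probes(self, published_fixture):
        probes = published_fixture.probes()
        assert probes["intron1"].presence_probe == INTRON1_FLANK + INTRON1_INSERT_PREFIX
        assert probes["exon2"].presence_probe == (
            EXON2_FLANK + EXON2_INSERT + EXON2_REF_DOWNSTREAM
        )

    def test_exon_insert_is_tandem_duplication_of_upstream(self):
        fixture = generate_locus(SimulationConfig(seed=3, locus_length=1200))
        exon = fixture.model.site("exon2")
        upstream = fixture.locus.sequence[exon.position - 9 : exon.position]
        assert exon.insert_seq == upstream

    def test_locus_too_short_rejected(self):
        with pytest.raises(ConfigurationError, match="locus_length"):
            generate_locus(SimulationConfig(seed=1, locus_length=400))


class TestGenerateCohort:
    def test_recessive_phenotypes(self, small_fixture):
        cfg = SimulationConfig(seed=1, cohort_composition={"F3F3": 5, "F1F2": 3})
        cohort = generate_cohort(cfg, small_fixture.model)
        assert len(cohort) == 8
        by_gt = {"F3F3": set(), "F1F2": set()}
        for ind in cohort:
            by_gt[ind.genotype.name].add(ind.phenotype)
        assert by_gt["F3F3"] == {"red"}
        assert by_gt["F1F2"] == {"pink"}

    def test_empty_composition(self, small_fixture):
        cfg = SimulationConfig(seed=1, cohort_composition={})
        assert generate_cohort(cfg, small_fixture.model) == []

    def test_unknown_genotype_label_rejected(self, small_fixture):
        with pytest.raises(ConfigurationError):
            parse_genotype_label("F1F9", small_fixture.model)
        cfg = SimulationConfig(seed=1, cohort_composition={"FXFY": 1})
        with pytest.raises(ConfigurationError):
            generate_cohort(cfg, small_fixture.model)

    def test_phenotype_noise_flips_labels(self, small_fixture):
        cfg = SimulationConfig(
            seed=9, cohort_composition={"F3F3": 200}, phenotype_noise=0.3
        )
        cohort = generate_cohort(cfg, small_fixture.model)
        flipped = sum(ind.phenotype == "pink" for ind in cohort)
        # Binomial(200, 0.3): 3 sigma band
        assert abs(flipped - 60) < 3 * math.sqrt(200 * 0.3 * 0.7)


class TestSimulateReads:
    def test_read_count_arithmetic(self):
        """coverage x mean haplotype length / read length, rounded."""
        fixture = generate_locus(SimulationConfig(seed=5, locus_length=1200))
        cfg = SimulationConfig(seed=5, locus_length=1200, coverage=30)
        ind = Individual("i1", DiploidGenotype.of("F1", "F1"))
        rs = simulate_reads(ind, fixture, cfg)
        assert len(rs.reads) == round(30 * 1200 / 150)
        # coverage conservation: total bases == read_count x L exactly
        assert sum(len(seq) for _, seq, _ in rs.reads) == len(rs.reads) * 150

    def test_error_free_reads_are_exact_substrings(self, small_fixture):
        cfg = SimulationConfig(seed=11, locus_length=1500, error_rate=0.0, coverage=5)
        ind = Individual("i1", DiploidGenotype.of("F1", "F3"))
        rs = simulate_reads(ind, small_fixture, cfg)
        haps = {
            "F1": small_fixture.allele_sequence("F1"),
            "F3": small_fixture.allele_sequence("F3"),
        }
        for (_, seq, _), origin in zip(rs.reads, rs.truth):
            allele, start = origin.split(":")
            assert haps[allele][int(start) : int(start) + 150] == seq

    def test_same_seed_identical_reads(self, small_fixture):
        cfg = SimulationConfig(seed=13, locus_length=1500)
        ind = Individual("i1", DiploidGenotype.of("F2", "F3"))
        assert simulate_reads(ind, small_fixture, cfg).reads == \
            simulate_reads(ind, small_fixture, cfg).reads

    def test_haplotype_balance_three_sigma(self, small_fixture):
        """Fair-coin haplotype choice over >= 10000 reads."""
        cfg = SimulationConfig(seed=17, locus_length=1500, coverage=1000)
        ind = Individual("i1", DiploidGenotype.of("F1", "F3"))
        rs = simulate_reads(ind, small_fixture, cfg)
        n = len(rs.reads)
        assert n >= 10_000
        from_f1 = sum(origin.startswith("F1:") for origin in rs.truth)
        se = 0.5 / math.sqrt(n)
        assert abs(from_f1 / n - 0.5) < 3 * se

    def test_realized_substitution_rate_three_sigma(self, small_fixture):
        e = 0.02
        cfg = SimulationConfig(seed=19, locus_length=1500, coverage=200, error_rate=e)
        ind = Individual("i1", DiploidGenotype.of("F2", "F2"))
        rs = simulate_reads(ind, small_fixture, cfg)
        hap = small_fixture.allele_sequence("F2")
        mismatches = 0
        total = 0
        for (_, seq, _), origin in zip(rs.reads, rs.truth):
            start = int(origin.split(":")[1])
            src = hap[start : start + 150]
            mismatches += sum(a != b for a, b in zip(seq, src))
            total += 150
        se = math.sqrt(e * (1 - e) / total)
        assert abs(mismatches / total - e) < 3 * se

    def test_paired_mode_honors_base_yield(self, small_fixture):
        cfg = SimulationConfig(seed=23, locus_length=1500, coverage=30, paired=True)
        ind = Individual("i1", DiploidGenotype.of("F1", "F1"))
        rs = simulate_reads(ind, small_fixture, cfg)
        expected_pairs = round(30 * 1500 / 300)
        assert len(rs.reads) == 2 * expected_pairs
        assert len(rs.truth) == expected_pairs
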