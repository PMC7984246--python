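"""Generators: seed determinism, planted structure, estimator truth."""

import numpy as np
import pytest

from evodiv import phenotype_gxe
from evodiv.synthetic_data import (
    BiologScenario,
    CompetitionScenario,
    PlantedVariant,
    ReadScenario,
    SharedVariant,
    VariantScenario,
    final_fraction,
    generate_biolog,
    generate_clone_reads,
    generate_competition,
    generate_variant_tables,
    serial_transfer_generations,
)


class TestBiolog:
    def test_noise_free_generalists_identical(self):
        scenario = BiologScenario(n_populations_per_treatment=2, noise_sd=0.0, seed=1)
        for m in generate_biolog(scenario, "generalist"):
            assert np.ptp(m.values) == 0.0
            comp = phenotype_gxe.decompose(m)
            assert comp.R == comp.I == 0.0

    def test_specialist_types_anticorrelate_on_niche_columns(self):
        scenario = BiologScenario(
            n_populations_per_treatment=1,
            n_clones=4,
            n_substrates=20,
            niche_size=5,
            n_specialist_types=2,
            noise_sd=0.0,
            seed=2,
        )
        m = generate_biolog(scenario, "specialist")[0]
        # clones 0 and 1 have different niche types (cyclic assignment)
        niche_cols = np.ptp(m.values, axis=0) > 0
        a, b = m.values[0, niche_cols], m.values[1, niche_cols]
        r = np.corrcoef(a, b)[0, 1]
        assert r == pytest.approx(-1.0)

    def test_seed_determinism(self):
        scenario = BiologScenario(n_populations_per_treatment=2, seed=3)
        m1 = generate_biolog(scenario, "specialist")
        m2 = generate_biolog(scenario, "specialist")
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_values_non_negative_even_with_huge_noise(self):
        scenario = BiologScenario(n_populations_per_treatment=1, noise_sd=5.0, seed=4)
        m = generate_biolog(scenario, "generalist")[0]
        assert (m.values >= 0).all()

    def test_niche_capacity_validated(self):
        with pytest.raises(ValueError, match="niche capacity"):
            BiologScenario(n_substrates=10, niche_size=6, n_specialist_types=2)

    def test_specialists_exceed_generalists_in_inconsistency(self):
        # gain/loss >= 2 x noise_sd: specialist I dominates over many seeds
        spec_means, gen_means = [], []
        for seed in range(20):
            s = BiologScenario(n_populations_per_treatment=1, seed=seed)
            spec = generate_biolog(s, "specialist")[0]
            gen = generate_biolog(s, "generalist")[0]
            spec_means.append(phenotype_gxe.inconsistency(spec))
            gen_means.append(phenotype_gxe.inconsistency(gen))
        assert np.mean(spec_means) > np.mean(gen_means)
        assert min(spec_means) > max(gen_means)


class TestVariantTables:
    def test_empty_scenario_gives_empty_tables(self):
        tables = generate_variant_tables(
            VariantScenario(n_populations=4, mean_variants_per_population=0.0, seed=0)
        )
        assert all(len(t) == 0 for t in tables)

    def test_full_fraction_shared_variant_in_all_members(self):
        scenario = VariantScenario(
            n_populations=12,
            mean_variants_per_population=0.0,
            shared_variant_spec=(SharedVariant("s1", "heterogeneous", 1.0, 0.8),),
            seed=1,
        )
        tables = generate_variant_tables(scenario)
        het = [t for t in tables if t.treatment == "heterogeneous"]
        hom = [t for t in tables if t.treatment == "homogeneous"]
        assert all(len(t) == 1 and t.records[0].proportion == 0.8 for t in het)
        assert all(len(t) == 0 for t in hom)

    def test_partial_fraction_counts(self):
        scenario = VariantScenario(
            n_populations=12,
            mean_variants_per_population=0.0,
            shared_variant_spec=(SharedVariant("s1", "heterogeneous", 4 / 6, None),),
            seed=2,
        )
        tables = generate_variant_tables(scenario)
        carriers = sum(len(t) for t in tables if t.treatment == "heterogeneous")
        assert carriers == 4

    def test_proportions_in_unit_interval(self):
        tables = generate_variant_tables(
            VariantScenario(n_populations=6, mean_variants_per_population=5.0, seed=3)
        )
        for t in tables:
            assert all(0 < r.proportion <= 1 for r in t.records)

    def test_seed_determinism(self):
        s = VariantScenario(n_populations=6, mean_variants_per_population=3.0, seed=4)
        t1, t2 = generate_variant_tables(s), generate_variant_tables(s)
        assert [t.records for t in t1] == [t.records for t in t2]

    def test_invalid_beta_parameters_rejected(self):
        with pytest.raises(ValueError):
            VariantScenario(proportion_alpha=0.0)


class TestCompetition:
    def test_final_fraction_solves_odds_ratio(self):
        assert final_fraction(0.5, 3.0) == pytest.approx(0.75)
        assert final_fraction(0.5, 1.0) == pytest.approx(0.5)

    def test_huge_plates_recover_truth(self):
        from evodiv.fitness_assays import assay_fitness

        scenario = CompetitionScenario(
            true_relative_fitness=3.0, plated_colonies_mean=2_000_000, seed=5
        )
        w = assay_fitness(generate_competition(scenario)).relative_fitness
        assert w == pytest.approx(3.0, rel=0.01)

    def test_seed_determinism(self):
        s = CompetitionScenario(seed=6)
        assert generate_competition(s) == generate_competition(s)

    def test_fractions_never_degenerate(self):
        for seed in range(50):
            a = generate_competition(CompetitionScenario(seed=seed, plated_colonies_mean=20))
            assert 0 < a.white_T0 < a.white_T0 + a.blue_T0
            assert 0 < a.white_T7 < a.white_T7 + a.blue_T7

    def test_invalid_fitness_rejected(self):
        with pytest.raises(ValueError):
            CompetitionScenario(true_relative_fitness=0.0)


class TestCloneReads:
    def scenario(self, **kw):
        defaults = dict(
            genome_length=2_000,
            n_clones=2,
            read_length=100,
            coverage_per_clone=10,
            planted_variants=(PlantedVariant(500, "A", "G", frozenset({0})),),
            error_rate=0.0,
            seed=7,
        )
        defaults.update(kw)
        return ReadScenario(**defaults)

    def test_read_count_matches_coverage(self, tmp_path):
        paths, _ = generate_clone_reads(self.scenario(), tmp_path)
        n_reads = sum(1 for line in paths[0].open()) // 4
        assert n_reads == 10 * 2000 // 100

    def test_carrier_reads_show_alt_everywhere(self, tmp_path):
        paths, truth = generate_clone_reads(self.scenario(), tmp_path)
        assert truth["carrier_fraction"].iloc[0] == 0.5
        for path, expect_alt in zip(paths, (True, False)):
            with path.open() as fh:
                records = fh.read().strip().split("\n")
            for header, seq in zip(records[0::4], records[1::4]):
                pos = int(header.split("pos=")[1])
                if pos <= 500 < pos + 100:
                    base = seq[500 - pos]
                    assert base == ("G" if expect_alt else "A")

    def test_seed_determinism_bytes(self, tmp_path):
        p1, _ = generate_clone_reads(self.scenario(), tmp_path / "a")
        p2, _ = generate_clone_reads(self.scenario(), tmp_path / "b")
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()

    def test_invalid_configurations_rejected(self):
        with pytest.raises(ValueError, match="read_length"):
            self.scenario(read_length=5000)
        with pytest.raises(ValueError):
            self.scenario(
                planted_variants=(
                    PlantedVariant(1, "A", "G", frozenset()),
                    PlantedVariant(1, "C", "T", frozenset()),
                )
            )
        with pytest.raises(ValueError, match="carrier"):
            self.scenario(planted_variants=(PlantedVariant(5, "A", "G", frozenset({9})),))


def test_serial_transfer_generation_floor():
    assert serial_transfer_generations(8, 3) == 12
    assert serial_transfer_generations(0, 3) == 0
    with pytest.raises(ValueError):
        serial_transfer_generations(8, 1.0)
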