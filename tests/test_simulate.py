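"""Synthetic cohort generator: determinism, planted-variant recovery,
Hardy-Weinberg calibration and the gene-drop transmission model."""

import itertools

import numpy as np
import pytest

from famseg.cohort import HET, HOM_ALT, Family
from famseg.simulate import (
    MmafMixture,
    PlantedSpec,
    SimulationConfig,
    build_schematic_pedigree,
    expected_chance_segregating,
    gene_drop_family,
    simulate_cohort,
)
from famseg.tiers import (
    HIGH_RISK_TIER,
    NOVEL_CANDIDATE_TIER,
    screen_high_risk,
    screen_novel_candidates,
)


class TestConfig:
    def test_default_shape_matches_study(self):
        sim = simulate_cohort(SimulationConfig(seed=0, n_background_variants=10))
        assert len(sim.families) == 24
        assert sim.cohort.n_samples == 59
        wes = sorted(f.wes_class for f in sim.families)
        assert wes.count(4) == 3 and wes.count(3) == 6
        assert wes.count(2) == 14 and wes.count(1) == 1

    def test_infeasible_planted_spec_rejected(self):
        with pytest.raises(ValueError, match="does not satisfy"):
            PlantedSpec(tier=HIGH_RISK_TIER, mmaf_high=0.01, cadd_low=26)
        with pytest.raises(ValueError, match="does not satisfy"):
            PlantedSpec(tier=NOVEL_CANDIDATE_TIER, mmaf_high=1e-3, cadd_low=19)

    def test_family_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_families=5, wes_class_distribution={2: 3})


class TestDeterminism:
    def test_identical_seed_gives_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_background_variants=60)
        p1 = simulate_cohort(cfg).write(tmp_path / "a")
        p2 = simulate_cohort(cfg).write(tmp_path / "b")
        for name in ("vcf", "families", "annotations", "truth"):
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimulationConfig(seed=1, n_background_variants=40))
        b = simulate_cohort(SimulationConfig(seed=2, n_background_variants=40))
        assert a.cohort.variants != b.cohort.variants


class TestPlantedRecovery:
    def test_zero_missingness_recovers_every_planted_variant(self):
        sim = simulate_cohort(
            SimulationConfig(seed=5, missingness=0.0, n_background_variants=150)
        )
        records = sim.variant_records()
        novel = screen_novel_candidates(sim.cohort, sim.families, records)
        high = screen_high_risk(novel, sim.families)
        novel_set = {(c.key, c.family_id) for c in novel}
        high_set = {(c.key, c.family_id) for c in high}
        planted = [t for t in sim.truth if t.planted]
        assert len(planted) == 24
        for t in planted:
            assert (t.key, t.target_family) in novel_set
            if t.expected_tier == "HighRisk":
                assert (t.key, t.target_family) in high_set

    def test_planted_variants_are_het_in_whole_target_family(self):
        sim = simulate_cohort(
            SimulationConfig(seed=6, missingness=0.0, n_background_variants=0)
        )
        by_id = {f.family_id: f for f in sim.families}
        for t in sim.truth:
            assert t.planted
            fam = by_id[t.target_family]
            for member in fam.members:
                assert sim.cohort.call(t.key, member) == HET


class TestBackgroundCalibration:
    def test_carrier_frequency_within_three_binomial_sd(self):
        """Empirical carrier rate at a common site must sit within 3
        binomial standard deviations of 2p(1-p) + p^2."""
        cfg = SimulationConfig(
            seed=9,
            n_background_variants=200,
            n_planted_per_family=0,
            missingness=0.0,
            mmaf_mixture=MmafMixture(
                p_zero=0.0, p_rare=0.0, common_low=0.2, common_high=0.2000001
            ),
        )
        sim = simulate_cohort(cfg)
        p = 0.2
        expected = 2 * p * (1 - p) + p * p
        n = sim.cohort.calls.size
        observed = np.mean((sim.cohort.calls == HET) | (sim.cohort.calls == HOM_ALT))
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * sd


class TestGeneDrop:
    def test_frequency_zero_never_carries(self):
        fam = Family("F", ("F.1", "F.2"))
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert not any(gene_drop_family(fam, 0.0, rng).values())

    def test_frequency_one_always_carries(self):
        fam = Family("F", ("F.1", "F.2", "F.3"))
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert all(gene_drop_family(fam, 1.0, rng).values())

    def test_sib_pair_joint_carrier_rate_matches_enumeration(self):
        """Oracle: exhaustive enumeration over the 9 founder genotype
        combinations with Mendelian transmission probabilities."""
        p = 0.2
        hwe = [(1 - p) ** 2, 2 * p * (1 - p), p * p]
        exact = sum(
            hwe[g1] * hwe[g2] * (1 - (1 - g1 / 2) * (1 - g2 / 2)) ** 2
            for g1, g2 in itertools.product(range(3), repeat=2)
        )
        fam = Family("F", ("F.1", "F.2"), degree_span="1st")
        rng = np.random.default_rng(42)
        n = 40_000
        hits = sum(all(gene_drop_family(fam, p, rng).values()) for _ in range(n))
        observed = hits / n
        sd = np.sqrt(exact * (1 - exact) / n)
        assert abs(observed - exact) < 4 * sd

    def test_second_degree_pair_shares_less_than_sibs(self):
        """One extra meiosis halves the sharing of a transmitted allele, so
        an avuncular pair segregates a rare allele less often than sibs."""
        p = 0.05
        rng = np.random.default_rng(7)
        n = 20_000
        sibs = Family("A", ("A.1", "A.2"), degree_span="1st")
        avunc = Family("B", ("B.1", "B.2"), degree_span="2nd")
        rate_sibs = sum(all(gene_drop_family(sibs, p, rng).values()) for _ in range(n)) / n
        rate_avunc = sum(all(gene_drop_family(avunc, p, rng).values()) for _ in range(n)) / n
        assert rate_sibs > rate_avunc

    def test_pedigree_members_all_reachable(self):
        fam = Family("F", ("F.1", "F.2", "F.3"), degree_span="3rd")
        ped = build_schematic_pedigree(fam)
        for m in fam.members:
            assert m in ped
            # walking up always terminates at founders
            frontier = [m]
            seen = set()
            while frontier:
                person = frontier.pop()
                seen.add(person)
                parents = ped[person]
                if parents:
                    frontier.extend(x for x in parents if x not in seen)


class TestChanceSegregation:
    def test_wes1_count_is_single_member_carrier_census(self):
        mean, _ = expected_chance_segregating(
            SimulationConfig(seed=1, n_background_variants=50), 1, n_replicates=5, seed=3
        )
        assert mean >= 0  # degenerate segregation: any carrier passes

    def test_smaller_families_see_more_chance_hits(self):
        cfg = SimulationConfig(
            seed=0,
            n_background_variants=150,
            mmaf_mixture=MmafMixture(p_zero=0.0, p_rare=0.2),
        )
        m2, _ = expected_chance_segregating(cfg, 2, n_replicates=40, seed=5)
        m4, _ = expected_chance_segregating(cfg, 4, n_replicates=40, seed=5)
        assert m2 > m4

    def test_no_qualifying_annotation_means_zero(self):
        # every allele common (MMAF >= 0.01): nothing can pass the rarity
        # criterion, so the chance-hit count is exactly zero
        cfg = SimulationConfig(
            seed=0,
            n_background_variants=80,
            mmaf_mixture=MmafMixture(p_zero=0.0, p_rare=0.0),
        )
        mean, sd = expected_chance_segregating(cfg, 2, n_replicates=10, seed=1)
        assert mean == 0.0
        assert sd == 0.0
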