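"""Meiosis engine: crossover process, segregation, genotyping, ploidy calls."""

import dataclasses
import math

import numpy as np
import pytest

import sporedrive as sd
from sporedrive.genome import SK, SP, ParentalChromosome
from sporedrive.meiosis import (
    HAPLOID,
    HET_CHR3_ANEUPLOID,
    HET_DIPLOID,
    Chromatid,
    Spore,
    draw_crossovers,
    meiose_bivalent,
    segregate,
)
from sporedrive.presets import MARKERS, krk_chromosome2, no_drive_model, preset


def collinear_cfg(**over):
    return preset("collinear_hybrid_wt", drive=no_drive_model(), p_dist=1.0, **over)


class TestDrawCrossovers:
    def test_zero_genetic_length_gives_no_events(self, rng):
        cfg = collinear_cfg()
        genome = dataclasses.replace(cfg.genome, cM_per_kb=0.0)
        for _ in range(50):
            assert (
                draw_crossovers(
                    genome, cfg.parent1[0], cfg.parent2[0], "wt", 0.0, rng
                )
                == []
            )

    def test_poisson_mean_is_twice_map_length_in_morgans(self, rng):
        # scale the map so chromosome 1 is exactly 50 cM: mean 1.0 events
        cfg = collinear_cfg()
        rate = 50.0 / (cfg.genome.length(1) / 1000.0)
        genome = dataclasses.replace(cfg.genome, cM_per_kb=rate)
        n = 4000
        counts = [
            len(draw_crossovers(genome, cfg.parent1[0], cfg.parent2[0], "wt", 0.0, rng))
            for _ in range(n)
        ]
        assert np.mean(counts) == pytest.approx(1.0, abs=3.0 / math.sqrt(n))

    def test_rec12_null_residual_bernoulli(self, rng):
        cfg = collinear_cfg()
        n = 4000
        counts = [
            len(
                draw_crossovers(
                    cfg.genome, cfg.parent1[0], cfg.parent2[0], "null", 0.1, rng
                )
            )
            for _ in range(n)
        ]
        assert max(counts) <= 1
        assert np.mean(counts) == pytest.approx(0.1, abs=0.02)


class TestHaldaneConsistency:
    @pytest.mark.parametrize("morgans", [0.05, 0.2, 0.5, 1.0])
    def test_two_point_recombinant_fraction(self, morgans):
        """Simulated per-chromatid recombinant fractions match
        (1 - exp(-2d))/2 within 3 binomial SE at n = 20,000 chromatids."""
        cfg = collinear_cfg(seed=int(morgans * 100))
        span = int(sd.genetic_to_physical(100.0 * morgans))
        a, b = 1_000_000, 1_000_000 + span
        rng = np.random.default_rng(cfg.seed)
        rec = tot = 0
        for _ in range(5000):
            for spore in sd.simulate_meiosis(cfg, rng):
                tot += 1
                rec += spore.genotype_at(1, a) != spore.genotype_at(1, b)
        expected = (1.0 - math.exp(-2.0 * morgans)) / 2.0
        se = math.sqrt(expected * (1 - expected) / tot)
        assert tot == 20_000
        assert abs(rec / tot - expected) < 3 * se


class TestSegregate:
    def _bivalent(self, cfg):
        return meiose_bivalent(cfg.genome, cfg.parent1[0], cfg.parent2[0], [])

    def test_chiasmate_bivalent_gives_one_copy_per_spore(self, rng):
        cfg = collinear_cfg()
        for _ in range(40):
            spores = segregate(self._bivalent(cfg), 1, 0.0, rng)
            assert [len(s) for s in spores] == [1, 1, 1, 1]

    def test_achiasmate_random_poles_disome_probability(self, rng):
        # brute force over many meioses: P(a spore is disomic) = 1/4 at
        # p_dist = 0 (two of the four equiprobable MI configurations load
        # one pole, and half of those spores carry two copies)
        cfg = collinear_cfg()
        n = 3000
        disomic = total = 0
        for _ in range(n):
            for s in segregate(self._bivalent(cfg), 0, 0.0, rng):
                total += 1
                disomic += len(s) == 2
        p = disomic / total
        assert abs(p - 0.25) < 3 * math.sqrt(0.25 * 0.75 / total)

    def test_perfect_distributive_system_behaves_chiasmate(self, rng):
        cfg = collinear_cfg()
        for _ in range(40):
            spores = segregate(self._bivalent(cfg), 0, 1.0, rng)
            assert [len(s) for s in spores] == [1, 1, 1, 1]


class TestSimulateMeiosis:
    def test_pure_species_gives_parental_haploids(self, rng):
        cfg = preset("PPPxPPP_wt")
        for _ in range(20):
            tetrad = sd.simulate_meiosis(cfg, rng)
            for spore in tetrad:
                assert spore.copy_number() == (1, 1, 1)
                for chrom in (1, 2, 3):
                    assert spore.genotype_at(chrom, 1000) == {SP}

    def test_chromatid_conservation(self, rng):
        cfg = preset("PPPxKKK_wt")
        for _ in range(30):
            tetrad = sd.simulate_meiosis(cfg, rng)
            for chrom in (1, 2, 3):
                total = sum(
                    1 for s in tetrad for c in s.chromatids if c.chrom == chrom
                )
                assert total == 4

    def test_ancestry_conservation(self, rng):
        # total bp of each ancestry across a tetrad = 2 x parental content
        cfg = preset("PPPxKKK_wt")
        genome = cfg.genome
        expected = {SK: 0, SP: 0}
        for parent in cfg.parents:
            for pc in parent:
                for iv, anc in pc.ancestry:
                    expected[anc] += 2 * iv.length
        for _ in range(20):
            tetrad = sd.simulate_meiosis(cfg, rng)
            got = {SK: 0, SP: 0}
            for spore in tetrad:
                for c in spore.chromatids:
                    for s, e, anc in c.ancestry:
                        got[anc] += e - s
            assert got == expected

    def test_heterozygous_inversion_yields_unbalanced_chromatids(self, rng):
        cfg = preset("PPPxKKK_wt")
        unbalanced = 0
        for _ in range(100):
            tetrad = sd.simulate_meiosis(cfg, rng)
            unbalanced += sum(
                1 for s in tetrad for c in s.chromatids if not c.balanced
            )
        # the inversion spans > 3.5 Morgans, so odd-parity chromatids are common
        assert unbalanced > 50

    def test_homokaryotypic_meiosis_never_unbalanced(self, rng):
        cfg = collinear_cfg()
        for _ in range(50):
            tetrad = sd.simulate_meiosis(cfg, rng)
            assert all(c.balanced for s in tetrad for c in s.chromatids)


class TestGenotypeAt:
    def _chromatid(self, genome, code_chrom):
        return Chromatid.from_parental(genome, code_chrom, 0)

    def test_haploid_sk_spore_at_ade6(self, genome):
        k3 = ParentalChromosome.uniform(genome, 3, SK, SK)
        spore = Spore([self._chromatid(genome, k3)])
        assert sd.genotype_at(spore, MARKERS["ade6"], genome) == {SK}

    def test_chr3_disome_is_heterozygous_at_ade6(self, genome):
        k3 = ParentalChromosome.uniform(genome, 3, SK, SK)
        p3 = ParentalChromosome.uniform(genome, 3, SP, SP)
        spore = Spore([self._chromatid(genome, k3), self._chromatid(genome, p3)])
        assert sd.genotype_at(spore, MARKERS["ade6"], genome) == {SK, SP}

    def test_recombinant_chromosome_follows_ancestry_map(self, genome):
        # the KRK strain's chromosome 2: Sp alleles distal to mat1, Sk
        # proximal, Sk on the translocated chr3 right arm
        spore = Spore([self._chromatid(genome, krk_chromosome2(genome))])
        assert sd.genotype_at(spore, MARKERS["his5"], genome) == {SP}
        assert sd.genotype_at(spore, MARKERS["leu1"], genome) == {SP}
        assert spore.genotype_at(2, 1_000_000) == {SK}  # proximal core
        assert spore.genotype_at(3, 2_000_000) == {SK}  # translocated arm

    def test_off_chromosome_locus_rejected(self, genome):
        k3 = ParentalChromosome.uniform(genome, 3, SK, SK)
        spore = Spore([self._chromatid(genome, k3)])
        bad = sd.Locus("bad", 3, genome.length(3) + 10)
        with pytest.raises(ValueError):
            sd.genotype_at(spore, bad, genome)


class TestClassifySpore:
    def _spore(self, genome, chroms):
        return Spore([Chromatid.from_parental(genome, pc, i) for i, pc in enumerate(chroms)])

    def test_both_chr2_alleles_is_het_diploid(self, genome):
        chroms = [
            ParentalChromosome.uniform(genome, 2, SK, SK),
            ParentalChromosome.uniform(genome, 2, SP, SP),
            ParentalChromosome.uniform(genome, 3, SK, SK),
            ParentalChromosome.uniform(genome, 3, SP, SP),
        ]
        spore = self._spore(genome, chroms)
        assert sd.classify_spore(spore, MARKERS["his5"], MARKERS["ade6"]) == HET_DIPLOID

    def test_both_chr3_alleles_single_chr2_is_het_aneuploid(self, genome):
        chroms = [
            ParentalChromosome.uniform(genome, 2, SK, SK),
            ParentalChromosome.uniform(genome, 3, SK, SK),
            ParentalChromosome.uniform(genome, 3, SP, SP),
        ]
        spore = self._spore(genome, chroms)
        assert (
            sd.classify_spore(spore, MARKERS["his5"], MARKERS["ade6"])
            == HET_CHR3_ANEUPLOID
        )

    def test_homozygous_disome_counted_as_haploid(self, genome):
        # a true K3+K3 disome is invisible to the codominant markers
        chroms = [
            ParentalChromosome.uniform(genome, 2, SK, SK),
            ParentalChromosome.uniform(genome, 3, SK, SK),
            ParentalChromosome.uniform(genome, 3, SK, SK),
        ]
        spore = self._spore(genome, chroms)
        assert sd.classify_spore(spore, MARKERS["his5"], MARKERS["ade6"]) == HAPLOID
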