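"""Exact crossover-free enumeration: probabilities, symmetry, oracle role."""

import math
from collections import Counter

import numpy as np
import pytest

import sporedrive as sd
from sporedrive.enumeration import (
    UnsupportedModeError,
    enumerate_no_crossover,
    expected_transmission,
    viable_fraction,
)
from sporedrive.genome import SK, SP, CrossConfig, DriveLocus, DriveModel
from sporedrive.presets import (
    MARKERS,
    collinear_parent,
    default_drive_model,
    no_drive_model,
    preset,
)


def collinear(p_dist, drive=None, flip=False):
    g = sd.build_default_genome()
    a, b = (SK, SP) if flip else (SP, SK)
    return CrossConfig(
        g,
        collinear_parent(g, a),
        collinear_parent(g, b),
        drive or no_drive_model(),
        rec12="null",
        residual_rate=0.0,
        p_dist=p_dist,
    )


class TestClassProbabilities:
    def test_euploid_haploid_probability_at_random_segregation(self):
        """Brute force over the 64 joint MI configurations: a fully random
        spore is a euploid haploid with probability 1/8."""
        dist = enumerate_no_crossover(collinear(0.0))
        p = sum(
            c.prob_pre for c in dist.classes if c.spore.copy_number() == (1, 1, 1)
        )
        assert p == pytest.approx(1 / 8, abs=1e-12)

    def test_viable_complement_probability_is_13_64(self):
        """Haploid + diploid + chr3 disome at p_dist = 0 without
        rearrangement heterozygosity: 13/64 ~ 20.3 %."""
        assert viable_fraction(collinear(0.0)) == pytest.approx(13 / 64, abs=1e-12)

    def test_partial_distributive_fidelity_reaches_25_percent(self):
        # p_dist ~ 0.2 brings the viable-complement probability to >= 25 %
        assert viable_fraction(collinear(0.2)) >= 0.25

    def test_perfect_distributive_homokaryotypic_all_haploid_viable(self):
        cfg = preset(
            "KKKxKKK_rec12", p_dist=1.0, residual_rate=0.0, drive=no_drive_model()
        )
        assert viable_fraction(cfg, "haploid") == pytest.approx(1.0, abs=1e-12)

    def test_normalization(self):
        for cfg in (
            collinear(0.0),
            collinear(0.7),
            preset("PPPxKKK_rec12", residual_rate=0.0),
            preset("KKRxKKK_rec12", residual_rate=0.0),
        ):
            dist = enumerate_no_crossover(cfg)
            assert dist.total_pre() == pytest.approx(1.0, abs=1e-12)
            assert 0.0 <= dist.viable_fraction <= 1.0

    def test_crossover_mode_rejected(self):
        with pytest.raises(UnsupportedModeError):
            enumerate_no_crossover(preset("PPPxKKK_wt"))


class TestTranslocationPenalty:
    def test_haploid_viability_exactly_halved(self):
        """A translocation heterozygote recovers exactly half the viable
        haploids of a homokaryotypic cross: half of the gametes inherit an
        incompatible chromosome 2/3 combination."""
        for p_dist in (0.0, 0.3, 0.5, 1.0):
            het = preset(
                "PPPxKKK_rec12",
                residual_rate=0.0,
                p_dist=p_dist,
                drive=no_drive_model(),
            )
            hom = collinear(p_dist)
            ratio = viable_fraction(het, "haploid") / viable_fraction(hom, "haploid")
            assert ratio == pytest.approx(0.5, abs=1e-12)


class TestSymmetry:
    def test_ancestry_swap_preserves_viability_and_flips_transmission(self):
        drive = DriveModel(
            (
                DriveLocus(1, 4_050_000, killer=SK, strength=0.6, name="k1"),
                DriveLocus(3, 1_310_000, killer=SK, strength=0.9, name="k3"),
            )
        )
        mirrored = DriveModel(
            (
                DriveLocus(1, 4_050_000, killer=SP, strength=0.6, name="k1"),
                DriveLocus(3, 1_310_000, killer=SP, strength=0.9, name="k3"),
            )
        )
        cfg = collinear(0.4, drive=drive)
        swapped = collinear(0.4, drive=mirrored, flip=True)
        assert viable_fraction(cfg) == pytest.approx(viable_fraction(swapped), abs=1e-12)
        for marker in ("lys1", "ade6"):
            t = expected_transmission(cfg, MARKERS[marker], killer=SK)
            t_swapped = expected_transmission(swapped, MARKERS[marker], killer=SP)
            assert t == pytest.approx(t_swapped, abs=1e-12)
            t_flip = expected_transmission(swapped, MARKERS[marker], killer=SK)
            assert t_flip == pytest.approx(1.0 - t, abs=1e-12)


class TestExpectedTransmission:
    def test_no_drive_is_mendelian(self):
        cfg = collinear(0.5)
        for marker in ("lys1", "his5", "ade6"):
            assert expected_transmission(cfg, MARKERS[marker]) == pytest.approx(0.5)

    @pytest.mark.parametrize("d", [0.2, 0.5, 0.9])
    def test_single_driver_haploid_only_closed_form(self, d):
        """With only haploids viable (p_dist = 1) and a single killer at the
        assayed locus, t = 1/(2 - d)."""
        drive = DriveModel(
            (DriveLocus(1, MARKERS["lys1"].pos, killer=SK, strength=d, name="k1"),)
        )
        cfg = collinear(1.0, drive=drive)
        t = expected_transmission(cfg, MARKERS["lys1"])
        assert t == pytest.approx(1.0 / (2.0 - d), abs=1e-12)

    def test_empty_conditioning_set_rejected(self):
        lethal = DriveModel(
            (
                DriveLocus(1, MARKERS["lys1"].pos, killer=SK, strength=1.0),
                DriveLocus(1, MARKERS["lys1"].pos, killer=SP, strength=1.0),
            )
        )
        cfg = collinear(1.0, drive=lethal)
        with pytest.raises(ZeroDivisionError):
            expected_transmission(cfg, MARKERS["lys1"])

    def test_monotonicity_in_drive_strength(self):
        """Stronger killing weakly lowers viable yield and raises the
        killer allele's transmission among survivors."""
        previous_vf, previous_t = None, None
        for d in (0.0, 0.3, 0.6, 0.9):
            cfg = preset(
                "PPPxKKK_rec12",
                residual_rate=0.0,
                drive=default_drive_model(0.0, 0.0, d, 0.0),
            )
            vf = viable_fraction(cfg)
            t = expected_transmission(cfg, MARKERS["ade6"])
            if previous_vf is not None:
                assert vf <= previous_vf + 1e-12
                assert t >= previous_t - 1e-12
            previous_vf, previous_t = vf, t

    def test_pseudo_linkage_boosts_weak_chr2_killer(self):
        """A chr2 killer drives harder in a translocation heterozygote with a
        stronger chr3 killer than in a karyotypically matched cross: spores
        keeping Sk chr2 must keep Sk chr3 to live, so the weak killer rides
        the strong one."""
        drive = DriveModel(
            (
                DriveLocus(2, 3_270_000, killer=SK, strength=0.5, name="k2"),
                DriveLocus(3, 1_310_000, killer=SK, strength=0.9, name="k3"),
            )
        )
        het = preset("PPPxKKK_rec12", residual_rate=0.0, drive=drive)
        hom = collinear(0.5, drive=drive)
        t_het = expected_transmission(het, MARKERS["leu1"])
        t_hom = expected_transmission(hom, MARKERS["leu1"])
        assert t_het > t_hom


class TestMonteCarloAgreement:
    def test_simulation_matches_enumeration(self):
        """Monte Carlo viable-class frequencies agree with the exact
        enumeration within 3 binomial SE per class."""
        cfg = preset("PPPxKKK_rec12", residual_rate=0.0, seed=5)
        dist = enumerate_no_crossover(cfg)
        rng = np.random.default_rng(17)
        n = 4000
        counts = Counter()
        total = 0
        for _ in range(n):
            for spore in sd.simulate_and_assess(cfg, rng):
                total += 1
                if spore.verdict.alive:
                    key = tuple(
                        {(0,): "A", (1,): "B", (0, 1): "AB", (): "0"}[
                            spore.origins(c)
                        ]
                        for c in (1, 2, 3)
                    )
                    counts[key] += 1
        for c in dist.classes:
            observed = counts.get(c.key, 0) / total
            se = math.sqrt(max(c.prob_post * (1 - c.prob_post), 1e-12) / total)
            assert abs(observed - c.prob_post) < max(3 * se, 5e-4), c.key
        mc_viable = sum(counts.values()) / total
        se = math.sqrt(dist.viable_fraction * (1 - dist.viable_fraction) / total)
        assert abs(mc_viable - dist.viable_fraction) < 3 * se
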