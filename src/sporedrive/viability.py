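"""Spore-death rules: structural balance, essential-gene complement,
copy-number (aneuploidy) lethality, and gamete-killer drive.

Rules are applied in a fixed order and the first failing rule is recorded as
the cause of death:

1. *unbalanced* — any chromatid derives from an odd number of crossovers
   inside a heterozygous inversion (duplication/deficiency product);
2. *missing_essential* — the spore's content does not cover every essential
   segment at least once (e.g. an intact-K2 + intact-P3 haploid);
3. *aneuploid_lethal* — the chromosome copy-number vector is not haploid,
   diploid, or chromosome 3 disome;
4. *drive_killed* — independent Bernoulli killing by each active gamete
   killer.  A spore is immune to a driver iff it carries at least one copy
   of the killer-ancestry allele at that locus (one-locus poison/antidote),
   so heterozygous diploids and chr3-heterozygous disomes are immune to the
   chromosome 3 drivers.

Drive is strictly post-segregation trans-acting gamete killing, never biased
segregation.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .genome import CrossConfig, DriveLocus, DriveModel, GenomeSpec
from .meiosis import Spore, Tetrad, ViabilityVerdict

UNBALANCED = "unbalanced"
MISSING_ESSENTIAL = "missing_essential"
ANEUPLOID_LETHAL = "aneuploid_lethal"
DRIVE_KILLED = "drive_killed"

VIABLE_COPY_NUMBERS = frozenset({(1, 1, 1), (2, 2, 2), (1, 1, 2)})


def structurally_balanced(spore: Spore) -> bool:
    """False iff any chromatid has odd crossover parity inside a
    heterozygous inversion."""
    return all(c.balanced for c in spore.chromatids)


def essential_complement_ok(spore: Spore, genome: GenomeSpec) -> bool:
    """True iff every essential segment is covered by at least one chromatid."""
    for seg, _label in genome.essential_segments:
        covered = _union_coverage(spore, seg.chrom)
        pos = seg.start
        for lo, hi in covered:
            if lo <= pos <= hi + 1:
                pos = max(pos, hi + 1)
            if pos > seg.end:
                break
        if pos <= seg.end:
            return False
    return True


def _union_coverage(spore: Spore, chrom: int) -> list[tuple[int, int]]:
    ivs = sorted(
        (region.start, region.end)
        for c in spore.chromatids
        for region in c.layout
        if region.chrom == chrom
    )
    out: list[tuple[int, int]] = []
    for lo, hi in ivs:
        if out and lo <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def copy_number_viable(spore: Spore) -> bool:
    """Haploid, diploid, or chromosome 3 disome; anything else is lethal."""
    return spore.copy_number() in VIABLE_COPY_NUMBERS


def drive_survival_prob(
    spore: Spore,
    drive: DriveModel | Sequence[DriveLocus],
    active: Optional[Sequence[DriveLocus]] = None,
) -> float:
    """Product over drivers of per-locus survival.

    A driver contributes 1 if the spore carries its killer-ancestry allele,
    else (1 - strength).  If ``active`` is given only those drivers act
    (drivers whose killer ancestry is absent from the whole cross are inert).
    """
    drivers = active if active is not None else (
        drive.drivers if isinstance(drive, DriveModel) else drive
    )
    p = 1.0
    for d in drivers:
        if d.killer not in spore.genotype_at(d.chrom, d.pos):
            p *= 1.0 - d.strength
    return p


def assess_spore(
    spore: Spore,
    genome: GenomeSpec,
    active_drivers: Sequence[DriveLocus],
    rng: Optional[np.random.Generator] = None,
) -> ViabilityVerdict:
    """Apply the death rules to one spore.

    With ``rng`` the drive step is a sampled Bernoulli event; without it the
    verdict is returned alive with the survival probability attached (used
    by the exact-enumeration kernel, which weights in expectation).
    """
    if not structurally_balanced(spore):
        return ViabilityVerdict(False, UNBALANCED, 0.0)
    if not essential_complement_ok(spore, genome):
        return ViabilityVerdict(False, MISSING_ESSENTIAL, 0.0)
    if not copy_number_viable(spore):
        return ViabilityVerdict(False, ANEUPLOID_LETHAL, 0.0)
    p = drive_survival_prob(spore, active_drivers, active=active_drivers)
    if rng is not None and rng.random() >= p:
        return ViabilityVerdict(False, DRIVE_KILLED, p)
    return ViabilityVerdict(True, None, p)


def apply_viability(
    tetrad: Tetrad,
    genome: GenomeSpec,
    drive: DriveModel,
    rng: np.random.Generator,
    active_drivers: Optional[Sequence[DriveLocus]] = None,
) -> Tetrad:
    """Attach a ViabilityVerdict to every spore of a tetrad (in place).

    ``active_drivers`` should normally come from
    :meth:`CrossConfig.active_drivers` so that killers whose ancestry is
    absent from the cross stay inert.
    """
    drivers = tuple(drive.drivers) if active_drivers is None else tuple(active_drivers)
    for spore in tetrad:
        spore.verdict = assess_spore(spore, genome, drivers, rng)
    return tetrad


def simulate_and_assess(cfg: CrossConfig, rng: np.random.Generator) -> Tetrad:
    """Convenience: one meiosis with viability applied."""
    from .meiosis import simulate_meiosis

    tetrad = simulate_meiosis(cfg, rng)
    return apply_viability(tetrad, cfg.genome, cfg.drive, rng, cfg.active_drivers())
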