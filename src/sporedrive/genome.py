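"""Two-species genome model for fission-yeast hybrid crosses.

The model describes the karyotypes of *Schizosaccharomyces pombe* (ancestry
label ``"P"``) and *S. kambucha* (``"K"``), two species whose hybrids are
nearly sterile.  All coordinates are 1-based, inclusive, on the *S. pombe*
reference; the *ancestry* of a chromatid is a breakpoint list in these
coordinates regardless of the physical arrangement of the DNA.

Two rearrangements distinguish the species:

* a large inversion on chromosome 1 carried by the *S. pombe* lineage
  (*S. kambucha* retains the ancestral arrangement), and
* a reciprocal translocation between chromosomes 2 and 3 carried by the
  *S. kambucha* lineage: the left end of *Sp* chromosome 2 is found on *Sk*
  chromosome 3, and the right end of *Sp* chromosome 3 is found on *Sk*
  chromosome 2.  Both translocated segments carry essential genes.

Physical distance converts to genetic distance at a uniform genome-average
rate (default 0.16 cM/kb); hotspot structure is deliberately ignored.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

SK = "K"  # S. kambucha
SP = "P"  # S. pombe
ANCESTRIES = (SK, SP)

#: Standard S. pombe reference chromosome lengths (bp).
CHROM_LENGTHS = {1: 5_579_133, 2: 4_539_804, 3: 2_452_883}

#: Chromosome 1 inversion breakpoints (Sp reference, carried by the Sp lineage).
INVERSION_START = 2_683_632
INVERSION_END = 4_911_515

#: Reciprocal chr2/chr3 translocation breakpoints (Sp reference, Sk lineage).
TRANSLOCATION_CHR2 = 676_281
TRANSLOCATION_CHR3 = 1_932_034

#: Genome-average genetic map rate, cM per kb.
CM_PER_KB = 0.16


class ConfigError(ValueError):
    """Raised when a cross configuration is structurally invalid."""


@dataclass(frozen=True)
class Interval:
    """Closed interval of the Sp reference, 1-based inclusive."""

    chrom: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: int, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class ChromosomeSpec:
    id: int
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("chromosome length must be positive")


@dataclass(frozen=True)
class Locus:
    """A genotyping marker, positioned on the Sp reference."""

    name: str
    chrom: int
    pos: int


@dataclass(frozen=True)
class DriveLocus:
    """A gamete-killer locus.

    ``killer`` is the ancestry whose allele produces the poison; a spore that
    does not inherit the killer-ancestry allele at this position dies with
    probability ``strength``.  Carrying at least one copy of the killer allele
    confers full resistance (one-locus poison/antidote).
    """

    chrom: int
    pos: int
    killer: str
    strength: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.killer not in ANCESTRIES:
            raise ValueError(f"unknown killer ancestry {self.killer!r}")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError(f"drive strength {self.strength} outside [0, 1]")


@dataclass(frozen=True)
class DriveModel:
    """The set of killer loci acting in a cross.

    At most one driver per ancestry per chromosome; killing events at
    distinct loci are independent.
    """

    drivers: tuple[DriveLocus, ...] = ()

    def __post_init__(self) -> None:
        seen = set()
        for d in self.drivers:
            key = (d.chrom, d.killer)
            if key in seen:
                raise ValueError(
                    f"multiple {d.killer} drivers on chromosome {d.chrom}"
                )
            seen.add(key)

    def with_strengths(self, strengths: dict[str, float]) -> "DriveModel":
        """Return a copy with named drivers' strengths replaced."""
        new = tuple(
            replace(d, strength=strengths.get(d.name, d.strength))
            for d in self.drivers
        )
        return DriveModel(new)


@dataclass(frozen=True)
class GenomeSpec:
    """The two-species karyotype: lengths, rearrangements, essential segments."""

    chromosomes: tuple[ChromosomeSpec, ...]
    inversion: Interval
    translocation: tuple[int, int]  # (chr2 breakpoint, chr3 breakpoint)
    essential_segments: tuple[tuple[Interval, str], ...]
    cM_per_kb: float = CM_PER_KB
    inversion_carrier: str = SP
    translocation_carrier: str = SK
    extra_inversions: tuple[tuple[Interval, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.inversion.start < self.inversion.end:
            raise ValueError("inversion start must precede end")
        if self.inversion.end > self.length(self.inversion.chrom):
            raise ValueError("inversion exceeds chromosome length")

    def length(self, chrom: int) -> int:
        for c in self.chromosomes:
            if c.id == chrom:
                return c.length
        raise KeyError(f"no chromosome {chrom}")

    @property
    def chrom_ids(self) -> tuple[int, ...]:
        return tuple(c.id for c in self.chromosomes)

    def inversions_on(self, chrom: int) -> tuple[tuple[Interval, str], ...]:
        out = []
        if self.inversion.chrom == chrom:
            out.append((self.inversion, self.inversion_carrier))
        out.extend((iv, c) for iv, c in self.extra_inversions if iv.chrom == chrom)
        return tuple(out)

    def content_regions(self, chrom: int, karyotype: str) -> tuple[Interval, ...]:
        """Content carried by the given physical chromosome, in physical order.

        For the translocation carrier, chromosome 2 is [chr3 right arm][chr2
        core] (translocated segment at the left tip) and chromosome 3 is
        [chr3 core][chr2 left arm].
        """
        t2, t3 = self.translocation
        if karyotype == self.translocation_carrier:
            if chrom == 2:
                return (
                    Interval(3, t3, self.length(3)),
                    Interval(2, t2 + 1, self.length(2)),
                )
            if chrom == 3:
                return (Interval(3, 1, t3 - 1), Interval(2, 1, t2))
        return (Interval(chrom, 1, self.length(chrom)),)


def build_default_genome() -> GenomeSpec:
    """The default *Sp*/*Sk* genome with both published rearrangements."""
    t2, t3 = TRANSLOCATION_CHR2, TRANSLOCATION_CHR3
    l1, l2, l3 = (CHROM_LENGTHS[i] for i in (1, 2, 3))
    essential = (
        (Interval(1, 1, l1), "chr1_core"),
        (Interval(2, 1, t2), "chr2L_translocated_alr2"),
        (Interval(2, t2 + 1, l2), "chr2_core"),
        (Interval(3, 1, t3 - 1), "chr3_core"),
        (Interval(3, t3, l3), "chr3R_translocated_SPCP1E11.08"),
    )
    return GenomeSpec(
        chromosomes=tuple(ChromosomeSpec(i, CHROM_LENGTHS[i]) for i in (1, 2, 3)),
        inversion=Interval(1, INVERSION_START, INVERSION_END),
        translocation=(t2, t3),
        essential_segments=essential,
    )


def physical_to_genetic(span_bp: float, rate: float = CM_PER_KB) -> float:
    """Convert a physical span (bp) to genetic length (cM) at ``rate`` cM/kb."""
    if span_bp < 0:
        raise ValueError("physical span must be non-negative")
    if rate < 0:
        raise ValueError("map rate must be non-negative")
    return span_bp / 1000.0 * rate


def genetic_to_physical(cM: float, rate: float = CM_PER_KB) -> float:
    """Inverse of :func:`physical_to_genetic` (bp for a given cM at rate > 0)."""
    if cM < 0:
        raise ValueError("genetic length must be non-negative")
    if rate <= 0:
        raise ValueError("map rate must be positive")
    return cM / rate * 1000.0


@dataclass(frozen=True)
class ParentalChromosome:
    """One haploid chromosome contributed by a parent.

    ``ancestry`` lists (Interval, ancestry-label) pairs that must exactly tile
    the content regions of (``chrom``, ``karyotype``).
    """

    chrom: int
    karyotype: str
    ancestry: tuple[tuple[Interval, str], ...]

    @staticmethod
    def uniform(
        genome: GenomeSpec, chrom: int, karyotype: str, ancestry: str
    ) -> "ParentalChromosome":
        regions = genome.content_regions(chrom, karyotype)
        return ParentalChromosome(
            chrom, karyotype, tuple((r, ancestry) for r in regions)
        )

    def ancestry_at(self, chrom: int, pos: int) -> Optional[str]:
        for iv, anc in self.ancestry:
            if iv.contains(chrom, pos):
                return anc
        return None


Parent = tuple[ParentalChromosome, ParentalChromosome, ParentalChromosome]


def parent_from_code(genome: GenomeSpec, code: str) -> Parent:
    """Build a parent from a three-letter code like ``"PPP"`` or ``"PKK"``.

    Letter *i* gives both the karyotype and the (uniform) ancestry of
    chromosome *i*.  Recombinant ("R") chromosomes must be built explicitly
    with :class:`ParentalChromosome`.
    """
    if len(code) != 3 or any(c not in ANCESTRIES for c in code):
        raise ConfigError(f"bad parent code {code!r}")
    return tuple(
        ParentalChromosome.uniform(genome, i + 1, c, c) for i, c in enumerate(code)
    )  # type: ignore[return-value]


@dataclass(frozen=True)
class CrossConfig:
    """Everything defining one cross.

    ``rec12`` selects the crossover regime: ``"wt"`` gives a Poisson crossover
    process (Haldane model); ``"null"`` replaces it with a rare residual
    Rec12-independent event per chromosome per meiosis.  ``p_dist`` is the
    fidelity of the distributive (recombination-independent) segregation
    system for achiasmate homolog pairs.
    """

    genome: GenomeSpec
    parent1: Parent
    parent2: Parent
    drive: DriveModel = DriveModel()
    rec12: str = "wt"
    residual_rate: float = 0.005
    p_dist: float = 0.5
    seed: int = 0

    @property
    def parents(self) -> tuple[Parent, Parent]:
        return (self.parent1, self.parent2)

    def parental_alleles_at(self, chrom: int, pos: int) -> frozenset[str]:
        """All ancestry alleles present among the parents at a position."""
        out = set()
        for parent in self.parents:
            for pc in parent:
                a = pc.ancestry_at(chrom, pos)
                if a is not None:
                    out.add(a)
        return frozenset(out)

    def active_drivers(self) -> tuple[DriveLocus, ...]:
        """Drivers whose killer-ancestry allele is present in this cross."""
        return tuple(
            d
            for d in self.drive.drivers
            if d.killer in self.parental_alleles_at(d.chrom, d.pos)
        )

    def config_hash(self) -> str:
        payload = repr(
            (
                tuple(
                    (pc.chrom, pc.karyotype, pc.ancestry)
                    for parent in self.parents
                    for pc in parent
                ),
                self.drive,
                self.rec12,
                self.residual_rate,
                self.p_dist,
                self.genome,
            )
        ).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def _coverage_violations(genome: GenomeSpec, parent: Parent, who: str) -> list[str]:
    """Check that a haploid parent covers every essential segment exactly once."""
    out = []
    for seg, label in genome.essential_segments:
        n = 0
        for pc in parent:
            for region in genome.content_regions(pc.chrom, pc.karyotype):
                if (
                    region.chrom == seg.chrom
                    and region.start <= seg.start
                    and seg.end <= region.end
                ):
                    n += 1
        if n == 0:
            out.append(f"{who}: missing essential segment {label}")
        elif n > 1:
            out.append(f"{who}: essential segment {label} present {n} times")
    return out


def validate_config(cfg: CrossConfig) -> list[str]:
    """Return a list of violations; an empty list means the config is valid."""
    out: list[str] = []
    if cfg.rec12 not in ("wt", "null"):
        out.append(f"unknown rec12 status {cfg.rec12!r}")
    for name, val in (
        ("residual_rate", cfg.residual_rate),
        ("p_dist", cfg.p_dist),
    ):
        if not 0.0 <= val <= 1.0:
            out.append(f"{name} {val} outside [0, 1]")
    for d in cfg.drive.drivers:
        if not 0.0 <= d.strength <= 1.0:
            out.append(f"driver {d.name or d.chrom} strength {d.strength} outside [0, 1]")
        if not 1 <= d.pos <= cfg.genome.length(d.chrom):
            out.append(f"driver {d.name or d.chrom} position off chromosome")
    for who, parent in (("parent1", cfg.parent1), ("parent2", cfg.parent2)):
        if tuple(pc.chrom for pc in parent) != cfg.genome.chrom_ids:
            out.append(f"{who}: must carry one chromosome of each id, in order")
            continue
        out.extend(_coverage_violations(cfg.genome, parent, who))
        for pc in parent:
            regions = cfg.genome.content_regions(pc.chrom, pc.karyotype)
            covered = tuple(iv for iv, _ in pc.ancestry)
            if covered != regions:
                # ancestry must tile content regions; allow subdivision
                ok = _tiles(covered, regions)
                if not ok:
                    out.append(
                        f"{who} chromosome {pc.chrom}: ancestry segments do not "
                        "tile the content regions"
                    )
            for _, anc in pc.ancestry:
                if anc not in ANCESTRIES:
                    out.append(f"{who} chromosome {pc.chrom}: bad ancestry {anc!r}")
    return out


def _tiles(cover: Sequence[Interval], regions: Sequence[Interval]) -> bool:
    """True if ``cover`` exactly tiles ``regions`` in order (subdivision ok)."""
    i = 0
    for region in regions:
        pos = region.start
        while pos <= region.end:
            if i >= len(cover):
                return False
            iv = cover[i]
            if iv.chrom != region.chrom or iv.start != pos or iv.end > region.end:
                return False
            pos = iv.end + 1
            i += 1
    return i == len(cover)
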