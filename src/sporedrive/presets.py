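"""Named cross configurations replicating the study designs.

Marker and drive-locus coordinates are fixed package constants on the Sp
reference.  Gene positions are approximate reference coordinates chosen to
satisfy every published structural constraint (lys1/lys7 inside the
chromosome 1 inversion, all chromosome 2 markers on the
translocation-retained core, ade6/ura4 on the chromosome 3 core) and the
observed ordering of transmission biases; they are not base-accurate gene
annotations.

Default drive strengths for the fully heterozygous presets are the
single-locus maximum-likelihood estimates d = 2 - 1/t from the nearest
markers' observed transmissions (t = 0.72, 0.94, 0.82), i.e. derived
calibration values, not measured constants.  The weak *S. pombe* chromosome
3 counter-driver (strength 0.2) implements the heterozygote-resistance
(aneuploid rescue) hypothesis and is a labelled hypothesis, not a
measurement.
"""

from __future__ import annotations

from .genome import (
    SK,
    SP,
    CrossConfig,
    DriveLocus,
    DriveModel,
    GenomeSpec,
    Interval,
    Locus,
    ParentalChromosome,
    build_default_genome,
    parent_from_code,
)

#: Genotyping marker panel (Sp reference coordinates, approximate).
MARKERS: dict[str, Locus] = {
    "ura1": Locus("ura1", 1, 1_290_000),
    "arg3": Locus("arg3", 1, 2_000_000),
    "lys7": Locus("lys7", 1, 3_450_000),
    "lys1": Locus("lys1", 1, 4_100_000),
    "ade8": Locus("ade8", 2, 2_200_000),
    "lys4": Locus("lys4", 2, 2_350_000),
    "his4": Locus("his4", 2, 2_500_000),
    "his5": Locus("his5", 2, 2_830_000),
    "leu1": Locus("leu1", 2, 3_262_000),
    "ura4": Locus("ura4", 3, 116_000),
    "ade6": Locus("ade6", 3, 1_316_437),
}

#: Core panel used for routine genotyping and ploidy calls.
CORE_PANEL = ("lys1", "his5", "ade6")
EXTENDED_PANEL = tuple(MARKERS)

#: mat1-adjacent breakpoint of the KRK recombinant chromosome 2
#: (midpoint of the flanking SNPs 2,113,023 and 2,115,195).
R2_BREAKPOINT = 2_114_109
#: chr3 breakpoints of the KKR strain (midpoints of the flanking SNP pairs).
KKR_CHR2_TIP_BREAKPOINT = 2_291_600
R3_BREAKPOINT = 1_559_154

#: Calibrated killer strengths (single-locus MLEs of the nearest-marker
#: transmissions) and the hypothesized Sp chromosome 3 counter-driver.
D1_CALIBRATED = 2.0 - 1.0 / 0.72  # lys1, 72 % Sk transmission
D2_CALIBRATED = 2.0 - 1.0 / 0.94  # leu1, 94 %
D3_CALIBRATED = 2.0 - 1.0 / 0.82  # ade6, 82 %
D3_COUNTER = 0.2

DRIVER_POSITIONS = {"sdk1": (1, 4_050_000), "sdk2": (2, 3_270_000), "sdk3": (3, 1_310_000)}


def default_drive_model(
    d1: float = D1_CALIBRATED,
    d2: float = D2_CALIBRATED,
    d3: float = D3_CALIBRATED,
    counter: float = D3_COUNTER,
) -> DriveModel:
    """Three Sk killers (one per chromosome) plus the Sp chr3 counter-driver."""
    return DriveModel(
        (
            DriveLocus(*DRIVER_POSITIONS["sdk1"], killer=SK, strength=d1, name="sdk1"),
            DriveLocus(*DRIVER_POSITIONS["sdk2"], killer=SK, strength=d2, name="sdk2"),
            DriveLocus(*DRIVER_POSITIONS["sdk3"], killer=SK, strength=d3, name="sdk3"),
            DriveLocus(3, DRIVER_POSITIONS["sdk3"][1], killer=SP, strength=counter, name="sdp3"),
        )
    )


def no_drive_model() -> DriveModel:
    return default_drive_model(0.0, 0.0, 0.0, 0.0)


def _ancestry(genome: GenomeSpec, chrom: int, karyotype: str, segments):
    """Build a ParentalChromosome from (Interval, ancestry) pairs."""
    return ParentalChromosome(chrom, karyotype, tuple(segments))


def krk_chromosome2(genome: GenomeSpec) -> ParentalChromosome:
    """The KRK strain's recombinant chromosome 2 (Sk karyotype).

    Generated by a crossover with Sp chromosome 2 in the retained core near
    mat1: Sp ancestry distal to the breakpoint (his5, leu1 and the chr2
    driver side), Sk ancestry elsewhere including the translocated chr3
    right arm.
    """
    t2, t3 = genome.translocation
    l2, l3 = genome.length(2), genome.length(3)
    return _ancestry(
        genome,
        2,
        SK,
        (
            (Interval(3, t3, l3), SK),
            (Interval(2, t2 + 1, R2_BREAKPOINT), SK),
            (Interval(2, R2_BREAKPOINT + 1, l2), SP),
        ),
    )


def kkr_chromosome2(genome: GenomeSpec) -> ParentalChromosome:
    """The KKR strain's chromosome 2: Sk karyotype with an Sp-derived tip of
    the translocated chr3 right arm (crossover with Sp chromosome 3)."""
    t2, t3 = genome.translocation
    l2, l3 = genome.length(2), genome.length(3)
    return _ancestry(
        genome,
        2,
        SK,
        (
            (Interval(3, t3, KKR_CHR2_TIP_BREAKPOINT), SK),
            (Interval(3, KKR_CHR2_TIP_BREAKPOINT + 1, l3), SP),
            (Interval(2, t2 + 1, l2), SK),
        ),
    )


def kkr_chromosome3(genome: GenomeSpec) -> ParentalChromosome:
    """The KKR strain's recombinant chromosome 3 (Sk karyotype): Sp ancestry
    on the proximal core (ade6 and the chr3 driver side), Sk beyond the
    breakpoint and on the translocated chr2 left arm."""
    t2, t3 = genome.translocation
    return _ancestry(
        genome,
        3,
        SK,
        (
            (Interval(3, 1, R3_BREAKPOINT), SP),
            (Interval(3, R3_BREAKPOINT + 1, t3 - 1), SK),
            (Interval(2, 1, t2), SK),
        ),
    )


def collinear_parent(genome: GenomeSpec, ancestry: str) -> tuple:
    """A parent with the ancestral (Sk-like) karyotype on every chromosome
    but uniform ancestry ``ancestry``.  Crosses between two such parents are
    free of rearrangement heterozygosity (model-exploration configs)."""
    return tuple(
        ParentalChromosome.uniform(genome, i, SK, ancestry) for i in (1, 2, 3)
    )


def _preset(name: str) -> CrossConfig:
    genome = build_default_genome()
    drive = default_drive_model()
    wt = dict(rec12="wt", residual_rate=0.005, p_dist=0.5)
    null = dict(rec12="null", residual_rate=0.005, p_dist=0.5)
    if name == "PPPxKKK_wt":
        return CrossConfig(
            genome, parent_from_code(genome, "PPP"), parent_from_code(genome, "KKK"),
            drive, **wt,
        )
    if name == "PPPxKKK_rec12":
        return CrossConfig(
            genome, parent_from_code(genome, "PPP"), parent_from_code(genome, "KKK"),
            drive, **null,
        )
    if name == "PKKxKKK_rec12":
        return CrossConfig(
            genome, parent_from_code(genome, "PKK"), parent_from_code(genome, "KKK"),
            drive, **null,
        )
    if name == "KRKxKKK_rec12":
        k1 = ParentalChromosome.uniform(genome, 1, SK, SK)
        k3 = ParentalChromosome.uniform(genome, 3, SK, SK)
        parent1 = (k1, krk_chromosome2(genome), k3)
        return CrossConfig(
            genome, parent1, parent_from_code(genome, "KKK"), drive, **null
        )
    if name == "KKRxKKK_rec12":
        k1 = ParentalChromosome.uniform(genome, 1, SK, SK)
        parent1 = (k1, kkr_chromosome2(genome), kkr_chromosome3(genome))
        return CrossConfig(
            genome, parent1, parent_from_code(genome, "KKK"), drive, **null
        )
    if name in ("KKKxKKK_wt", "KKKxKKK_rec12", "PPPxPPP_wt", "PPPxPPP_rec12"):
        code = name[:3]
        mode = wt if name.endswith("_wt") else null
        return CrossConfig(
            genome,
            parent_from_code(genome, code),
            parent_from_code(genome, code),
            drive,
            **mode,
        )
    if name in ("collinear_hybrid_wt", "collinear_hybrid_rec12"):
        mode = wt if name.endswith("_wt") else null
        return CrossConfig(
            genome,
            collinear_parent(genome, SP),
            collinear_parent(genome, SK),
            drive,
            **mode,
        )
    raise KeyError(f"unknown preset {name!r}")


PRESET_NAMES = (
    "PPPxKKK_wt",
    "PPPxKKK_rec12",
    "PKKxKKK_rec12",
    "KRKxKKK_rec12",
    "KKRxKKK_rec12",
    "KKKxKKK_wt",
    "KKKxKKK_rec12",
    "PPPxPPP_wt",
    "PPPxPPP_rec12",
    "collinear_hybrid_wt",
    "collinear_hybrid_rec12",
)


def preset(name: str, **overrides) -> CrossConfig:
    """A fully specified named cross configuration.

    Keyword overrides replace CrossConfig fields (e.g. ``p_dist=0.0``,
    ``drive=no_drive_model()``, ``residual_rate=0.0``, ``seed=...``).
    """
    cfg = _preset(name)
    if overrides:
        import dataclasses

        cfg = dataclasses.replace(cfg, **overrides)
    return cfg
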