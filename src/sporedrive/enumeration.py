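"""Exact spore-class distribution for crossover-free meiosis.

With no crossovers, the three bivalents segregate independently and each
chromosome of a random spore has one of four outcomes: the parent-1 homolog
(``A``), the parent-2 homolog (``B``), both (``AB``, a heterozygous
2-copy class) or neither (``0``).  With distributive-system fidelity
``p_dist`` the per-chromosome probabilities are

    P(A) = P(B) = q/2,   P(AB) = P(0) = (1 - q)/2,   q = (1 + p_dist)/2,

so the joint distribution over the 64 spore classes is an exact product.
Deterministic viability rules are applied per class and gamete-killer drive
is applied in expectation (survival weights), which makes this module both
the Monte-Carlo oracle and the likelihood kernel for inference.

At ``p_dist = 0`` the viable-complement probability (haploid, diploid, or
chromosome 3 disome, no rearrangement heterozygosity) is 13/64 ≈ 20.3%;
partial distributive fidelity raises it (≥ 25% from p_dist ≈ 0.2 up).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .genome import ConfigError, CrossConfig, Locus
from .meiosis import Chromatid, Spore
from .viability import (
    assess_spore,
    drive_survival_prob,
)

OUTCOMES = ("A", "B", "AB", "0")

ClassKey = tuple[str, str, str]


class UnsupportedModeError(ConfigError):
    """Enumeration requires a crossover-free (rec12-null) configuration."""


@dataclass
class SporeClass:
    key: ClassKey
    spore: Spore
    prob_pre: float
    prob_post: float
    cause: str | None  # deterministic death cause, if any
    drive_weight: float


@dataclass
class ClassDistribution:
    """Exact pre- and post-viability probabilities of the 64 spore classes."""

    classes: list[SporeClass]
    cfg: CrossConfig

    @property
    def viable_fraction(self) -> float:
        return sum(c.prob_post for c in self.classes)

    def total_pre(self) -> float:
        return sum(c.prob_pre for c in self.classes)


def _class_spore(cfg: CrossConfig, key: ClassKey) -> Spore:
    chromatids: list[Chromatid] = []
    for chrom_idx, outcome in enumerate(key):
        for origin, parent in ((0, cfg.parent1), (1, cfg.parent2)):
            label = "A" if origin == 0 else "B"
            if outcome in (label, "AB"):
                chromatids.append(
                    Chromatid.from_parental(cfg.genome, parent[chrom_idx], origin)
                )
    return Spore(chromatids)


def enumerate_no_crossover(cfg: CrossConfig) -> ClassDistribution:
    """Exact class distribution for a crossover-free meiosis.

    The configuration must be in rec12-null mode; the residual
    Rec12-independent event rate is treated as zero.
    """
    if cfg.rec12 != "null":
        raise UnsupportedModeError(
            "exact enumeration supports only rec12-null configurations"
        )
    q = (1.0 + cfg.p_dist) / 2.0
    probs = {"A": q / 2, "B": q / 2, "AB": (1 - q) / 2, "0": (1 - q) / 2}
    active = cfg.active_drivers()
    classes = []
    for key in itertools.product(OUTCOMES, repeat=3):
        p_pre = probs[key[0]] * probs[key[1]] * probs[key[2]]
        spore = _class_spore(cfg, key)  # type: ignore[arg-type]
        verdict = assess_spore(spore, cfg.genome, active, rng=None)
        if verdict.alive:
            weight = drive_survival_prob(spore, active, active=active)
            cause = None
        else:
            weight = 0.0
            cause = verdict.cause
        classes.append(
            SporeClass(
                key=key,  # type: ignore[arg-type]
                spore=spore,
                prob_pre=p_pre,
                prob_post=p_pre * weight,
                cause=cause,
                drive_weight=weight,
            )
        )
    return ClassDistribution(classes, cfg)


def viable_fraction(cfg: CrossConfig, classes: str = "all") -> float:
    """Sum of post-viability class probabilities.

    ``classes`` restricts the sum: ``"all"``, ``"haploid"`` (copy number
    (1,1,1)), ``"diploid"`` or ``"chr3_disome"``.
    """
    dist = enumerate_no_crossover(cfg)
    wanted = {
        "all": None,
        "haploid": (1, 1, 1),
        "diploid": (2, 2, 2),
        "chr3_disome": (1, 1, 2),
    }[classes]
    total = 0.0
    for c in dist.classes:
        if wanted is None or c.spore.copy_number() == wanted:
            total += c.prob_post
    return total


def expected_transmission(
    cfg: CrossConfig, locus: Locus, killer: str = "K"
) -> float:
    """P(a viable single-allele spore carries the killer-species allele).

    Classes heterozygous at the locus are excluded from the denominator,
    emulating the assay's exclusion of heterozygous diploids (and, for
    chromosome 3 loci, heterozygous aneuploids).
    """
    dist = enumerate_no_crossover(cfg)
    num = den = 0.0
    for c in dist.classes:
        if c.prob_post == 0.0:
            continue
        alleles = c.spore.genotype_at(locus.chrom, locus.pos)
        if len(alleles) != 1:
            continue
        den += c.prob_post
        if killer in alleles:
            num += c.prob_post
    if den == 0.0:
        raise ZeroDivisionError(
            f"no viable single-allele class at locus {locus.name}"
        )
    return num / den


def to_rows(dist: ClassDistribution) -> list[dict]:
    """Flat export of a class distribution (for the TSV interface)."""
    rows = []
    for c in dist.classes:
        rows.append(
            {
                "class": "/".join(c.key),
                "copy_number": ",".join(map(str, c.spore.copy_number())),
                "probability_pre": c.prob_pre,
                "probability_post": c.prob_post,
                "deterministic_cause": c.cause or "",
                "drive_weight": c.drive_weight,
            }
        )
    return rows
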