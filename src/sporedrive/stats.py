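"""Descriptive statistics on spore tables.

Viable spore yield, transmission bias with the G-test, Haldane two-point
mapping, aneuploids produced per meiosis, and the single-driver
transmission-distance curve t(r) = (1 - r·d)/(2 - d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class FertilityResult:
    """Viable spore yield: viable colonies per cell plated.

    A relative fertility measure; because cells may divide before meiosis
    the value can exceed 4.
    """

    viable_colonies: int
    cells_plated: int
    yield_: float


@dataclass(frozen=True)
class TransmissionResult:
    n_killer: int
    n_other: int
    t: float
    G: float
    p_value: float


@dataclass(frozen=True)
class GeneticInterval:
    parentals: int
    recombinants: int
    r: float
    cM: Optional[float]  # None when r >= 0.5 (unlinked)

    @property
    def unlinked(self) -> bool:
        return self.cM is None


def viable_spore_yield(viable_colonies: int, cells_plated: int) -> FertilityResult:
    if cells_plated <= 0:
        raise ValueError("cells_plated must be positive")
    if viable_colonies < 0:
        raise ValueError("viable_colonies must be non-negative")
    return FertilityResult(viable_colonies, cells_plated, viable_colonies / cells_plated)


def g_statistic(observed: tuple[int, int], williams: bool = False) -> float:
    """Goodness-of-fit G against a 50:50 expectation (zero cells contribute 0)."""
    n = sum(observed)
    e = n / 2.0
    g = 2.0 * sum(o * math.log(o / e) for o in observed if o > 0)
    if williams:
        # Williams correction for a 1-df, two-cell goodness-of-fit test
        g /= 1.0 + 1.0 / (2.0 * n)
    return g


def transmission_test(
    n_killer: int, n_other: int, williams: bool = False
) -> TransmissionResult:
    """Transmission proportion with a 1-df two-sided G-test against 50:50."""
    if n_killer < 0 or n_other < 0:
        raise ValueError("counts must be non-negative")
    n = n_killer + n_other
    if n == 0:
        raise ValueError("at least one spore is required")
    g = g_statistic((n_killer, n_other), williams=williams)
    return TransmissionResult(
        n_killer, n_other, n_killer / n, g, float(sps.chi2.sf(g, df=1))
    )


def haldane_cM(r: float) -> float:
    """Map distance (cM) from a recombinant fraction, Haldane's function."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombinant fraction {r} outside [0, 0.5): unlinked")
    return -50.0 * math.log(1.0 - 2.0 * r)


def haldane_r(cM: float) -> float:
    """Recombinant fraction from map distance (cM), inverse Haldane."""
    if cM < 0:
        raise ValueError("map distance must be non-negative")
    return (1.0 - math.exp(-2.0 * cM / 100.0)) / 2.0


def interval_from_counts(parentals: int, recombinants: int) -> GeneticInterval:
    """Two-point interval from per-spore parental/recombinant counts."""
    total = parentals + recombinants
    if total <= 0:
        raise ValueError("at least one spore is required")
    r = recombinants / total
    cM = haldane_cM(r) if r < 0.5 else None
    return GeneticInterval(parentals, recombinants, r, cM)


def aneuploids_per_meiosis(
    yield_result: FertilityResult | float, fraction_aneuploid_or_diploid: float
) -> float:
    """Aneuploid-or-diploid viable spores produced per cell induced to
    undergo meiosis: viable spore yield × fraction of viable spores that are
    aneuploid or diploid."""
    if not 0.0 <= fraction_aneuploid_or_diploid <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    y = (
        yield_result.yield_
        if isinstance(yield_result, FertilityResult)
        else float(yield_result)
    )
    return y * fraction_aneuploid_or_diploid


def transmission_curve(d: float, r: float) -> float:
    """Expected killer-allele transmission among surviving haploids.

    Single driver of strength ``d``, marker at recombinant fraction ``r``
    from the driver: t = (1 - r·d)/(2 - d).
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("drive strength outside [0, 1]")
    if not 0.0 <= r <= 0.5:
        raise ValueError("recombinant fraction outside [0, 0.5]")
    return (1.0 - r * d) / (2.0 - d)


def table_transmission(
    df: pd.DataFrame, locus: str, killer: str = "K", williams: bool = False
) -> TransmissionResult:
    """Transmission test for one marker column of a spore table.

    Only viable spores with a single-allele call at the locus are counted
    (heterozygous calls — and hence heterozygous diploids, and heterozygous
    aneuploids for chromosome 3 markers — are excluded, as in the assay).
    """
    if locus not in df.columns:
        raise KeyError(f"no column {locus!r} in table")
    sub = df
    if "viability" in df.columns:
        sub = df[df["viability"] == "alive"]
    calls = sub[locus]
    n_k = int((calls == killer).sum())
    others = [a for a in ("K", "P") if a != killer]
    n_o = int(calls.isin(others).sum())
    return transmission_test(n_k, n_o, williams=williams)


def table_interval(
    df: pd.DataFrame, locus_a: str, locus_b: str
) -> GeneticInterval:
    """Two-point interval between two marker columns of a spore table.

    Scored per spore over viable spores with single-allele calls at both
    markers; recombinants carry different ancestries at the two loci.
    """
    sub = df
    if "viability" in df.columns:
        sub = df[df["viability"] == "alive"]
    single = sub[sub[locus_a].isin(("K", "P")) & sub[locus_b].isin(("K", "P"))]
    rec = int((single[locus_a] != single[locus_b]).sum())
    par = len(single) - rec
    return interval_from_counts(par, rec)
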