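"""Forward simulation of one meiosis of a configured diploid.

Crossovers follow a Haldane-consistent model: the number of exchange events
per bivalent is Poisson with mean 2d (d = genetic length in Morgans), each
event picks one chromatid from each homolog uniformly and its position is
uniform in genetic (equivalently, at a uniform map rate, physical) distance
within the region of shared homology.  There is no chiasma or chromatid
interference, which reproduces Haldane's mapping function exactly.

Segregation: a bivalent with at least one crossover always disjoins properly
at MI.  An achiasmate bivalent disjoins properly with probability ``p_dist``
(the distributive-system fidelity); otherwise each homolog independently
picks a pole, so a spore ends up with 1 copy w.p. 1/2 and 0 or 2 copies
w.p. 1/4 each when ``p_dist = 0``.  MII always separates sisters.

In a heterokaryotypic pair, homology is restricted to the content shared by
the two physical chromosomes (for the translocation, the retained core; the
inversion leaves content homologous throughout chromosome 1).  A chromatid
that derives from an odd number of crossovers inside a heterozygous
inversion is flagged unbalanced (duplication/deficiency product).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome import (
    ConfigError,
    CrossConfig,
    GenomeSpec,
    Interval,
    Locus,
    ParentalChromosome,
    physical_to_genetic,
    validate_config,
)

HAPLOID = "haploid"
HET_DIPLOID = "het_diploid"
HET_CHR3_ANEUPLOID = "het_chr3_aneuploid"
PLOIDY_CLASSES = (HAPLOID, HET_DIPLOID, HET_CHR3_ANEUPLOID)


@dataclass
class Chromatid:
    """One meiotic chromatid.

    ``layout`` is the fixed physical content of the (chromosome, karyotype)
    pair; ``ancestry`` is a list of half-open segments in the chromatid's own
    physical coordinate (0-based offsets over the concatenated layout), each
    labelled with an ancestry.  ``origin`` records the contributing parent
    (0 or 1).  ``inv_crossovers`` counts crossovers inside a heterozygous
    inversion; odd parity marks the chromatid unbalanced.
    """

    chrom: int
    karyotype: str
    layout: tuple[Interval, ...]
    ancestry: list[tuple[int, int, str]]
    origin: int
    inv_crossovers: int = 0

    @property
    def phys_length(self) -> int:
        return sum(iv.length for iv in self.layout)

    @property
    def balanced(self) -> bool:
        return self.inv_crossovers % 2 == 0

    @classmethod
    def from_parental(
        cls, genome: GenomeSpec, pc: ParentalChromosome, origin: int
    ) -> "Chromatid":
        layout = genome.content_regions(pc.chrom, pc.karyotype)
        # map ancestry segments (content coordinates) to physical offsets
        offsets = _region_offsets(layout)
        segs: list[tuple[int, int, str]] = []
        for iv, anc in pc.ancestry:
            for region, off in zip(layout, offsets):
                if iv.chrom == region.chrom and region.start <= iv.start <= region.end:
                    start = off + (iv.start - region.start)
                    segs.append((start, start + iv.length, anc))
                    break
            else:
                raise ConfigError(
                    f"ancestry segment {iv} outside content of chromosome "
                    f"{pc.chrom} ({pc.karyotype} karyotype)"
                )
        segs.sort()
        return cls(pc.chrom, pc.karyotype, layout, _merge(segs), origin)

    def phys_offset(self, chrom: int, pos: int) -> Optional[int]:
        off = 0
        for region in self.layout:
            if region.contains(chrom, pos):
                return off + (pos - region.start)
            off += region.length
        return None

    def allele_at(self, chrom: int, pos: int) -> Optional[str]:
        off = self.phys_offset(chrom, pos)
        if off is None:
            return None
        for s, e, anc in self.ancestry:
            if s <= off < e:
                return anc
        raise AssertionError("ancestry does not tile the chromatid")

    def content_suffix(self, offset: int) -> tuple[tuple[int, int, int], ...]:
        """Content (chrom, start, end) carried beyond a physical offset."""
        out = []
        off = 0
        for region in self.layout:
            lo = max(offset, off)
            hi = off + region.length
            if lo < hi:
                out.append(
                    (region.chrom, region.start + (lo - off), region.end)
                )
            off = hi
        return tuple(out)


def _region_offsets(layout: Sequence[Interval]) -> list[int]:
    offsets, off = [], 0
    for region in layout:
        offsets.append(off)
        off += region.length
    return offsets


def _merge(segs: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    out: list[tuple[int, int, str]] = []
    for s, e, anc in segs:
        if out and out[-1][1] == s and out[-1][2] == anc:
            out[-1] = (out[-1][0], e, anc)
        else:
            out.append((s, e, anc))
    return out


def _split(
    segs: list[tuple[int, int, str]], off: int
) -> tuple[list[tuple[int, int, str]], list[tuple[int, int, str]]]:
    head, tail = [], []
    for s, e, anc in segs:
        if e <= off:
            head.append((s, e, anc))
        elif s >= off:
            tail.append((s, e, anc))
        else:
            head.append((s, off, anc))
            tail.append((off, e, anc))
    return head, tail


def _layout_split(layout: Sequence[Interval], offset: int):
    """Split a layout's content regions at a physical offset."""
    head, tail = [], []
    off = 0
    for region in layout:
        hi = off + region.length
        if hi <= offset:
            head.append(region)
        elif off >= offset:
            tail.append(region)
        else:
            cut = region.start + (offset - off)
            head.append(Interval(region.chrom, region.start, cut - 1))
            tail.append(Interval(region.chrom, cut, region.end))
        off = hi
    return head, tail


def exchange_tails(a: Chromatid, b: Chromatid, chrom: int, pos: int) -> None:
    """Reciprocally exchange everything downstream of a crossover position.

    Both the content layout and the ancestry labels beyond the event are
    swapped.  In a homokaryotypic pair (or a heterozygous inversion, where
    content is collinear in ancestry coordinates) this only exchanges
    ancestry; in a translocation heterozygote's shared core it also
    exchanges the downstream translocated content, which is what generates
    the rare viable "R"-type recombinant chromosomes.
    """
    oa = a.phys_offset(chrom, pos)
    ob = b.phys_offset(chrom, pos)
    if oa is None or ob is None:
        raise ValueError(f"crossover position {chrom}:{pos} not on both chromatids")
    head_la, tail_la = _layout_split(a.layout, oa)
    head_lb, tail_lb = _layout_split(b.layout, ob)
    head_a, tail_a = _split(a.ancestry, oa)
    head_b, tail_b = _split(b.ancestry, ob)
    shift = oa - ob
    a.layout = tuple(head_la + tail_lb)
    b.layout = tuple(head_lb + tail_la)
    a.ancestry = _merge(head_a + [(s + shift, e + shift, x) for s, e, x in tail_b])
    b.ancestry = _merge(head_b + [(s - shift, e - shift, x) for s, e, x in tail_a])


@dataclass(frozen=True)
class CrossoverEvent:
    chrom: int  # content chromosome of the Sp reference
    pos: int
    chromatid_a: int  # 0 or 1, chromatid index within homolog A
    chromatid_b: int


def shared_homology(
    genome: GenomeSpec, homA: ParentalChromosome, homB: ParentalChromosome
) -> tuple[Interval, ...]:
    """Content intervals shared by the two homologs, in A's physical order."""
    regions_b = genome.content_regions(homB.chrom, homB.karyotype)
    out = []
    for ra in genome.content_regions(homA.chrom, homA.karyotype):
        for rb in regions_b:
            if ra.chrom != rb.chrom:
                continue
            lo, hi = max(ra.start, rb.start), min(ra.end, rb.end)
            if lo <= hi:
                out.append(Interval(ra.chrom, lo, hi))
    return tuple(out)


def draw_crossovers(
    genome: GenomeSpec,
    homA: ParentalChromosome,
    homB: ParentalChromosome,
    rec12: str,
    residual_rate: float,
    rng: np.random.Generator,
) -> list[CrossoverEvent]:
    """Sample crossover events for one bivalent.

    wt: Poisson count with mean 2d (d in Morgans over the shared homology);
    rec12-null: a single residual event with probability ``residual_rate``.
    Positions are uniform in genetic distance; at a uniform map rate this is
    uniform in physical distance over the shared homology.
    """
    homology = shared_homology(genome, homA, homB)
    total_bp = sum(iv.length for iv in homology)
    if total_bp == 0:
        return []
    if rec12 == "wt":
        morgans = physical_to_genetic(total_bp, genome.cM_per_kb) / 100.0
        n = int(rng.poisson(2.0 * morgans))
    elif rec12 == "null":
        n = int(rng.random() < residual_rate)
    else:
        raise ConfigError(f"unknown rec12 status {rec12!r}")
    events = []
    for _ in range(n):
        x = int(rng.integers(total_bp))
        for iv in homology:
            if x < iv.length:
                pos = iv.start + x
                chrom = iv.chrom
                break
            x -= iv.length
        events.append(
            CrossoverEvent(chrom, pos, int(rng.integers(2)), int(rng.integers(2)))
        )
    # apply in physical order along homolog A's layout
    offsets = {}
    off = 0
    for region in genome.content_regions(homA.chrom, homA.karyotype):
        offsets[(region.chrom, region.start)] = (region, off)
        off += region.length

    def order(ev: CrossoverEvent) -> int:
        o = 0
        for region in genome.content_regions(homA.chrom, homA.karyotype):
            if region.contains(ev.chrom, ev.pos):
                return o + (ev.pos - region.start)
            o += region.length
        raise AssertionError

    events.sort(key=order)
    return events


def meiose_bivalent(
    genome: GenomeSpec,
    homA: ParentalChromosome,
    homB: ParentalChromosome,
    events: Sequence[CrossoverEvent],
) -> list[list[Chromatid]]:
    """Replicate homologs into sister chromatids and apply crossovers.

    Crossover events are positioned on the four aligned chromatid axes of
    the bivalent, so they are swept left to right and each event exchanges
    the tails of whichever recombinant products currently occupy the two
    chosen axes (a product switches axis at every exchange it takes part
    in).  Returns the four products grouped into two pairs for MI.
    """
    products = [Chromatid.from_parental(genome, homA, 0) for _ in range(2)] + [
        Chromatid.from_parental(genome, homB, 1) for _ in range(2)
    ]
    axis_a, axis_b = [0, 1], [2, 3]
    het_inversions = [
        iv
        for iv, carrier in genome.inversions_on(homA.chrom)
        if (homA.karyotype == carrier) != (homB.karyotype == carrier)
    ]
    for ev in events:  # events are sorted by physical position
        iu, iv_ = axis_a[ev.chromatid_a], axis_b[ev.chromatid_b]
        u, v = products[iu], products[iv_]
        exchange_tails(u, v, ev.chrom, ev.pos)
        axis_a[ev.chromatid_a], axis_b[ev.chromatid_b] = iv_, iu
        if any(iv.contains(ev.chrom, ev.pos) for iv in het_inversions):
            u.inv_crossovers += 1
            v.inv_crossovers += 1
    return [[products[0], products[1]], [products[2], products[3]]]


def segregate(
    bivalent: list[list[Chromatid]],
    n_crossovers: int,
    p_dist: float,
    rng: np.random.Generator,
) -> list[list[Chromatid]]:
    """MI pole assignment and MII sister separation -> 4 chromatid sets.

    Spores 0,1 derive from MI pole 0 and spores 2,3 from pole 1.
    """
    if n_crossovers >= 1 or rng.random() < p_dist:
        pole_a = int(rng.integers(2))
        pole_b = 1 - pole_a
    else:
        pole_a = int(rng.integers(2))
        pole_b = int(rng.integers(2))
    spores: list[list[Chromatid]] = [[], [], [], []]
    for sisters, pole in ((bivalent[0], pole_a), (bivalent[1], pole_b)):
        first = int(rng.integers(2))
        spores[2 * pole].append(sisters[first])
        spores[2 * pole + 1].append(sisters[1 - first])
    return spores


@dataclass
class ViabilityVerdict:
    """Outcome of the spore-death rules for one spore."""

    alive: bool
    cause: Optional[str] = None
    survival_prob: float = 1.0


@dataclass
class Spore:
    """One meiotic product: chromatids, copy numbers, viability state."""

    chromatids: list[Chromatid]
    verdict: Optional[ViabilityVerdict] = None

    def copy_number(self, chrom_ids: Iterable[int] = (1, 2, 3)) -> tuple[int, ...]:
        return tuple(
            sum(1 for c in self.chromatids if c.chrom == i) for i in chrom_ids
        )

    def genotype_at(self, chrom: int, pos: int) -> frozenset[str]:
        alleles = set()
        for c in self.chromatids:
            a = c.allele_at(chrom, pos)
            if a is not None:
                alleles.add(a)
        return frozenset(alleles)

    def origins(self, chrom: int) -> tuple[int, ...]:
        return tuple(sorted(c.origin for c in self.chromatids if c.chrom == chrom))


@dataclass
class Tetrad:
    """The four spores of one meiosis."""

    spores: tuple[Spore, Spore, Spore, Spore]

    def __iter__(self):
        return iter(self.spores)


def simulate_meiosis(cfg: CrossConfig, rng: np.random.Generator) -> Tetrad:
    """Simulate one meiosis; viability rules are applied separately."""
    spore_chromatids: list[list[Chromatid]] = [[], [], [], []]
    for i, (homA, homB) in enumerate(zip(cfg.parent1, cfg.parent2)):
        events = draw_crossovers(
            cfg.genome, homA, homB, cfg.rec12, cfg.residual_rate, rng
        )
        bivalent = meiose_bivalent(cfg.genome, homA, homB, events)
        for spore_idx, chromatids in enumerate(
            segregate(bivalent, len(events), cfg.p_dist, rng)
        ):
            spore_chromatids[spore_idx].extend(chromatids)
    return Tetrad(tuple(Spore(c) for c in spore_chromatids))  # type: ignore[arg-type]


def genotype_at(spore: Spore, locus: Locus, genome: GenomeSpec) -> frozenset[str]:
    """Set of ancestry alleles present at a marker position.

    Translocated arrangements are handled by ancestry lookup in Sp-reference
    content coordinates, not physical order.
    """
    if not 1 <= locus.pos <= genome.length(locus.chrom):
        raise ValueError(f"locus {locus.name} outside chromosome {locus.chrom}")
    return spore.genotype_at(locus.chrom, locus.pos)


def classify_spore(spore: Spore, chr2_marker: Locus, chr3_marker: Locus) -> str:
    """Assay-style ploidy call from codominant chr2/chr3 markers.

    Both chr2 alleles -> heterozygous diploid; both chr3 alleles with a single
    chr2 allele -> heterozygous chr3 aneuploid; anything else is called
    haploid.  Homozygous diploids and disomes are deliberately miscounted as
    haploids, emulating the marker assay.
    """
    if chr2_marker.chrom != 2 or chr3_marker.chrom != 3:
        raise ValueError("classification needs codominant chr2 and chr3 markers")
    g2 = spore.genotype_at(chr2_marker.chrom, chr2_marker.pos)
    g3 = spore.genotype_at(chr3_marker.chrom, chr3_marker.pos)
    if len(g2) == 2:
        return HET_DIPLOID
    if len(g3) == 2:
        return HET_CHR3_ANEUPLOID
    return HAPLOID
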