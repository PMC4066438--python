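"""TOML cross-configuration files.

Example::

    seed = 7

    [parents]
    parent1 = "PPP"
    parent2 = "KKK"

    [[drive]]
    chrom = 1
    pos = 4050000
    killer = "K"
    strength = 0.61
    name = "sdk1"

    [recombination]
    rec12 = "wt"          # "wt" | "null"
    residual_rate = 0.005

    [segregation]
    p_dist = 0.5

    [genome]              # optional overrides
    cM_per_kb = 0.16

A parent may also be given as an array of chromosome tables with explicit
``karyotype`` and ``ancestry`` segments (for recombinant chromosomes)::

    [parents]
    parent2 = "KKK"
    [[parents.parent1]]
    chrom = 1
    karyotype = "K"
    ancestry = [[1, 1, 5579133, "K"]]
"""

from __future__ import annotations

import dataclasses
import tomllib

from .genome import (
    ConfigError,
    CrossConfig,
    DriveLocus,
    DriveModel,
    GenomeSpec,
    Interval,
    ParentalChromosome,
    build_default_genome,
    parent_from_code,
)


def _parse_parent(genome: GenomeSpec, spec):
    if isinstance(spec, str):
        return parent_from_code(genome, spec)
    if isinstance(spec, list):
        chroms = []
        for entry in spec:
            ancestry = tuple(
                (Interval(int(c), int(s), int(e)), anc)
                for c, s, e, anc in entry["ancestry"]
            )
            chroms.append(
                ParentalChromosome(int(entry["chrom"]), entry["karyotype"], ancestry)
            )
        return tuple(sorted(chroms, key=lambda pc: pc.chrom))
    raise ConfigError(f"cannot parse parent spec {spec!r}")


def load_cross_config(path) -> CrossConfig:
    """Read a cross configuration from a TOML file."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    genome = build_default_genome()
    if "genome" in raw:
        over = raw["genome"]
        fields = {}
        if "cM_per_kb" in over:
            fields["cM_per_kb"] = float(over["cM_per_kb"])
        genome = dataclasses.replace(genome, **fields)
    try:
        parents = raw["parents"]
        parent1 = _parse_parent(genome, parents["parent1"])
        parent2 = _parse_parent(genome, parents["parent2"])
    except KeyError as exc:
        raise ConfigError(f"missing [parents] entry: {exc}") from exc
    drivers = tuple(
        DriveLocus(
            chrom=int(d["chrom"]),
            pos=int(d["pos"]),
            killer=d["killer"],
            strength=float(d["strength"]),
            name=d.get("name", ""),
        )
        for d in raw.get("drive", [])
    )
    rec = raw.get("recombination", {})
    seg = raw.get("segregation", {})
    return CrossConfig(
        genome=genome,
        parent1=parent1,
        parent2=parent2,
        drive=DriveModel(drivers),
        rec12=rec.get("rec12", "wt"),
        residual_rate=float(rec.get("residual_rate", 0.005)),
        p_dist=float(seg.get("p_dist", 0.5)),
        seed=int(raw.get("seed", 0)),
    )
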