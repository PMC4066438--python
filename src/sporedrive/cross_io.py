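"""Synthetic spore-table generation and TSV input/output.

A spore table records one row per surviving spore (optionally per spore
including dead ones in full-census mode): marker genotype calls, the
assay-style ploidy class, viability and cause of death.  Files are
tab-delimited UTF-8 with ``#``-prefixed header lines carrying the config
hash, seed and package version, so identical seed + configuration gives a
byte-identical file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .genome import ConfigError, CrossConfig, Locus, validate_config
from .meiosis import classify_spore, genotype_at, simulate_meiosis
from .presets import CORE_PANEL, MARKERS
from .viability import apply_viability

REQUIRED_COLUMNS = ("meiosis_id", "spore_id", "ploidy_class", "viability", "cause")


@dataclass
class SporeTable:
    """A spore table: pandas DataFrame plus provenance metadata."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def viable(self) -> pd.DataFrame:
        if "viability" in self.df.columns:
            return self.df[self.df["viability"] == "alive"]
        return self.df

    def marker_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in REQUIRED_COLUMNS]

    def __len__(self) -> int:
        return len(self.df)


def _call(alleles: frozenset[str]) -> str:
    if not alleles:
        return "-"
    return "/".join(sorted(alleles))


def generate_cross_table(
    cfg: CrossConfig,
    n_meioses: int,
    seed: int | None = None,
    panel: tuple[str, ...] = CORE_PANEL,
    full_census: bool = False,
) -> SporeTable:
    """Simulate ``n_meioses`` tetrads, apply viability, and tabulate spores.

    By default only viable spores are recorded (what the assay can see);
    ``full_census=True`` records dead spores too, for testing.  The result
    is deterministic given seed and configuration.
    """
    violations = validate_config(cfg)
    if violations:
        raise ConfigError("; ".join(violations))
    if n_meioses <= 0:
        raise ValueError("n_meioses must be positive")
    loci = [MARKERS[name] if isinstance(name, str) else name for name in panel]
    chr2_marker = next(l for l in loci if l.chrom == 2)
    chr3_marker = next(l for l in loci if l.chrom == 3)
    used_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    active = cfg.active_drivers()
    rows = []
    for m in range(n_meioses):
        tetrad = simulate_meiosis(cfg, rng)
        apply_viability(tetrad, cfg.genome, cfg.drive, rng, active)
        for s, spore in enumerate(tetrad):
            assert spore.verdict is not None
            if not spore.verdict.alive and not full_census:
                continue
            row = {"meiosis_id": m, "spore_id": s}
            for locus in loci:
                row[locus.name] = _call(genotype_at(spore, locus, cfg.genome))
            row["ploidy_class"] = classify_spore(spore, chr2_marker, chr3_marker)
            row["viability"] = "alive" if spore.verdict.alive else "dead"
            row["cause"] = spore.verdict.cause or ""
            rows.append(row)
    columns = ["meiosis_id", "spore_id", *[l.name for l in loci],
               "ploidy_class", "viability", "cause"]
    df = pd.DataFrame(rows, columns=columns)
    meta = {
        "config_hash": cfg.config_hash(),
        "seed": used_seed,
        "n_meioses": n_meioses,
        "version": __version__,
    }
    return SporeTable(df, meta)


def write_spore_table(table: SporeTable, path) -> None:
    """Write a spore table as '#'-headed TSV (UTF-8, no quoting)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key in sorted(table.meta):
            fh.write(f"# {key}={table.meta[key]}\n")
        table.df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_spore_table(path) -> SporeTable:
    """Read a spore table written by :func:`write_spore_table`.

    Unknown columns are preserved; malformed rows raise a parse error with
    the offending line number; a zero-row table is valid.
    """
    meta: dict = {}
    header: list[str] | None = None
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in REQUIRED_COLUMNS if c not in header]
                if missing:
                    raise ValueError(
                        f"{path}: missing required column(s): {', '.join(missing)}"
                    )
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            rows.append(fields)
    if header is None:
        raise ValueError(f"{path}: no header line found")
    df = pd.DataFrame(rows, columns=header)
    for col in ("meiosis_id", "spore_id"):
        df[col] = df[col].astype(int) if len(df) else df[col].astype("int64")
    return SporeTable(df, meta)
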