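"""Maximum-likelihood estimation of gamete-killer strengths and positions.

For recombination-free (rec12-null) spore tables the exact enumeration
kernel gives the class probabilities in closed form, so killer strengths are
estimated by a survivorship-conditioned multinomial likelihood over the
observable spore classes (marker genotype calls + assay ploidy class); dead
spores are unobservable and never enter the likelihood.

Driver positions are only coarsely identifiable; they are estimated from
multi-marker transmission counts with the single-driver curve
t(x) = (1 - r(x)·d)/(2 - d), r(x) from Haldane at the genome-average map
rate, on a 10 kb grid with local refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .cross_io import SporeTable
from .enumeration import enumerate_no_crossover
from .genome import CM_PER_KB, CrossConfig, DriveLocus
from .meiosis import classify_spore
from .presets import MARKERS
from .stats import haldane_r, transmission_curve

_CHI2_95_1DF = 3.8414588206941245  # likelihood-ratio CI threshold, 1 df


class NotIdentifiableError(RuntimeError):
    """The requested parameter cannot be estimated from this cross design."""


def mle_single_locus(n_killer: int, n_other: int) -> float:
    """Killer strength from counts at a fully linked marker.

    Inverts t = 1/(2 - d): d = 2 - 1/t, clamped to [0, 1] (a marker at or
    below 50 % transmission gives d = 0).
    """
    n = n_killer + n_other
    if n == 0:
        raise ValueError("at least one spore is required")
    t = n_killer / n
    if t <= 0.5:
        return 0.0
    return min(1.0, 2.0 - 1.0 / t)


@dataclass
class FitResult:
    """Result of a drive-model fit."""

    estimates: dict[str, float]
    ci: dict[str, tuple[float, float]]
    loglik: float
    n: int
    n_dropped: int
    converged: bool
    not_identifiable: tuple[str, ...]
    seed: int
    model_version: str = "1"


class _Kernel:
    """Vectorised survivorship-conditioned class-probability kernel."""

    def __init__(self, cfg: CrossConfig, panel: list[str]):
        self.cfg = cfg
        loci = [MARKERS[m] for m in panel]
        chr2 = next(l for l in loci if l.chrom == 2)
        chr3 = next(l for l in loci if l.chrom == 3)
        base = replace(
            cfg, drive=cfg.drive.with_strengths({d.name: 0.0 for d in cfg.drive.drivers})
        )
        dist = enumerate_no_crossover(base)
        self.active = cfg.active_drivers()
        self.p_pre = np.array([c.prob_pre for c in dist.classes])
        self.det_ok = np.array([c.cause is None for c in dist.classes], dtype=float)
        self.carries = np.array(
            [
                [
                    d.killer in c.spore.genotype_at(d.chrom, d.pos)
                    for d in self.active
                ]
                for c in dist.classes
            ],
            dtype=bool,
        )
        obs_keys = []
        for c in dist.classes:
            calls = tuple(
                "/".join(sorted(c.spore.genotype_at(l.chrom, l.pos))) or "-"
                for l in loci
            )
            obs_keys.append((calls, classify_spore(c.spore, chr2, chr3)))
        # only deterministically viable classes are observable: a table row
        # matching a structurally dead class (e.g. a rare residual
        # recombinant) must be dropped, not given zero likelihood
        uniq = sorted(
            {k for k, c in zip(obs_keys, dist.classes) if c.cause is None}
        )
        self.obs_index = {k: i for i, k in enumerate(uniq)}
        self.class_obs = np.array(
            [self.obs_index.get(k, -1) for k in obs_keys]
        )
        self.n_obs = len(uniq)

    def observable_probs(self, strengths: np.ndarray) -> np.ndarray:
        """P(observable class | viable) for given active-driver strengths."""
        w = self.p_pre * self.det_ok
        for j in range(len(self.active)):
            w = w * np.where(self.carries[:, j], 1.0, 1.0 - strengths[j])
        total = w.sum()
        if total <= 0:
            return np.zeros(self.n_obs)
        p = np.zeros(self.n_obs)
        mask = self.class_obs >= 0
        np.add.at(p, self.class_obs[mask], w[mask])
        return p / total


def _observed_counts(table: SporeTable, kernel: _Kernel, panel: list[str]):
    counts = np.zeros(kernel.n_obs)
    dropped = 0
    for _, row in table.viable.iterrows():
        key = (tuple(row[m] for m in panel), row["ploidy_class"])
        idx = kernel.obs_index.get(key)
        if idx is None:
            dropped += 1
        else:
            counts[idx] += 1
    return counts, dropped


def model_loglik(
    table: SporeTable, cfg: CrossConfig, strengths: dict[str, float] | None = None
) -> float:
    """Multinomial log-likelihood of a rec12-null table at given strengths.

    ``strengths`` overrides named drivers; unnamed drivers keep the
    strengths of ``cfg``.  Rows in observable classes of zero model
    probability are ignored (mirrors :func:`fit_drive_model`).
    """
    panel = table.marker_columns()
    kernel = _Kernel(cfg, panel)
    counts, _ = _observed_counts(table, kernel, panel)
    s = np.array(
        [
            (strengths or {}).get(d.name, d.strength)
            for d in kernel.active
        ]
    )
    p = kernel.observable_probs(s)
    mask = (counts > 0) & (p > 0)
    return float(np.sum(counts[mask] * np.log(p[mask])))


def fit_drive_model(
    table: SporeTable,
    cfg: CrossConfig,
    seed: int = 0,
    n_restarts: int = 5,
    compute_ci: bool = True,
) -> FitResult:
    """Fit killer strengths to a rec12-null spore table by multinomial ML.

    Free parameters are the active drivers whose locus is heterozygous
    between the parents; drivers fixed in the cross are flagged
    non-identifiable.  Bounded L-BFGS-B with seeded random restarts;
    identical seed + config + table give a bit-identical result.  Rows whose
    observable class has zero model probability under every parameter value
    (e.g. rare residual recombinants) are dropped and counted.
    """
    panel = table.marker_columns()
    if not panel:
        raise NotIdentifiableError("table has no marker columns")
    kernel = _Kernel(cfg, panel)
    free, fixed_flags = [], []
    for j, d in enumerate(kernel.active):
        alleles = cfg.parental_alleles_at(d.chrom, d.pos)
        (free if len(alleles) == 2 else fixed_flags).append((j, d))
    inert = [d.name or f"chr{d.chrom}:{d.killer}" for d in cfg.drive.drivers
             if d not in kernel.active]
    not_ident = tuple(
        [d.name or f"chr{d.chrom}:{d.killer}" for _, d in fixed_flags] + inert
    )
    if not free:
        raise NotIdentifiableError(
            "no driver locus is heterozygous in this cross; nothing to fit"
        )
    counts, dropped = _observed_counts(table, kernel, panel)
    n_used = int(counts.sum())
    if n_used == 0:
        raise NotIdentifiableError("no usable viable spores in the table")

    base = np.array([d.strength for d in kernel.active])
    free_idx = np.array([j for j, _ in free])

    def negloglik(x: np.ndarray) -> float:
        s = base.copy()
        s[free_idx] = x
        p = kernel.observable_probs(s)
        mask = counts > 0
        if np.any(p[mask] <= 0):
            return 1e12
        return -float(np.sum(counts[mask] * np.log(p[mask])))

    rng = np.random.default_rng(seed)
    starts = [np.full(len(free), 0.5)]
    starts += [rng.uniform(0.0, 1.0, size=len(free)) for _ in range(n_restarts - 1)]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=[(0.0, 1.0)] * len(free)
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    est = {d.name or f"chr{d.chrom}:{d.killer}": float(v)
           for (_, d), v in zip(free, best.x)}
    lmax = -best.fun

    cis: dict[str, tuple[float, float]] = {}
    if compute_ci:
        for k, ((j, d), xhat) in enumerate(zip(free, best.x)):
            cis[d.name or f"chr{d.chrom}:{d.killer}"] = _profile_ci(
                negloglik, best.x, k, lmax, len(free)
            )
    return FitResult(
        estimates=est,
        ci=cis,
        loglik=lmax,
        n=n_used,
        n_dropped=dropped,
        converged=bool(best.success),
        not_identifiable=not_ident,
        seed=seed,
    )


def _profile_ci(negloglik, xhat, k, lmax, n_free) -> tuple[float, float]:
    """Likelihood-ratio 95 % CI for one parameter by profile bisection."""
    target = -lmax + _CHI2_95_1DF / 2.0  # negloglik threshold

    def profile(v: float) -> float:
        if n_free == 1:
            x = np.array([v])
            return negloglik(x)
        others = [i for i in range(n_free) if i != k]

        def inner(y):
            x = np.empty(n_free)
            x[k] = v
            x[others] = y
            return negloglik(x)

        res = optimize.minimize(
            inner, xhat[others], method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * len(others),
        )
        return res.fun

    def g(v: float) -> float:
        return profile(v) - target

    lo, hi = 0.0, 1.0
    x = float(xhat[k])
    lower = lo if g(lo) <= 0 else optimize.brentq(g, lo, x, xtol=1e-4) if x > lo else lo
    upper = hi if g(hi) <= 0 else optimize.brentq(g, x, hi, xtol=1e-4) if x < hi else hi
    return (float(lower), float(upper))


@dataclass
class LocalizationResult:
    position: float | None
    d_hat: float
    loglik: float
    flag: str = ""  # "", "single_marker", "no_drive"
    interval: tuple[int, int] | None = None


def localize_driver(
    markers: list[tuple[float, int, int]],
    chrom_length: int,
    rate: float = CM_PER_KB,
    grid_bp: int = 10_000,
) -> LocalizationResult:
    """Estimate a killer's position and strength from per-marker counts.

    ``markers`` holds (position bp, n_killer, n_other) triples on one
    chromosome.  Maximizes the binomial likelihood of the counts under
    t(x) = (1 - r(x)·d)/(2 - d) with r(x) from Haldane at ``rate`` cM/kb,
    scanning candidate positions on a ``grid_bp`` grid, then refining
    locally.  With a single marker the position is unidentifiable and the
    whole chromosome is returned as the interval.
    """
    if not markers:
        raise ValueError("at least one marker is required")
    if len(markers) == 1:
        x, nk, no = markers[0]
        return LocalizationResult(
            position=None,
            d_hat=mle_single_locus(nk, no),
            loglik=float("nan"),
            flag="single_marker",
            interval=(1, chrom_length),
        )

    def negloglik(pos: float, d: float) -> float:
        ll = 0.0
        for x, nk, no in markers:
            r = min(0.5, haldane_r(rate * abs(pos - x) / 1000.0))
            t = transmission_curve(d, r)
            t = min(max(t, 1e-12), 1 - 1e-12)
            ll += nk * math.log(t) + no * math.log(1.0 - t)
        return -ll

    def best_d(pos: float):
        res = optimize.minimize_scalar(
            lambda d: negloglik(pos, d), bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-6},
        )
        return float(res.x), float(res.fun)

    grid = np.arange(1, chrom_length + 1, grid_bp, dtype=float)
    evals = [best_d(p) for p in grid]
    i = int(np.argmin([f for _, f in evals]))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    res = optimize.minimize_scalar(
        lambda p: best_d(p)[1], bounds=(lo, hi), method="bounded",
        options={"xatol": 100.0},
    )
    pos_hat = float(res.x)
    d_hat, nll = best_d(pos_hat)
    if d_hat < 1e-6:
        return LocalizationResult(None, 0.0, -nll, flag="no_drive")
    return LocalizationResult(pos_hat, d_hat, -nll)


def marker_counts_from_table(
    table: SporeTable, chrom: int, killer: str = "K"
) -> list[tuple[float, int, int]]:
    """(position, n_killer, n_other) triples for a chromosome's markers."""
    out = []
    for name in table.marker_columns():
        locus = MARKERS.get(name)
        if locus is None or locus.chrom != chrom:
            continue
        calls = table.viable[name]
        nk = int((calls == killer).sum())
        no = int(calls.isin([a for a in "KP" if a != killer]).sum())
        if nk + no:
            out.append((float(locus.pos), nk, no))
    return out
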