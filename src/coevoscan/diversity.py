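"""Windowed Tajima's D with an empirical null, and Weir-Cockerham FST.

Tajima's D contrasts mean pairwise diversity pi with Watterson's estimator
S/a1; strongly negative windows indicate an excess of rare alleles (sweeps,
purifying selection), strongly positive windows an excess of intermediate
frequencies (balancing selection).  Significance is empirical: windows are
compared against the 2.5th/97.5th percentiles of D computed on user-supplied
null regions (e.g. genic windows of a reference chromosome), giving a
two-sided empirical p < 0.05 call without distributional assumptions.

FST follows the Weir & Cockerham (1984) variance-component estimator on a
per-site basis: theta = a / (a + b + c) with a, b, c the among-population,
among-individual and within-individual components.  Per-gene summaries are
means of raw per-site ratios, negatives retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from coevoscan.io import MISSING, GenotypeMatrix, Region
from coevoscan.quantiles import percentile

__all__ = [
    "TajimaWindow",
    "EmpiricalNull",
    "FstSite",
    "tajima_constants",
    "tajimas_d",
    "scan_windows",
    "build_null",
    "classify_windows",
    "wc_fst_site",
    "wc_fst_matrix",
    "gene_mean",
]


@dataclass
class TajimaWindow:
    chrom: str
    start: int  # 0-based half-open window
    end: int
    n_snps: int
    pi: float
    n_chrom: int
    d: float  # nan when undefined

    @property
    def defined(self) -> bool:
        return math.isfinite(self.d)


@dataclass
class EmpiricalNull:
    """Pooled null statistic values with their 2.5/97.5 percentile bounds."""

    values: np.ndarray
    lower: float
    upper: float


@dataclass
class FstSite:
    pos: int
    a: float
    b: float
    c: float
    fst: float  # nan when a+b+c == 0

    @property
    def defined(self) -> bool:
        return math.isfinite(self.fst)


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima's normalizing constants for n sampled chromosomes."""
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_from_counts(
    alt_counts: np.ndarray, chrom_counts: np.ndarray
) -> tuple[int, float, int, float]:
    """Core Tajima computation from per-site allele counts.

    Returns (S, pi, n_chrom, D).  Per-site pi_j = 2 k_j (n_j - k_j) /
    (n_j (n_j - 1)) accommodates per-site sample sizes under missingness;
    the variance constants use the median per-site n.  D is nan when S = 0,
    n < 3, or the variance term vanishes.
    """
    ac = np.asarray(alt_counts, dtype=np.int64)
    an = np.asarray(chrom_counts, dtype=np.int64)
    usable = an >= 2
    ac, an = ac[usable], an[usable]
    seg = (ac > 0) & (ac < an)
    s = int(seg.sum())
    if s == 0:
        return 0, 0.0, int(np.median(an)) if an.size else 0, math.nan
    k, n_j = ac[seg].astype(float), an[seg].astype(float)
    pi = float(np.sum(2.0 * k * (n_j - k) / (n_j * (n_j - 1.0))))
    n = int(np.median(an[seg]))
    if n < 3:
        return s, pi, n, math.nan
    c = tajima_constants(n)
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    if var <= 0:
        return s, pi, n, math.nan
    d = (pi - s / c["a1"]) / math.sqrt(var)
    return s, pi, n, d


def tajimas_d(window: GenotypeMatrix, chrom: str | None = None,
              start: int = 0, end: int | None = None) -> TajimaWindow:
    """Tajima's D over the sites of a GenotypeMatrix slice."""
    ac, an = window.alt_counts()
    s, pi, n, d = tajimas_d_from_counts(ac, an)
    if chrom is None:
        chrom = window.sites[0].chrom if window.sites else "NA"
    if end is None:
        end = max((s_.pos for s_ in window.sites), default=start + 1)
    return TajimaWindow(chrom, start, end, s, pi, n, d)


def scan_windows(
    genotypes: GenotypeMatrix,
    region: Region,
    width: int = 1000,
    max_missing: float = 0.10,
) -> tuple[list[TajimaWindow], int]:
    """Tile ``region`` with non-overlapping windows and compute D per window.

    Windows whose genotype entries exceed ``max_missing`` missingness are
    excluded; the second return value counts them.  The last window is
    truncated at the region end.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    pos0 = genotypes.positions - 1  # 0-based for interval arithmetic
    on_chrom = np.array([s.chrom == region.chrom for s in genotypes.sites])
    out: list[TajimaWindow] = []
    n_excluded = 0
    for wstart in range(region.start, region.end, width):
        wend = min(wstart + width, region.end)
        idx = np.nonzero(on_chrom & (pos0 >= wstart) & (pos0 < wend))[0]
        sub = genotypes.take_sites(idx)
        if sub.n_sites and sub.n_samples:
            miss_frac = float((sub.dosages == MISSING).mean())
            if miss_frac > max_missing:
                n_excluded += 1
                continue
        w = tajimas_d(sub, chrom=region.chrom, start=wstart, end=wend)
        w.start, w.end = wstart, wend
        out.append(w)
    return out, n_excluded


def build_null(null_windows: Iterable[TajimaWindow], min_defined: int = 40) -> EmpiricalNull:
    """Empirical 2.5/97.5 percentile null from defined window D values."""
    vals = np.array([w.d for w in null_windows if w.defined], dtype=float)
    if vals.size < min_defined:
        raise ValueError(
            f"only {vals.size} defined null values; need >= {min_defined} for stable percentiles"
        )
    return EmpiricalNull(vals, percentile(vals, 2.5), percentile(vals, 97.5))


def classify_windows(
    test: Sequence[TajimaWindow], null: EmpiricalNull
) -> list[str]:
    """Flag each window 'low', 'high' or 'ns' against the empirical null.

    Strict inequalities: a window exactly at a threshold is not significant.
    Undefined windows are 'ns'.
    """
    flags = []
    for w in test:
        if not w.defined:
            flags.append("ns")
        elif w.d < null.lower:
            flags.append("low")
        elif w.d > null.upper:
            flags.append("high")
        else:
            flags.append("ns")
    return flags


def gene_proportions(flags: Sequence[str]) -> tuple[float, float, int]:
    """(prop_low, prop_high, n_windows) over one gene's windows."""
    n = len(flags)
    if n == 0:
        return math.nan, math.nan, 0
    return flags.count("low") / n, flags.count("high") / n, n


def wc_fst_site(pop_counts: Sequence[tuple[int, int, int]], pos: int = 0) -> FstSite:
    """Weir-Cockerham per-site FST from per-population summaries.

    ``pop_counts`` holds, per population, (n_i diploid individuals,
    alt allele count, observed heterozygote count).  Requires r >= 2
    populations with n_i >= 2 each.  Monomorphic sites (a+b+c = 0) yield
    fst = nan.
    """
    r = len(pop_counts)
    if r < 2:
        raise ValueError("need >= 2 populations")
    n_i = np.array([c[0] for c in pop_counts], dtype=float)
    if np.any(n_i < 2):
        raise ValueError("each population needs >= 2 individuals")
    alt = np.array([c[1] for c in pop_counts], dtype=float)
    het = np.array([c[2] for c in pop_counts], dtype=float)
    p_i = alt / (2.0 * n_i)
    h_i = het / n_i

    nbar = n_i.sum() / r
    nc = (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1)
    pbar = float(np.sum(n_i * p_i) / (r * nbar))
    s2 = float(np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar))
    hbar = float(np.sum(n_i * h_i) / (r * nbar))

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - (2 * nbar - 1) * hbar / (4 * nbar)
    )
    c_comp = hbar / 2.0
    denom = a + b + c_comp
    fst = a / denom if denom != 0 else math.nan
    return FstSite(pos, a, b, c_comp, fst)


def wc_fst_matrix(genotypes: GenotypeMatrix) -> list[FstSite]:
    """Per-site WC FST across the populations labelled in a GenotypeMatrix."""
    groups = genotypes.pop_groups()
    if len(groups) < 2:
        raise ValueError("need >= 2 populations in the genotype matrix")
    out: list[FstSite] = []
    d = genotypes.dosages
    for j, site in enumerate(genotypes.sites):
        counts = []
        for idx in groups.values():
            col = d[idx, j]
            col = col[col != MISSING]
            if col.size < 2:
                counts = []
                break
            counts.append((col.size, int(col.sum()), int((col == 1).sum())))
        if not counts:
            out.append(FstSite(site.pos, 0.0, 0.0, 0.0, math.nan))
            continue
        out.append(wc_fst_site(counts, pos=site.pos))
    return out


def gene_mean(values: Sequence[float], positions: Sequence[int], gene: Region) -> tuple[float, int]:
    """Mean of defined per-site/per-window values falling in a gene.

    ``positions`` are 1-based site positions (or window midpoints).  Raw
    values are averaged, negatives included.  Returns (mean, count);
    mean is nan when no defined value falls in the gene.
    """
    vals = [
        v for v, p in zip(values, positions)
        if gene.contains_pos(int(p)) and math.isfinite(v)
    ]
    if not vals:
        return math.nan, 0
    return float(np.mean(vals)), len(vals)
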