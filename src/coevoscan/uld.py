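"""Unusual linkage disequilibrium: the gene-cluster co-evolution detector.

Squared genotype correlation (r2) between SNP pairs inside a cluster is
compared with a genome-wide empirical null built from windows that match
the cluster's physical length and gene count.  Null pair r2 values are
binned by genetic distance (0.01 cM bins) and each bin contributes its
99th-percentile threshold; a cluster pair whose r2 strictly exceeds its
bin's threshold is flagged as unusual LD (uLD).  Distance matching matters
because r2 decays with recombination distance: an absolute r2 cutoff would
conflate short-range background LD with the long-range signal of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from coevoscan.io import MISSING, GenotypeMatrix, GeneticMap, Region, RegionTable
from coevoscan.quantiles import percentile

__all__ = [
    "PairLD",
    "DistanceBinnedNull",
    "MatchedWindow",
    "geno_r2",
    "cluster_pairs",
    "find_matched_windows",
    "build_binned_null",
    "flag_uld",
    "extract_pairs_by_gene",
]

BIN_WIDTH_CM = 0.01


@dataclass
class PairLD:
    pos_i: int
    pos_j: int
    gene_i: str  # containing gene name or "intergenic"
    gene_j: str
    r2: float
    d_cm: float
    bin_index: int
    flagged: bool = False


@dataclass
class MatchedWindow:
    """A null window matching the target cluster: same length, same gene count."""

    chrom: str
    start: int
    end: int
    genes: list[str]

    def as_region(self, name: str) -> Region:
        return Region(name, self.chrom, self.start, self.end, "window")


@dataclass
class DistanceBinnedNull:
    bin_width: float
    counts: dict[int, int]
    thresholds: dict[int, float]  # only bins with >= min_pairs
    min_pairs: int
    n_windows: int = 0


def geno_r2(g1, g2) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over samples called in both vectors; requires >= 3 such
    samples and both vectors non-constant (else nan — the pair is skipped).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING)
    x, y = g1[ok], g2[ok]
    if x.size < 3:
        return math.nan
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return math.nan
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return min(r * r, 1.0)


def _gene_label(pos: int, genes: RegionTable, chrom: str) -> str:
    for g in genes:
        if g.chrom == chrom and g.contains_pos(pos):
            return g.name
    return "intergenic"


def cluster_pairs(
    genotypes: GenotypeMatrix,
    genes: RegionTable,
    gmap: GeneticMap | None,
    maf_min: float = 0.05,
    bin_width: float = BIN_WIDTH_CM,
    region: Region | None = None,
) -> list[PairLD]:
    """All unordered SNP pairs in a cluster (or matched window), annotated.

    SNPs must have MAF strictly above ``maf_min`` ("above 0.05").  Each
    surviving pair carries its genetic distance, distance bin and the gene
    containing each SNP.  Pairs with undefined r2 are dropped.
    """
    maf = genotypes.maf()
    keep = np.nonzero(maf > maf_min)[0]
    if region is not None:
        keep = np.array([i for i in keep if region.contains_pos(genotypes.sites[i].pos)],
                        dtype=int)
    if keep.size < 2:
        raise ValueError("fewer than 2 SNPs survive the MAF filter")
    sub = genotypes.take_sites(keep)
    pos = sub.positions
    chrom = sub.sites[0].chrom
    cm = (gmap.cm_at(chrom, pos) if gmap is not None else pos * 1e-6)
    labels = [_gene_label(int(p), genes, chrom) for p in pos]
    out: list[PairLD] = []
    d = sub.dosages
    for i in range(sub.n_sites):
        for j in range(i + 1, sub.n_sites):
            r2 = geno_r2(d[:, i], d[:, j])
            if not math.isfinite(r2):
                continue
            d_cm = abs(float(cm[j]) - float(cm[i]))
            out.append(PairLD(int(pos[i]), int(pos[j]), labels[i], labels[j],
                              r2, d_cm, int(d_cm // bin_width)))
    return out


def find_matched_windows(
    genes: RegionTable, length: int, k: int, exclude: RegionTable | None = None
) -> list[MatchedWindow]:
    """Genome-wide windows of ``length`` bp containing exactly ``k`` genes.

    One candidate window is anchored at the start of every gene:
    [gene.start, gene.start + length).  A candidate is kept iff exactly
    ``k`` genes of the table are fully contained in it and it does not
    overlap any ``exclude`` region (the target cluster itself).  Overlapping
    surviving candidates are all retained.
    """
    out: list[MatchedWindow] = []
    for chrom in genes.chroms():
        chrom_genes = sorted(genes.on_chrom(chrom), key=lambda g: (g.start, g.end))
        excl = list(exclude.on_chrom(chrom)) if exclude is not None else []
        for anchor in chrom_genes:
            win = Region("_w", chrom, anchor.start, anchor.start + length, "window")
            contained = [g.name for g in chrom_genes if win.contains_region(g)]
            if len(contained) != k:
                continue
            if any(win.overlaps(e) for e in excl):
                continue
            out.append(MatchedWindow(chrom, win.start, win.end, contained))
    return out


def build_binned_null(
    null_pairs: list[PairLD],
    bin_width: float = BIN_WIDTH_CM,
    pct: float = 99.0,
    min_pairs: int = 100,
    n_windows: int = 0,
) -> DistanceBinnedNull:
    """Per-distance-bin r2 thresholds from matched-window pairs.

    Each 0.01 cM bin with at least ``min_pairs`` pairs contributes its
    ``pct``-th percentile r2; thinner bins carry no threshold and the
    cluster pairs falling in them can never be flagged.
    """
    bins: dict[int, list[float]] = {}
    for p in null_pairs:
        b = int(p.d_cm // bin_width)
        bins.setdefault(b, []).append(p.r2)
    counts = {b: len(v) for b, v in bins.items()}
    thresholds = {
        b: percentile(v, pct) for b, v in bins.items() if len(v) >= min_pairs
    }
    if not thresholds:
        raise ValueError("no distance bin reaches min_pairs; null unusable")
    return DistanceBinnedNull(bin_width, counts, thresholds, min_pairs, n_windows)


def flag_uld(pairs: list[PairLD], null: DistanceBinnedNull) -> dict:
    """Flag cluster pairs whose r2 strictly exceeds their bin's threshold.

    Pairs in bins without a threshold stay unflagged and are counted as
    uncovered.  Returns a summary with the flagged fraction overall and
    per ordered gene-pair counts; ``pairs`` is modified in place.
    """
    n_flagged = 0
    n_uncovered = 0
    per_gene_pair: dict[tuple[str, str], int] = {}
    for p in pairs:
        b = int(p.d_cm // null.bin_width)
        thr = null.thresholds.get(b)
        if thr is None:
            p.flagged = False
            n_uncovered += 1
            continue
        p.flagged = p.r2 > thr
        if p.flagged:
            n_flagged += 1
            key = tuple(sorted((p.gene_i, p.gene_j)))
            per_gene_pair[key] = per_gene_pair.get(key, 0) + 1
    n = len(pairs)
    return {
        "n_pairs": n,
        "n_flagged": n_flagged,
        "n_uncovered": n_uncovered,
        "flagged_fraction": n_flagged / n if n else math.nan,
        "per_gene_pair": per_gene_pair,
    }


def extract_pairs_by_gene(pairs: list[PairLD], gene: str,
                          known_genes: RegionTable | None = None,
                          mode: str = "either", flagged_only: bool = True) -> list[PairLD]:
    """Replication subset: flagged pairs touching a named gene.

    ``mode='either'`` keeps pairs with at least one endpoint in the gene;
    ``mode='exactly_one'`` keeps pairs where exactly one endpoint is.
    """
    if known_genes is not None and gene not in known_genes:
        raise KeyError(f"unknown gene {gene!r}")
    out = []
    for p in pairs:
        if flagged_only and not p.flagged:
            continue
        hits = (p.gene_i == gene) + (p.gene_j == gene)
        if (mode == "either" and hits >= 1) or (mode == "exactly_one" and hits == 1):
            out.append(p)
    return out
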