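"""Reading, filtering and harmonizing the formats the pipeline consumes.

Conventions
-----------
* VCF positions are 1-based; every interval table (BED-style masks, gene
  regions, matched windows) is 0-based half-open.  Conversion happens only
  here, at the I/O boundary.
* Genotype dosages are counts of the non-reference allele in {0, 1, 2} with
  ``-1`` marking a missing genotype.  Haplotype-based stages require
  complete, phased data and refuse missing entries.
* Genetic-map lookups clamp to the nearest map endpoint outside the mapped
  range (constant extrapolation) so genetic distances are never negative or
  extrapolated beyond the data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from cyvcf2 import VCF

MISSING = -1

__all__ = [
    "MISSING",
    "SiteRecord",
    "Region",
    "RegionTable",
    "GenotypeMatrix",
    "HaplotypePanel",
    "GeneticMap",
    "read_vcf_region",
    "write_vcf",
    "polarize_ancestral",
    "apply_mask",
    "interpolate_cm",
    "read_genetic_map",
    "read_population_panel",
    "read_bed",
    "read_gtf_genes",
]


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP: position, alleles, ancestral state and mask flag."""

    chrom: str
    pos: int  # 1-based physical position
    ref_allele: str
    alt_allele: str
    ancestral_state: str = "unknown"  # one of {"ref", "alt", "unknown"}
    masked: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if self.ancestral_state not in ("ref", "alt", "unknown"):
            raise ValueError(f"bad ancestral_state {self.ancestral_state!r}")


def _check_sorted_unique(sites: Sequence[SiteRecord]) -> None:
    keys = [(s.chrom, s.pos) for s in sites]
    if any(k2 <= k1 for k1, k2 in zip(keys, keys[1:])):
        raise ValueError("sites must be sorted by (chrom, pos) with no duplicates")


@dataclass(frozen=True)
class Region:
    """Named half-open interval [start, end) in 0-based coordinates."""

    name: str
    chrom: str
    start: int
    end: int
    feature: str = "gene"

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"empty/inverted interval for {self.name}")

    def contains_pos(self, pos: int) -> bool:
        """Whether a 1-based position falls inside the interval."""
        return self.start <= pos - 1 < self.end

    def contains_region(self, other: "Region") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Region") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


class RegionTable:
    """Ordered collection of named regions with unique names."""

    def __init__(self, regions: Iterable[Region]):
        self.regions = list(regions)
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique within a table")

    def __len__(self):
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(r.name == name for r in self.regions)

    def on_chrom(self, chrom: str) -> "RegionTable":
        return RegionTable(r for r in self.regions if r.chrom == chrom)

    def sorted(self) -> "RegionTable":
        return RegionTable(sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end)))

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.chrom, None)
        return list(seen)


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage matrix with per-site metadata.

    ``dosages[i, j]`` is the non-reference allele count of sample ``i`` at
    site ``j`` (0/1/2, ``MISSING`` = -1).
    """

    sites: list[SiteRecord]
    samples: list[str]
    dosages: np.ndarray
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} != "
                f"(samples={len(self.samples)}, sites={len(self.sites)})"
            )
        _check_sorted_unique(self.sites)
        if self.populations:
            missing = [s for s in self.samples if s not in self.populations]
            if missing:
                raise ValueError(f"samples without population label: {missing[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def alt_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called chromosome count) over non-missing samples."""
        d = self.dosages
        called = d != MISSING
        ac = np.where(called, d, 0).sum(axis=0).astype(np.int64)
        an = 2 * called.sum(axis=0).astype(np.int64)
        return ac, an

    def maf(self) -> np.ndarray:
        ac, an = self.alt_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
        return np.minimum(p, 1.0 - p)

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.sites[i] for i in idx], list(self.samples),
            self.dosages[:, idx], dict(self.populations),
        )

    def take_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in order]
        if missing:
            raise KeyError(f"samples not present: {missing}")
        idx = [order[n] for n in names]
        pops = {n: self.populations[n] for n in names} if self.populations else {}
        return GenotypeMatrix(list(self.sites), list(names), self.dosages[idx, :], pops)

    def pop_groups(self) -> dict[str, list[int]]:
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            groups.setdefault(self.populations.get(s, "pop0"), []).append(i)
        return groups


@dataclass
class HaplotypePanel:
    """Phased haplotypes, 2N x sites, coded 1 = derived allele after polarization."""

    sites: list[SiteRecord]
    haplotypes: np.ndarray

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.sites):
            raise ValueError("haplotype matrix must be 2N x n_sites")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotypes must be 0/1 with no missing entries")
        _check_sorted_unique(self.sites)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def derived_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def take_sites(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel([self.sites[i] for i in idx], self.haplotypes[:, idx])


class GeneticMap:
    """Monotone bp -> cM mapping per chromosome with linear interpolation.

    Positions must be strictly increasing and cM non-decreasing.  Lookups
    outside the mapped range return the nearest endpoint's cM.
    """

    def __init__(self, points: dict[str, Sequence[tuple[int, float]]]):
        self._pos: dict[str, np.ndarray] = {}
        self._cm: dict[str, np.ndarray] = {}
        for chrom, pts in points.items():
            pts = sorted(pts)
            pos = np.array([p for p, _ in pts], dtype=np.float64)
            cm = np.array([c for _, c in pts], dtype=np.float64)
            if pos.size == 0:
                raise ValueError(f"empty map for chromosome {chrom}")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"map positions not strictly increasing on {chrom}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"map cM decreasing on {chrom}")
            self._pos[chrom] = pos
            self._cm[chrom] = cm

    def chroms(self) -> list[str]:
        return list(self._pos)

    def cm_at(self, chrom: str, pos) -> np.ndarray | float:
        if chrom not in self._pos:
            raise KeyError(f"no genetic map for chromosome {chrom}")
        # np.interp clamps to the endpoint values outside the range
        out = np.interp(np.asarray(pos, dtype=float), self._pos[chrom], self._cm[chrom])
        return float(out) if np.isscalar(pos) or np.ndim(pos) == 0 else out


def interpolate_cm(gmap: GeneticMap, chrom: str, pos) -> float | np.ndarray:
    """Genetic position (cM) of ``pos`` bp, clamped beyond the map ends."""
    return gmap.cm_at(chrom, pos)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _is_biallelic_snp(variant) -> bool:
    return (
        len(variant.ALT) == 1
        and len(variant.REF) == 1
        and len(variant.ALT[0]) == 1
        and variant.REF.upper() in "ACGT"
        and variant.ALT[0].upper() in "ACGT"
    )


def read_vcf_region(
    path: str | os.PathLike,
    region: Region | str | None = None,
    sample_subset: Sequence[str] | None = None,
    with_haplotypes: bool = False,
    populations: dict[str, str] | None = None,
):
    """Read biallelic SNPs from a VCF, optionally restricted to a region.

    ``region`` may be a :class:`Region` (0-based half-open), a chromosome
    label, or None for the whole file.  Indels and multiallelic records are
    dropped; if several records share one position the position is dropped
    entirely (biallelic-only policy).

    Returns a :class:`GenotypeMatrix`; with ``with_haplotypes=True`` returns
    ``(matrix, panel)`` where ``panel`` is a :class:`HaplotypePanel` coded by
    alt allele (not yet ancestrally polarized) if every genotype is phased
    and called, else None.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    if sample_subset is not None:
        header_samples = set(vcf.samples)
        absent = [s for s in sample_subset if s not in header_samples]
        if absent:
            raise KeyError(f"samples not in VCF header: {absent}")
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)

    chrom = start = end = None
    if isinstance(region, Region):
        chrom, start, end = region.chrom, region.start, region.end
    elif isinstance(region, str):
        chrom = region

    seen_chroms: set[str] = set()
    recs: list[tuple[SiteRecord, np.ndarray, np.ndarray | None]] = []
    for v in vcf:
        seen_chroms.add(v.CHROM)
        if chrom is not None and v.CHROM != chrom:
            continue
        if start is not None and not (start <= v.POS - 1 < end):
            continue
        if not _is_biallelic_snp(v):
            continue
        gts = np.array(v.genotypes, dtype=object)
        a0 = np.array([g[0] for g in gts], dtype=np.int16)
        a1 = np.array([g[1] for g in gts], dtype=np.int16)
        phased = np.array([g[2] for g in gts], dtype=bool)
        dos = np.where((a0 < 0) | (a1 < 0), MISSING, a0 + a1).astype(np.int8)
        haps = None
        if phased.all() and (a0 >= 0).all() and (a1 >= 0).all():
            haps = np.empty(2 * len(samples), dtype=np.uint8)
            haps[0::2] = a0
            haps[1::2] = a1
        site = SiteRecord(v.CHROM, v.POS, v.REF.upper(), v.ALT[0].upper())
        recs.append((site, dos, haps))

    if chrom is not None and chrom not in seen_chroms:
        hdr_chroms = set(vcf.seqnames) if vcf.seqnames else seen_chroms
        if chrom not in hdr_chroms:
            raise KeyError(f"chromosome {chrom!r} absent from VCF")

    # drop positions carried by more than one record (multiallelic split across lines)
    from collections import Counter

    pos_count = Counter((s.chrom, s.pos) for s, _, _ in recs)
    recs = [r for r in recs if pos_count[(r[0].chrom, r[0].pos)] == 1]
    recs.sort(key=lambda r: (r[0].chrom, r[0].pos))

    sites = [r[0] for r in recs]
    if recs:
        dosages = np.stack([r[1] for r in recs], axis=1)
    else:
        dosages = np.zeros((len(samples), 0), dtype=np.int8)
    pops = {s: populations[s] for s in samples} if populations else {}
    gm = GenotypeMatrix(sites, samples, dosages, pops)
    if not with_haplotypes:
        return gm
    panel = None
    if recs and all(r[2] is not None for r in recs):
        panel = HaplotypePanel(sites, np.stack([r[2] for r in recs], axis=1))
    return gm, panel


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike, phased_haplotypes: np.ndarray | None = None) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 text file.

    Unphased dosages are written as 0/0, 0/1, 1/1 or ./.; if
    ``phased_haplotypes`` (2N x sites, alt-coded) is given, phased GTs are
    emitted instead.
    """
    chroms: dict[str, None] = {}
    for s in gm.sites:
        chroms.setdefault(s.chrom, None)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        for j, site in enumerate(gm.sites):
            if phased_haplotypes is not None:
                gts = [f"{phased_haplotypes[2 * i, j]}|{phased_haplotypes[2 * i + 1, j]}" for i in range(gm.n_samples)]
            else:
                code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [code[int(gm.dosages[i, j])] for i in range(gm.n_samples)]
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref_allele}\t{site.alt_allele}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Ancestral polarization and masking
# ---------------------------------------------------------------------------

def polarize_ancestral(panel: HaplotypePanel, ancestral_calls: Sequence[str]):
    """Re-code an alt-coded panel so 1 = derived allele everywhere.

    ``ancestral_calls`` gives the ancestral base per site (case-insensitive;
    low-confidence lowercase calls are accepted as valid).  Sites whose
    ancestral base matches neither allele, or is missing ('.', '-', 'N'),
    are dropped.  Returns ``(polarized_panel, n_dropped)``.
    """
    if len(ancestral_calls) != panel.n_sites:
        raise ValueError(
            f"{len(ancestral_calls)} ancestral calls for {panel.n_sites} sites"
        )
    keep: list[int] = []
    flip: list[bool] = []
    new_sites: list[SiteRecord] = []
    for j, (site, anc) in enumerate(zip(panel.sites, ancestral_calls)):
        a = anc.strip().upper()
        if a == site.ref_allele:
            keep.append(j)
            flip.append(False)
            new_sites.append(replace(site, ancestral_state="ref"))
        elif a == site.alt_allele:
            keep.append(j)
            flip.append(True)
            new_sites.append(replace(site, ancestral_state="alt"))
        # unknown or third-allele ancestral state: drop the site
    haps = panel.haplotypes[:, keep].copy()
    flip_arr = np.array(flip, dtype=bool)
    haps[:, flip_arr] = 1 - haps[:, flip_arr]
    n_dropped = panel.n_sites - len(keep)
    return HaplotypePanel(new_sites, haps), n_dropped


def apply_mask(sites: Sequence[SiteRecord], mask: RegionTable) -> list[int]:
    """Indices of sites surviving a repeat/low-mappability mask.

    A site is removed when its 0-based position (pos - 1) falls inside any
    mask interval on its chromosome.  An empty mask keeps everything.
    """
    kept: list[int] = []
    by_chrom: dict[str, list[Region]] = {}
    for r in mask:
        by_chrom.setdefault(r.chrom, []).append(r)
    for i, s in enumerate(sites):
        hit = any(m.start <= s.pos - 1 < m.end for m in by_chrom.get(s.chrom, ()))
        if not hit:
            kept.append(i)
    return kept


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------

def read_genetic_map(path: str | os.PathLike) -> GeneticMap:
    """Read a genetic map: PLINK 4-column (chrom pos rate cM), 3-column
    (pos rate cM, single chromosome) or 2-column (pos cM) text, with an
    optional header line."""
    points: dict[str, list[tuple[int, float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            if ln == 0:
                try:
                    float(parts[-1])
                except ValueError:
                    continue  # header
            if len(parts) >= 4:
                chrom, pos, cm = parts[0], int(parts[1]), float(parts[3])
            elif len(parts) == 3:
                chrom, pos, cm = "0", int(parts[0]), float(parts[2])
            elif len(parts) == 2:
                chrom, pos, cm = "0", int(parts[0]), float(parts[1])
            else:
                raise ValueError(f"unparseable map line: {line!r}")
            points.setdefault(chrom, []).append((pos, cm))
    if not points:
        raise ValueError(f"empty genetic map: {path}")
    return GeneticMap(points)


def read_population_panel(path: str | os.PathLike) -> dict[str, str]:
    """Read a sample->population TSV (columns: sample, pop[, super_pop])."""
    pops: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            if ln == 0 and parts[0].lower() in ("sample", "sample_id", "iid"):
                continue
            pops[parts[0]] = parts[1]
    return pops


def read_bed(path: str | os.PathLike, feature: str = "mask") -> RegionTable:
    """Read a BED3+ file into a RegionTable (0-based half-open intervals)."""
    regions: list[Region] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            parts = line.split()
            name = parts[3] if len(parts) > 3 else f"{feature}_{i}"
            regions.append(Region(name, parts[0], int(parts[1]), int(parts[2]), feature))
    return RegionTable(regions)


def read_gtf_genes(path: str | os.PathLike, feature: str = "gene") -> RegionTable:
    """Extract gene records from an Ensembl-dialect GTF into a RegionTable.

    GTF is 1-based inclusive; intervals are converted to 0-based half-open.
    The region name is gene_name when present, else gene_id.
    """
    regions: list[Region] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != feature:
                continue
            attrs: dict[str, str] = {}
            for item in parts[8].strip().split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attrs[key] = val.strip().strip('"')
            name = attrs.get("gene_name") or attrs.get("gene_id") or f"gene_{len(regions)}"
            if name in seen:  # duplicated gene symbols: disambiguate by id
                name = f"{name}|{attrs.get('gene_id', len(regions))}"
            seen.add(name)
            regions.append(Region(name, parts[0], int(parts[3]) - 1, int(parts[4]), "gene"))
    return RegionTable(regions)
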