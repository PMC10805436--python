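"""Haplotype-based selection scans: EHH/iHS and the folded beta score.

iHS (integrated haplotype score) detects recent positive selection from the
decay of extended haplotype homozygosity (EHH) around a core SNP: the
unstandardized score is ln(iHH_A / iHH_D), the log ratio of the EHH curve
integrals (in cM) over carriers of the ancestral versus the derived core
allele.  Negative standardized scores mean unusually long derived
haplotypes, i.e. selection acting on the derived allele; |iHS| >= 2 is the
conventional candidate threshold after within-frequency-bin
standardization.

The beta score targets long-term balancing selection: around a core SNP it
contrasts a frequency-similarity-weighted mutation-rate estimate
theta_beta with Watterson's theta_W in the same window.  An excess of
window SNPs whose folded frequencies cluster near the core's folded
frequency (beta > 0) is the balanced-haplotype signature.  Chromosome-wide
significance is empirical: scores in the top fraction (default 1%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from coevoscan.io import GeneticMap, HaplotypePanel
from coevoscan.quantiles import quantile

__all__ = [
    "EhhCurve",
    "IhsScore",
    "BetaScore",
    "ehh",
    "ihs",
    "ihs_scan",
    "standardize_ihs",
    "beta_score",
    "beta_scan",
    "empirical_top_fraction",
]


@dataclass
class EhhCurve:
    core_index: int
    side: str  # "left" | "right"
    allele: int  # 0 ancestral, 1 derived
    positions: np.ndarray  # bp of successive sites outward from the core
    cm: np.ndarray  # |cM - cM_core| distances, non-decreasing
    values: np.ndarray  # EHH values, starting at 1 at the core


@dataclass
class IhsScore:
    core_index: int
    pos: int
    derived_freq: float
    ihh_a: float = math.nan
    ihh_d: float = math.nan
    ihs_raw: float = math.nan
    ihs_std: float = math.nan
    status: str = "ok"  # ok | maf | edge | degenerate | carriers


@dataclass
class BetaScore:
    core_index: int
    pos: int
    folded_freq: float
    theta_beta: float
    theta_w: float
    beta: float
    half_width: int
    significant: bool = False


def ehh(panel: HaplotypePanel, core: int, allele: int, side: str,
        gmap: GeneticMap | None = None) -> EhhCurve:
    """Extended haplotype homozygosity outward from a core site.

    EHH at site s is the probability that two random carrier haplotypes of
    ``allele`` at the core are identical over every site from the core
    through s: sum_g C(m_g, 2) / C(m, 2) over the distinct extended
    haplotypes g.  Requires >= 2 carriers.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    carriers = np.nonzero(panel.haplotypes[:, core] == allele)[0]
    m = carriers.size
    if m < 2:
        raise ValueError(f"need >= 2 carriers of allele {allele} at core {core}")
    pair_total = m * (m - 1) / 2.0

    order = (
        range(core - 1, -1, -1) if side == "left" else range(core + 1, panel.n_sites)
    )
    chrom = panel.sites[core].chrom
    pos_core = panel.sites[core].pos
    cm_core = gmap.cm_at(chrom, pos_core) if gmap is not None else 0.0

    group = np.zeros(m, dtype=np.int64)  # haplotype-identity class per carrier
    positions = [pos_core]
    cms = [0.0]
    values = [1.0]
    H = panel.haplotypes
    for s in order:
        group = group * 2 + H[carriers, s]
        _, counts = np.unique(group, return_counts=True)
        ehh_s = float(np.sum(counts * (counts - 1) / 2.0) / pair_total)
        positions.append(panel.sites[s].pos)
        if gmap is not None:
            cms.append(abs(gmap.cm_at(chrom, panel.sites[s].pos) - cm_core))
        else:
            cms.append(abs(panel.sites[s].pos - pos_core) * 1e-6)  # 1 cM/Mb fallback
        values.append(ehh_s)
        # relabel to keep group ids small
        _, group = np.unique(group, return_inverse=True)
    return EhhCurve(core, side, allele, np.array(positions), np.array(cms), np.array(values))


def _integrate_truncated(curve: EhhCurve, cutoff: float) -> float | None:
    """Trapezoidal integral of EHH over cM, truncated after the first point
    below ``cutoff`` (that point closes the last trapezoid).  None when the
    curve never drops below the cutoff before the region edge."""
    v, d = curve.values, curve.cm
    below = np.nonzero(v < cutoff)[0]
    if below.size == 0:  # includes a core at the panel edge with no flanking sites
        return None
    stop = below[0]
    return float(np.trapezoid(v[: stop + 1], d[: stop + 1]))


def ihs(panel: HaplotypePanel, gmap: GeneticMap | None, core: int,
        ehh_cutoff: float = 0.05, maf_min: float = 0.05) -> IhsScore:
    """Unstandardized iHS at one core site.

    iHH per core allele is the truncated EHH integral summed over both
    sides; ihs_raw = ln(iHH_A / iHH_D).  Cores with derived frequency
    outside [maf_min, 1 - maf_min] are skipped (status 'maf'); cores whose
    EHH never decays to the cutoff before the panel edge are skipped
    (status 'edge'); zero integrals give status 'degenerate'.
    """
    pos = panel.sites[core].pos
    q = float(panel.haplotypes[:, core].mean())
    score = IhsScore(core, pos, q)
    if not (maf_min <= q <= 1.0 - maf_min):
        score.status = "maf"
        return score
    n_der = int(panel.haplotypes[:, core].sum())
    n_anc = panel.n_haplotypes - n_der
    if n_der < 2 or n_anc < 2:
        score.status = "carriers"
        return score
    ihh = {}
    for allele, key in ((0, "a"), (1, "d")):
        total = 0.0
        for side in ("left", "right"):
            part = _integrate_truncated(ehh(panel, core, allele, side, gmap), ehh_cutoff)
            if part is None:
                score.status = "edge"
                return score
            total += part
        ihh[key] = total
    score.ihh_a, score.ihh_d = ihh["a"], ihh["d"]
    if ihh["a"] <= 0 or ihh["d"] <= 0:
        score.status = "degenerate"
        return score
    score.ihs_raw = math.log(ihh["a"] / ihh["d"])
    return score


def ihs_scan(panel: HaplotypePanel, gmap: GeneticMap | None = None,
             cores=None, ehh_cutoff: float = 0.05, maf_min: float = 0.05) -> list[IhsScore]:
    """iHS over many cores (default: every panel site)."""
    if cores is None:
        cores = range(panel.n_sites)
    return [ihs(panel, gmap, c, ehh_cutoff, maf_min) for c in cores]


def standardize_ihs(scores: list[IhsScore], n_bins: int = 50,
                    min_bin: int = 20, maf_min: float = 0.05) -> list[IhsScore]:
    """Standardize raw iHS within derived-allele-frequency bins.

    Equal-width bins on [maf_min, 1 - maf_min]; occupied bins with fewer
    than ``min_bin`` ok scores are merged with their nearest occupied
    neighbor before standardization, so every standardization group has
    mean 0 and sd 1 afterwards.
    """
    ok = [s for s in scores if s.status == "ok"]
    if not ok:
        return scores
    edges = np.linspace(maf_min, 1.0 - maf_min, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, [s.derived_freq for s in ok], side="right") - 1,
                  0, n_bins - 1)
    # merge under-occupied bins into the nearest occupied neighbor
    labels = {b: b for b in np.unique(idx)}
    counts = {b: int(np.sum(idx == b)) for b in labels}
    changed = True
    while changed and len(set(labels.values())) > 1:
        changed = False
        groups: dict[int, int] = {}
        for b in labels:
            groups.setdefault(labels[b], 0)
            groups[labels[b]] += counts[b]
        small = sorted(g for g, n in groups.items() if n < min_bin)
        if small:
            g = small[0]
            others = sorted(set(groups) - {g})
            target = min(others, key=lambda o: abs(o - g))
            for b in labels:
                if labels[b] == g:
                    labels[b] = target
            changed = True
    group_of = np.array([labels[b] for b in idx])
    raw = np.array([s.ihs_raw for s in ok])
    for g in np.unique(group_of):
        sel = group_of == g
        mu = raw[sel].mean()
        sd = raw[sel].std(ddof=0)
        if sd == 0:
            if sel.all():
                raise ValueError("all iHS scores in one degenerate bin with sd = 0")
            sd = math.nan  # leaves ihs_std undefined for the degenerate group
        for s_obj, z in zip(np.array(ok, dtype=object)[sel], (raw[sel] - mu) / sd):
            s_obj.ihs_std = float(z)
    return scores


def _beta_denominator(folded_core: float, n: int, p: float) -> float:
    k = np.arange(1, n)
    f = k / n
    folded = np.minimum(f, 1.0 - f)
    w = (1.0 - np.abs(folded - folded_core) / 0.5) ** p
    return float(np.sum(w / k))


def beta_score(folded_freqs: np.ndarray, positions: np.ndarray, core: int,
               n: int, half_width: int = 1000, p: float = 2.0) -> BetaScore:
    """Folded beta statistic at one core SNP.

    ``folded_freqs``/``positions`` describe every SNP on the chromosome
    (folded frequency in (0, 0.5], bp position); window SNPs are those
    within ``half_width`` bp of the core, core excluded.  theta_beta is the
    similarity-weighted SNP count normalized by the expected weighted
    frequency spectrum under neutrality; theta_w is Watterson's estimator
    of the same window.  beta = theta_beta - theta_w; an empty window gives
    beta = 0.
    """
    f_c = float(folded_freqs[core])
    if f_c <= 0.0:
        raise ValueError("core site is monomorphic")
    pos_c = positions[core]
    in_win = (np.abs(positions - pos_c) <= half_width) & (np.arange(len(positions)) != core)
    f_i = folded_freqs[in_win]
    a_n = float(np.sum(1.0 / np.arange(1, n)))
    if f_i.size == 0:
        return BetaScore(core, int(pos_c), f_c, 0.0, 0.0, 0.0, half_width)
    w = (1.0 - np.abs(f_i - f_c) / 0.5) ** p
    theta_beta = float(np.sum(w)) / _beta_denominator(f_c, n, p)
    theta_w = f_i.size / a_n
    return BetaScore(core, int(pos_c), f_c, theta_beta, theta_w,
                     theta_beta - theta_w, half_width)


def beta_scan(panel: HaplotypePanel, half_width: int = 1000, p: float = 2.0,
              maf_min: float = 0.0) -> list[BetaScore]:
    """Beta score at every polymorphic panel site (folded frequencies)."""
    freqs = panel.derived_freq
    folded = np.minimum(freqs, 1.0 - freqs)
    positions = panel.positions
    n = panel.n_haplotypes
    out = []
    for c in range(panel.n_sites):
        if folded[c] <= maf_min or folded[c] == 0.0:
            continue
        out.append(beta_score(folded, positions, c, n, half_width, p))
    return out


def empirical_top_fraction(scores, fraction: float = 0.01,
                           min_scores: int = 100) -> tuple[float, np.ndarray]:
    """Chromosome-wide empirical threshold: the (1 - fraction) quantile.

    Returns (threshold, boolean flags); scores strictly above the threshold
    are flagged, so an all-equal score list flags nothing.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size < min_scores:
        raise ValueError(f"need >= {min_scores} scores for a stable quantile")
    thr = quantile(arr, 1.0 - fraction)
    return thr, arr > thr
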