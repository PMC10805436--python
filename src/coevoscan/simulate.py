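"""Synthetic-data generators with known truth for every pipeline stage.

Each generator is a pure function of its seed and emulates the statistical
structure one analysis stage assumes:

* Balding-Nichols structured genotypes with a known fixation index F
  (validates the FST estimator);
* per-window neutral coalescent panels with known theta (null windows for
  Tajima's D — no recombination within a window, windows independent);
* constructive sweep panels where derived carriers copy a founder haplotype
  with distance-decaying fidelity (exercises EHH/iHS and its sign
  convention: long derived haplotypes give negative scores);
* frequency-matched SNP clusters around a balanced core (exercises beta);
* two-locus genotype pairs with controlled expected r2 at controlled
  genetic distances, including planted high-LD "epistatic" pairs
  (calibrates the unusual-LD null);
* expression matrices with planted eQTL effects and covariates;
* MR summary statistics with a known causal effect, optional directional
  pleiotropy and instrument correlation.

Every dataset ships with a :class:`SyntheticTruth` recording the scenario,
the true parameters and the seed; recovery tests read truth only from that
record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from coevoscan.eqtl import ExpressionSet
from coevoscan.io import GenotypeMatrix, HaplotypePanel, SiteRecord
from coevoscan.mr import MRInput

__all__ = [
    "SyntheticTruth",
    "sim_balding_nichols",
    "sim_neutral_windows",
    "sim_sweep_panel",
    "sim_balanced_cluster_panel",
    "sim_ld_pairs",
    "default_ld_profile",
    "sim_expression",
    "sim_mr_dataset",
]


@dataclass
class SyntheticTruth:
    scenario: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


def _sites(chrom: str, positions) -> list[SiteRecord]:
    return [SiteRecord(chrom, int(p), "A", "G", "ref") for p in positions]


# ---------------------------------------------------------------------------
# Structured populations (FST truth)
# ---------------------------------------------------------------------------

def sim_balding_nichols(
    F: float,
    p0=0.5,
    n_pops: int = 2,
    n_diploids: int = 100,
    n_sites: int = 500,
    seed: int = 0,
    chrom: str = "1",
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Structured genotypes under the Balding-Nichols model.

    Per population and site, the local allele frequency is drawn from
    Beta(p0 (1-F)/F, (1-p0)(1-F)/F) — mean p0, variance F p0 (1-p0) — and
    genotypes are Binomial(2, freq), i.e. Hardy-Weinberg within
    populations.  ``p0`` is a scalar or a (low, high) range sampled
    uniformly per site.
    """
    if not 0.0 < F < 1.0:
        raise ValueError("F must be in (0, 1)")
    if n_pops < 2 or n_diploids < 2 or n_sites < 1:
        raise ValueError("degenerate population sizes")
    rng = np.random.default_rng(seed)
    if np.isscalar(p0):
        anc = np.full(n_sites, float(p0))
    else:
        lo, hi = p0
        anc = rng.uniform(lo, hi, size=n_sites)
    a = anc * (1 - F) / F
    b = (1 - anc) * (1 - F) / F
    dosages = np.empty((n_pops * n_diploids, n_sites), dtype=np.int8)
    pops: dict[str, str] = {}
    samples: list[str] = []
    for k in range(n_pops):
        freq = rng.beta(a, b)
        block = rng.binomial(2, freq, size=(n_diploids, n_sites)).astype(np.int8)
        dosages[k * n_diploids:(k + 1) * n_diploids] = block
        for i in range(n_diploids):
            name = f"pop{k}_ind{i}"
            samples.append(name)
            pops[name] = f"pop{k}"
    gm = GenotypeMatrix(_sites(chrom, range(1, n_sites + 1)), samples, dosages, pops)
    truth = SyntheticTruth("balding_nichols", seed,
                           {"F": F, "p0": p0, "n_pops": n_pops,
                            "n_diploids": n_diploids, "n_sites": n_sites})
    return gm, truth


# ---------------------------------------------------------------------------
# Neutral coalescent windows (Tajima's D null)
# ---------------------------------------------------------------------------

def _coalescent_window(rng: np.random.Generator, n: int, theta: float,
                       window_bp: int) -> np.ndarray:
    """One standard-coalescent genealogy without recombination; returns the
    n x S derived-allele matrix (infinite sites)."""
    # lineages: list of (leafset, birth_time)
    lineages: list[tuple[frozenset, float]] = [(frozenset([i]), 0.0) for i in range(n)]
    branches: list[tuple[frozenset, float]] = []  # (carriers, length)
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        (set_i, t_i), (set_j, t_j) = lineages[i], lineages[j]
        branches.append((set_i, t - t_i))
        branches.append((set_j, t - t_j))
        merged = set_i | set_j
        lineages = [lin for idx, lin in enumerate(lineages) if idx not in (i, j)]
        lineages.append((merged, t))
    lengths = np.array([b[1] for b in branches])
    total = lengths.sum()
    n_mut = rng.poisson(theta / 2.0 * total)
    n_mut = min(n_mut, window_bp)  # infinite-sites cap at one mutation per bp
    if n_mut == 0:
        return np.zeros((n, 0), dtype=np.uint8)
    which = rng.choice(len(branches), size=n_mut, p=lengths / total)
    mat = np.zeros((n, n_mut), dtype=np.uint8)
    for col, b in enumerate(which):
        mat[list(branches[b][0]), col] = 1
    return mat


def sim_neutral_windows(
    n_chrom: int, theta: float, n_windows: int, seed: int = 0,
    window_bp: int = 1000, chrom: str = "22",
) -> list[HaplotypePanel]:
    """Independent neutral windows: coalescent trees with Poisson mutations.

    Coalescence times are exponential with rate k(k-1)/2 while k lineages
    remain; mutations fall on branches as a Poisson process of rate theta/2
    per unit branch length, each creating one infinite-sites SNP.  Sites
    get distinct uniform positions inside the window; successive windows
    tile the chromosome at ``window_bp`` spacing.
    """
    if n_chrom < 2:
        raise ValueError("need >= 2 chromosomes")
    rng = np.random.default_rng(seed)
    panels: list[HaplotypePanel] = []
    for w in range(n_windows):
        mat = _coalescent_window(rng, n_chrom, theta, window_bp)
        s = mat.shape[1]
        offset = w * window_bp
        pos = np.sort(rng.choice(window_bp, size=s, replace=False)) + offset + 1
        panels.append(HaplotypePanel(_sites(chrom, pos), mat))
    return panels


# ---------------------------------------------------------------------------
# Sweep panels (iHS truth)
# ---------------------------------------------------------------------------

def sim_sweep_panel(
    n_chrom: int = 100,
    n_sites: int = 201,
    derived_freq: float = 0.5,
    founder_fidelity: float = 0.99,
    decay_bp: float = 100.0,
    spacing_bp: int = 100,
    seed: int = 0,
    chrom: str = "7",
    sweep: bool = True,
) -> tuple[HaplotypePanel, SyntheticTruth]:
    """Constructive sweep: derived core-allele carriers copy one founder.

    The core SNP sits at the central site with derived frequency
    ``derived_freq``.  Each derived carrier copies the founder haplotype
    with per-site probability founder_fidelity ** (d / decay_bp) at
    distance d bp from the core (fidelity 1 = exact copies, EHH stays 1);
    elsewhere, and for all ancestral carriers, alleles are independent
    draws from per-site background frequencies.  ``sweep=False`` keeps the
    same core frequency but makes derived carriers as diverse as the
    background — the matched neutral control.
    """
    n_der = int(round(derived_freq * n_chrom))
    if n_der < 2 or n_chrom - n_der < 2:
        raise ValueError("derived frequency leaves < 2 carriers on one side")
    rng = np.random.default_rng(seed)
    core = n_sites // 2
    positions = (np.arange(n_sites) - core) * spacing_bp + 10 * spacing_bp * n_sites
    bg = rng.uniform(0.1, 0.9, size=n_sites)
    haps = (rng.random((n_chrom, n_sites)) < bg).astype(np.uint8)
    founder = (rng.random(n_sites) < bg).astype(np.uint8)
    carriers = rng.choice(n_chrom, size=n_der, replace=False)
    if sweep:
        d = np.abs(positions - positions[core]).astype(float)
        p_copy = founder_fidelity ** (d / decay_bp) if founder_fidelity < 1 else np.ones_like(d)
        for h in carriers:
            copy = rng.random(n_sites) < p_copy
            haps[h, copy] = founder[copy]
    haps[:, core] = 0
    haps[carriers, core] = 1
    panel = HaplotypePanel(_sites(chrom, positions), haps)
    truth = SyntheticTruth("sweep" if sweep else "neutral_control", seed,
                           {"core_index": core, "derived_freq": derived_freq,
                            "founder_fidelity": founder_fidelity,
                            "n_chrom": n_chrom, "n_sites": n_sites})
    return panel, truth


def sim_balanced_cluster_panel(
    n_chrom: int = 100,
    n_flank: int = 20,
    core_folded: float = 0.4,
    cluster: bool = True,
    window_bp: int = 1000,
    seed: int = 0,
    chrom: str = "19",
) -> tuple[HaplotypePanel, SyntheticTruth]:
    """Core SNP with flanking SNPs whose frequencies match the core's.

    With ``cluster=True`` the ``n_flank`` window SNPs get folded
    frequencies tightly clustered around the core's (the balanced-locus
    signature beta detects); with ``cluster=False`` they are drawn from a
    neutral-like spectrum p(f) proportional to 1/f.
    """
    rng = np.random.default_rng(seed)
    n_sites = n_flank + 1
    core = n_sites // 2
    pos = np.sort(rng.choice(window_bp, size=n_sites, replace=False)) + 1
    freqs = np.empty(n_sites)
    if cluster:
        freqs[:] = np.clip(core_folded + rng.normal(0, 0.03, n_sites), 0.05, 0.5)
    else:
        # sample from the ~1/f neutral folded spectrum on [1/n, 0.5]
        u = rng.random(n_sites)
        lo, hi = 1.0 / n_chrom, 0.5
        freqs = lo * (hi / lo) ** u
    freqs[core] = core_folded
    haps = np.zeros((n_chrom, n_sites), dtype=np.uint8)
    for j, f in enumerate(freqs):
        k = max(1, int(round(f * n_chrom)))
        haps[rng.choice(n_chrom, size=k, replace=False), j] = 1
    panel = HaplotypePanel(_sites(chrom, pos), haps)
    truth = SyntheticTruth("balanced_cluster" if cluster else "neutral_spectrum",
                           seed, {"core_index": core, "core_folded": core_folded,
                                  "n_chrom": n_chrom, "n_flank": n_flank})
    return panel, truth


# ---------------------------------------------------------------------------
# Two-locus LD pairs (uLD calibration)
# ---------------------------------------------------------------------------

def default_ld_profile(rng: np.random.Generator, d_cm: float) -> float:
    """Background expected r2 at genetic distance d: exponential decay with
    a long right tail (Beta-distributed multiplier)."""
    scale = np.exp(-d_cm / 0.05)
    return float(np.clip(rng.beta(0.5, 4.0) * scale, 0.0, 0.95))


def _draw_pair(rng, n_samples, p, q, target_r2, sign=1.0):
    """Dosage vectors for two loci with expected r2 = target (haplotype
    frequencies solved for the required D, 2N haplotypes multinomial)."""
    d_max_pos = min(p * (1 - q), (1 - p) * q)
    d_max_neg = min(p * q, (1 - p) * (1 - q))
    d = sign * np.sqrt(target_r2 * p * (1 - p) * q * (1 - q))
    limit = d_max_pos if sign > 0 else d_max_neg
    if abs(d) > limit:
        raise ValueError(f"target r2={target_r2} infeasible for p={p}, q={q}")
    f = np.array([
        (1 - p) * (1 - q) + d,  # 00
        (1 - p) * q - d,        # 01
        p * (1 - q) - d,        # 10
        p * q + d,              # 11
    ])
    haps = rng.choice(4, size=2 * n_samples, p=f)
    a1 = (haps // 2)[0::2] + (haps // 2)[1::2]  # locus 1 dosage per diploid
    a2 = (haps % 2)[0::2] + (haps % 2)[1::2]
    return a1.astype(np.int8), a2.astype(np.int8)


def sim_ld_pairs(
    n_pairs: int,
    n_samples: int = 500,
    seed: int = 0,
    bin_profile=default_ld_profile,
    planted: list[tuple[float, float]] | None = None,
    max_d_cm: float = 0.2,
) -> tuple[list[dict], SyntheticTruth]:
    """Independent SNP pairs with controlled r2 at controlled distances.

    Null pairs draw a genetic distance uniformly on (0, ``max_d_cm``] and a
    target r2 from ``bin_profile`` at that distance; ``planted`` entries
    are (d_cm, target_r2) pairs placed exactly (allele frequencies set
    equal so any r2 is feasible).  Returns one record per pair:
    ``{g1, g2, d_cm, target_r2, planted}``.
    """
    rng = np.random.default_rng(seed)
    records: list[dict] = []
    for _ in range(n_pairs):
        d_cm = rng.uniform(1e-4, max_d_cm)
        target = bin_profile(rng, d_cm)
        p = q = rng.uniform(0.25, 0.75)  # equal freqs keep any target feasible
        g1, g2 = _draw_pair(rng, n_samples, p, q, target)
        records.append({"g1": g1, "g2": g2, "d_cm": d_cm,
                        "target_r2": target, "planted": False})
    for d_cm, target in planted or []:
        p = q = rng.uniform(0.3, 0.7)
        g1, g2 = _draw_pair(rng, n_samples, p, q, target)
        records.append({"g1": g1, "g2": g2, "d_cm": d_cm,
                        "target_r2": target, "planted": True})
    truth = SyntheticTruth("ld_pairs", seed,
                           {"n_pairs": n_pairs, "n_samples": n_samples,
                            "planted": planted or [], "max_d_cm": max_d_cm})
    return records, truth


# ---------------------------------------------------------------------------
# Expression with planted eQTLs
# ---------------------------------------------------------------------------

def sim_expression(
    genotypes: GenotypeMatrix,
    effect_map: list[tuple[int, str, float]],
    genes: list[str] | None = None,
    n_covariates: int = 2,
    covariate_beta: float = 0.5,
    noise_sd: float = 0.5,
    tissue: str = "synthetic_tissue",
    seed: int = 0,
) -> tuple[ExpressionSet, SyntheticTruth]:
    """Expression = sum(beta * dosage) + covariate effects + Gaussian noise.

    ``effect_map`` lists (site index, gene name, beta); genes not named
    there are pure noise (null genes).  Covariates are standard-normal
    columns whose true effect ``covariate_beta`` applies to every gene.
    """
    for si, _, _ in effect_map:
        if not 0 <= si < genotypes.n_sites:
            raise KeyError(f"effect SNP index {si} not in genotype matrix")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = sorted({g for _, g, _ in effect_map}) or ["gene0"]
    n_s = genotypes.n_samples
    C = rng.normal(size=(n_s, n_covariates)) if n_covariates else np.zeros((n_s, 0))
    expr = np.zeros((len(genes), n_s))
    for gi in range(len(genes)):
        expr[gi] = C @ np.full(n_covariates, covariate_beta) + rng.normal(0, noise_sd, n_s)
    for si, gene, beta in effect_map:
        gi = genes.index(gene)
        expr[gi] += beta * genotypes.dosages[:, si].astype(float)
    es = ExpressionSet(tissue, list(genes), list(genotypes.samples), expr, C,
                       [f"cov{k}" for k in range(n_covariates)])
    truth = SyntheticTruth("expression", seed,
                           {"effects": [(si, g, b) for si, g, b in effect_map],
                            "noise_sd": noise_sd, "covariate_beta": covariate_beta})
    return es, truth


# ---------------------------------------------------------------------------
# MR summary statistics
# ---------------------------------------------------------------------------

def sim_mr_dataset(
    n_instruments: int = 8,
    causal_beta: float = 0.3,
    pleiotropy_intercept: float = 0.0,
    rho=0.0,
    se_x: float = 0.02,
    se_y: float = 0.05,
    seed: int = 0,
) -> tuple[MRInput, SyntheticTruth]:
    """Exposure/outcome summary statistics with a known causal effect.

    True instrument effects gamma_j are uniform on [0.2, 0.5] with random
    sign; observed b_X = gamma + N(0, se_x^2) and b_Y = causal_beta * gamma
    + pleiotropy_intercept + MVN(0, Omega) with Omega_ij = se_y^2 rho_ij.
    ``rho`` is a scalar equicorrelation or a full matrix.  ``se_x = se_y =
    0`` gives noiseless effects (IVW recovers causal_beta exactly).
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(rho):
        R = np.full((n_instruments, n_instruments), float(rho))
        np.fill_diagonal(R, 1.0)
    else:
        R = np.asarray(rho, dtype=float)
    if np.linalg.eigvalsh(R).min() < -1e-8:
        raise ValueError("rho not positive semi-definite")
    gamma = rng.uniform(0.2, 0.5, n_instruments) * rng.choice([-1.0, 1.0], n_instruments)
    b_x = gamma + (rng.normal(0, se_x, n_instruments) if se_x > 0 else 0.0)
    omega = se_y**2 * R
    noise_y = (rng.multivariate_normal(np.zeros(n_instruments), omega,
                                       method="cholesky")
               if se_y > 0 else np.zeros(n_instruments))
    b_y = causal_beta * gamma + pleiotropy_intercept + noise_y
    inp = MRInput([f"rs{j}" for j in range(n_instruments)], b_x,
                  np.full(n_instruments, max(se_x, 1e-12)), b_y,
                  np.full(n_instruments, max(se_y, 1e-12)), R)
    truth = SyntheticTruth("mr", seed,
                           {"causal_beta": causal_beta,
                            "pleiotropy_intercept": pleiotropy_intercept,
                            "n_instruments": n_instruments,
                            "se_x": se_x, "se_y": se_y})
    return inp, truth
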