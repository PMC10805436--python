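"""Mendelian randomization with correlated instruments.

Given per-SNP effects of the instruments on an exposure (b_X, se_X) and an
outcome (b_Y, se_Y) plus the instruments' LD correlation matrix rho, three
estimators of the causal effect of the exposure on the outcome:

* IVW (inverse-variance weighted) — generalized weighted regression of b_Y
  on b_X through the origin with weight matrix Omega^-1, where
  Omega_ij = se_Y,i * se_Y,j * rho_ij accounts for instrument correlation.
* MR-Egger — the same generalized regression with a free intercept; a
  non-zero intercept indicates directional pleiotropy, and the slope is the
  pleiotropy-corrected causal estimate.  When the intercept is significant
  (p < 0.05) the report flags IVW as unreliable and foregrounds Egger.
* Weighted median — the 50% weight-crossing point of the per-instrument
  ratio estimates b_Y/b_X; consistent when instruments carrying at least
  half the weight are valid.  Run on the pruned, weakly correlated
  instrument set, it ignores rho; its SE comes from a parametric bootstrap.

Instrument selection enforces instrument strength (F > 10), exposure
association (p < 0.001) and greedy LD pruning at r2 > 0.8.  With exposure
and outcome standardized upstream, beta is in SD-outcome per SD-exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MRInput",
    "MRResult",
    "select_instruments",
    "ivw_correlated",
    "egger_correlated",
    "weighted_median",
    "run_all_methods",
    "bonferroni_threshold",
]


@dataclass
class MRInput:
    snps: list[str]
    b_x: np.ndarray
    se_x: np.ndarray
    b_y: np.ndarray
    se_y: np.ndarray
    rho: np.ndarray  # instrument x instrument LD correlation

    def __post_init__(self):
        self.b_x = np.asarray(self.b_x, dtype=float)
        self.se_x = np.asarray(self.se_x, dtype=float)
        self.b_y = np.asarray(self.b_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        j = len(self.snps)
        for name in ("b_x", "se_x", "b_y", "se_y"):
            if getattr(self, name).shape != (j,):
                raise ValueError(f"{name} must have length {j}")
        if self.rho.shape != (j, j):
            raise ValueError("rho must be J x J")
        if not np.allclose(self.rho, self.rho.T, atol=1e-8):
            raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(self.rho), 1.0, atol=1e-8):
            raise ValueError("rho must have unit diagonal")
        if np.linalg.eigvalsh(self.rho).min() < -1e-8:
            raise ValueError("rho must be positive semi-definite")

    @property
    def n_instruments(self) -> int:
        return len(self.snps)

    def omega(self) -> np.ndarray:
        return np.outer(self.se_y, self.se_y) * self.rho

    def subset(self, idx) -> "MRInput":
        idx = list(idx)
        return MRInput([self.snps[i] for i in idx], self.b_x[idx], self.se_x[idx],
                       self.b_y[idx], self.se_y[idx], self.rho[np.ix_(idx, idx)])


@dataclass
class MRResult:
    method: str  # IVW | Egger | WeightedMedian
    beta: float
    se: float
    ci95: tuple[float, float]
    p: float
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    pleiotropy_flag: bool = False


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _result(method: str, beta: float, se: float, **kw) -> MRResult:
    return MRResult(method, beta, se, (beta - 1.96 * se, beta + 1.96 * se),
                    _normal_p(beta / se), **kw)


def select_instruments(
    snps, b_x, se_x, p_x, ld_r2: np.ndarray,
    f_min: float = 10.0, p_max: float = 1e-3, r2_max: float = 0.8,
) -> list[int]:
    """Instrument selection: strength, association and greedy LD pruning.

    Keeps SNPs with F = (b_X/se_X)^2 > f_min and p_X < p_max, then walks
    candidates by ascending p_X keeping each SNP unless its r2 with an
    already-kept SNP exceeds r2_max.  Returns kept indices (original order
    of the pruning walk).  Raises when nothing survives.
    """
    b_x = np.asarray(b_x, dtype=float)
    se_x = np.asarray(se_x, dtype=float)
    p_x = np.asarray(p_x, dtype=float)
    ld_r2 = np.asarray(ld_r2, dtype=float)
    f = (b_x / se_x) ** 2
    candidates = [i for i in range(len(snps)) if f[i] > f_min and p_x[i] < p_max]
    candidates.sort(key=lambda i: p_x[i])
    kept: list[int] = []
    for i in candidates:
        if all(ld_r2[i, j] <= r2_max for j in kept):
            kept.append(i)
    if not kept:
        raise ValueError("no instruments survive selection")
    return kept


def ivw_correlated(inp: MRInput, random_effects: bool = False) -> MRResult:
    """IVW causal estimate with LD-correlation-adjusted weights.

    Fixed-effect by default; with ``random_effects`` the standard error is
    inflated by max(1, sqrt(Q / (J - 1))) where Q is Cochran's
    heterogeneity statistic of the weighted regression residuals.
    """
    if inp.n_instruments < 1:
        raise ValueError("need >= 1 instrument")
    omega = inp.omega()
    try:
        oi = np.linalg.inv(omega)
    except np.linalg.LinAlgError as e:
        raise ValueError("Omega singular; prune highly correlated instruments") from e
    denom = float(inp.b_x @ oi @ inp.b_x)
    beta = float(inp.b_x @ oi @ inp.b_y) / denom
    se = math.sqrt(1.0 / denom)
    if random_effects and inp.n_instruments > 1:
        resid = inp.b_y - beta * inp.b_x
        q = float(resid @ oi @ resid)
        se *= max(1.0, math.sqrt(q / (inp.n_instruments - 1)))
    return _result("IVW", beta, se)


def egger_correlated(inp: MRInput) -> MRResult:
    """MR-Egger: GLS of b_Y on [1, b_X] with weight Omega^-1.

    The slope is the causal estimate; the intercept tests directional
    pleiotropy (two-sided normal).
    """
    if inp.n_instruments < 3:
        raise ValueError("MR-Egger needs >= 3 instruments")
    omega = inp.omega()
    try:
        oi = np.linalg.inv(omega)
    except np.linalg.LinAlgError as e:
        raise ValueError("Omega singular; prune highly correlated instruments") from e
    X = np.column_stack([np.ones(inp.n_instruments), inp.b_x])
    xtoi = X.T @ oi
    cov = np.linalg.inv(xtoi @ X)
    coef = cov @ (xtoi @ inp.b_y)
    intercept, slope = float(coef[0]), float(coef[1])
    se_i, se_s = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    p_i = _normal_p(intercept / se_i)
    return _result("Egger", slope, se_s, egger_intercept=intercept,
                   intercept_se=se_i, intercept_p=p_i,
                   pleiotropy_flag=p_i < 0.05)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Value where the cumulative sorted weight crosses 0.5, interpolating
    linearly between adjacent ratios (centered cumulative convention)."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - w / 2.0
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(cum, 0.5)) - 1
    frac = (0.5 - cum[k]) / (cum[k + 1] - cum[k])
    return float(r[k] + frac * (r[k + 1] - r[k]))


def weighted_median(inp: MRInput, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Ratio estimates b_Y,j / b_X,j weighted by (b_X,j / se_Y,j)^2; the SE
    resamples b_X and b_Y independently from their stated standard errors.
    """
    if inp.n_instruments < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    if np.any(inp.b_x == 0):
        raise ValueError("instrument with b_X = 0")
    weights = (inp.b_x / inp.se_y) ** 2
    est = _weighted_median_point(inp.b_y / inp.b_x, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(inp.b_x, inp.se_x)
        by = rng.normal(inp.b_y, inp.se_y)
        bx = np.where(bx == 0, 1e-12, bx)
        boots[b] = _weighted_median_point(by / bx, (bx / inp.se_y) ** 2)
    se = float(boots.std(ddof=1))
    return _result("WeightedMedian", est, se)


def run_all_methods(inp: MRInput, n_boot: int = 1000, seed: int = 0) -> dict:
    """IVW, Egger and weighted median, with the reporting rule applied.

    If the Egger intercept is significant (p < 0.05) the report marks IVW
    as unreliable and foregrounds Egger as the primary estimate.
    """
    ivw = ivw_correlated(inp)
    egger = egger_correlated(inp) if inp.n_instruments >= 3 else None
    wm = weighted_median(inp, n_boot=n_boot, seed=seed) if inp.n_instruments >= 3 else None
    pleiotropy = bool(egger and egger.pleiotropy_flag)
    return {
        "IVW": ivw,
        "Egger": egger,
        "WeightedMedian": wm,
        "pleiotropy_detected": pleiotropy,
        "primary": "Egger" if pleiotropy else "IVW",
    }


def bonferroni_threshold(category_counts, alpha: float = 0.05) -> float:
    """Family-wise significance threshold: alpha / total test count."""
    counts = list(category_counts)
    if not counts:
        raise ValueError("empty category list")
    if any(c <= 0 for c in counts):
        raise ValueError("category counts must be positive")
    return alpha / sum(counts)
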