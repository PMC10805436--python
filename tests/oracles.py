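"""Independent brute-force oracles used to cross-check the estimators.

Each oracle recomputes a statistic by a different route than the package
(explicit pairwise sums, normal equations, direct matrix solves) and is
deliberately written without importing the implementation internals.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def tajimas_d_brute(haps: np.ndarray) -> float:
    """Tajima's D from explicit pairwise haplotype differences.

    pi is the average Hamming distance over all C(n,2) haplotype pairs;
    the constants are summed directly.
    """
    n, n_sites = haps.shape
    seg = [(j, haps[:, j]) for j in range(n_sites)
           if 0 < haps[:, j].sum() < n]
    s = len(seg)
    if s == 0 or n < 3:
        return math.nan
    pi = 0.0
    n_pairs = 0
    for i in range(n):
        for k in range(i + 1, n):
            pi += sum(int(col[i] != col[k]) for _, col in seg)
            n_pairs += 1
    pi /= n_pairs
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return math.nan
    return (pi - s / a1) / math.sqrt(var)


def wc_fst_oracle(pop_counts) -> float:
    """Independent transcription of the Weir-Cockerham (1984) components."""
    r = len(pop_counts)
    n = [c[0] for c in pop_counts]
    p = [c[1] / (2.0 * c[0]) for c in pop_counts]
    h = [c[2] / c[0] for c in pop_counts]
    nbar = sum(n) / r
    sum_nsq = sum(ni * ni for ni in n)
    nc = (r * nbar - sum_nsq / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4.0 * nbar)
    )
    c = hbar / 2.0
    if a + b + c == 0:
        return math.nan
    return a / (a + b + c)


def r2_oracle(x, y) -> float:
    """Squared Pearson correlation via raw definitional sums."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = (n * sxx - sx * sx) * (n * syy - sy * sy)
    if den <= 0:
        return math.nan
    return num * num / den


def ols_oracle(y, X):
    """OLS via normal equations: (beta_hat, se, t, p) for each coefficient."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, t, p


def gls_oracle(y, X, omega):
    """Generalized least squares by explicit matrix arithmetic:
    (coef, covariance)."""
    oi = np.linalg.inv(np.asarray(omega, float))
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    cov = np.linalg.inv(X.T @ oi @ X)
    coef = cov @ X.T @ oi @ np.asarray(y, float)
    return coef, cov


def weighted_median_oracle(ratios, weights) -> float:
    """Brute-force cumulative-weight crossing with linear interpolation."""
    pairs = sorted(zip(ratios, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    centers = []
    for rat, w in pairs:
        centers.append((cum + w / 2.0) / total)
        cum += w
    if centers[0] >= 0.5:
        return pairs[0][0]
    if centers[-1] <= 0.5:
        return pairs[-1][0]
    for k in range(len(pairs) - 1):
        if centers[k] < 0.5 <= centers[k + 1]:
            frac = (0.5 - centers[k]) / (centers[k + 1] - centers[k])
            return pairs[k][0] + frac * (pairs[k + 1][0] - pairs[k][0])
    raise AssertionError("unreachable")
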