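"""Per-SNP linear-model eQTL association with covariate adjustment.

Each selected SNP is tested against each gene's expression in each tissue
with an ordinary least-squares model

    expression ~ intercept + dosage + covariates

where the dosage is the count of non-reference alleles, so beta_eqtl is the
expression change per non-reference allele.  Covariates (genotype PCs, age,
sex, PEER factors, technical variables) are consumed as given — upstream
normalization and hidden-factor estimation are not re-derived.  Genome-wide
significance uses a fixed p < 1e-8 threshold with no further multiplicity
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from coevoscan.io import MISSING, GenotypeMatrix

__all__ = ["ExpressionSet", "EqtlResult", "ols_association", "eqtl_scan"]


@dataclass
class ExpressionSet:
    """Expression for one tissue: genes x samples, with sample covariates."""

    tissue: str
    genes: list[str]
    samples: list[str]
    expression: np.ndarray  # genes x samples
    covariates: np.ndarray  # samples x n_cov (no intercept column)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.expression.shape != (len(self.genes), len(self.samples)):
            raise ValueError("expression must be genes x samples")
        if self.covariates.shape[0] != len(self.samples):
            raise ValueError("covariates must be samples x n_cov")
        if np.isnan(self.covariates).any():
            raise ValueError("missing covariate entries after alignment")


@dataclass
class EqtlResult:
    snp_pos: int
    gene: str
    tissue: str
    beta: float
    se: float
    t: float
    p: float
    significant: bool
    n: int


def ols_association(y, g, C=None) -> tuple[float, float, float, float]:
    """OLS of expression on genotype with covariates: (beta, se, t, p).

    The design is [intercept, g, C]; p is two-sided from the t distribution
    on the genotype coefficient.  A rank-deficient design (e.g. constant
    genotype) raises with the offending column named.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    cols = [np.ones_like(g), g]
    names = ["intercept", "genotype"]
    if C is not None:
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[0] != y.size:
            C = C.T
        for k in range(C.shape[1]):
            cols.append(C[:, k])
            names.append(f"covariate_{k}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a column whose removal restores full column rank
        for k in range(X.shape[1] - 1, -1, -1):
            if np.linalg.matrix_rank(np.delete(X, k, axis=1)) == rank:
                raise ValueError(f"design matrix rank-deficient at column {names[k]!r}")
        raise ValueError("design matrix rank-deficient")
    if y.size - X.shape[1] < 1:
        raise ValueError("residual degrees of freedom < 1")
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.tvalues[1]), float(fit.pvalues[1])


def eqtl_scan(
    snp_indices,
    genotypes: GenotypeMatrix,
    expressions: list[ExpressionSet],
    threshold: float = 1e-8,
    maf_min: float = 0.05,
) -> list[EqtlResult]:
    """Test every (selected SNP, gene, tissue) combination.

    SNPs with MAF <= ``maf_min`` are excluded.  Samples are aligned by
    intersecting genotype and expression sample ids; genotype-missing
    samples are dropped per test.  Significance is strict: p < threshold.
    """
    snp_indices = list(snp_indices)
    if not snp_indices:
        raise ValueError("empty SNP list")
    maf = genotypes.maf()
    tested = [i for i in snp_indices if maf[i] > maf_min]
    results: list[EqtlResult] = []
    geno_order = {s: i for i, s in enumerate(genotypes.samples)}
    for expr in expressions:
        shared = [s for s in expr.samples if s in geno_order]
        if not shared:
            raise ValueError(f"no shared samples with tissue {expr.tissue!r}")
        e_idx = [expr.samples.index(s) for s in shared]
        g_idx = [geno_order[s] for s in shared]
        C = expr.covariates[e_idx, :] if expr.covariates.size else None
        for si in tested:
            g = genotypes.dosages[g_idx, si].astype(float)
            called = g != MISSING
            for gi, gene in enumerate(expr.genes):
                y = expr.expression[gi, :][e_idx]
                Cs = C[called, :] if C is not None else None
                beta, se, t, p = ols_association(y[called], g[called], Cs)
                results.append(EqtlResult(
                    genotypes.sites[si].pos, gene, expr.tissue,
                    beta, se, t, p, p < threshold, int(called.sum()),
                ))
    return results
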