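# Methods

This note records the models, conventions and design choices behind each
stage, what the synthetic generators do and do not emulate, and the
problem sizes used by the default test and acceptance runs.

## Conventions used everywhere

* **Coordinates.** VCF positions are 1-based; every interval table
  (BED-style masks, gene regions, matched windows) is 0-based half-open.
  Conversion happens only at the I/O boundary.
* **Quantiles.** All empirical thresholds use linear interpolation between
  the closest order statistics (`numpy` "linear"). All outlier
  comparisons are strict inequalities, so a value exactly at a threshold
  is never significant. One convention, used by the Tajima null, the β
  top fraction and the uLD bin thresholds alike, so calibration results
  transfer.
* **Missing data.** Dosage matrices carry an explicit missing state;
  haplotype stages (EHH/iHS, β from panels) require complete phased data
  and refuse anything else, because homozygosity tracts are undefined on
  missing haplotypes.
* **Determinism.** Every simulator and every stochastic stage is a pure
  function of a single integer seed.

## Diversity scan

Tajima's D per window uses per-site π_j = 2k_j(n_j−k_j)/(n_j(n_j−1)), so
sites with different call rates contribute with their own sample size; the
variance constants use the median per-site chromosome count of the
window. Windows with more than 10% missing genotype entries are excluded
and counted (a declared rule; upstream callers may not document how their
windowed n treats missingness). D is undefined (not an error) when S = 0,
n < 3, or the variance term vanishes — at n = 2 the constants c₁ and c₂
are exactly zero.

The empirical null takes user-supplied null regions (typically genic
windows of a reference chromosome) and requires at
least 40 defined window values before percentiles are considered stable.
Classification is `low`/`high`/`ns` by strict comparison with the
2.5th/97.5th percentiles; per-gene output is the proportion of windows in
each class.

Weir–Cockerham F_ST is computed per site from (n_i, alt count, observed
heterozygote count) per population, requiring ≥ 2 populations of ≥ 2
diploids. Monomorphic sites are undefined. Per-gene means average raw
per-site ratios with negatives retained. Two properties of this estimator
matter for interpretation: it is invariant to allele-label swaps (tested),
and the *mean of per-site ratios* is Jensen-biased downward relative to
the ratio of summed components when few populations contribute — with two
populations at F = 0.3 the mean-of-ratios sits near 0.23, with four
populations (the four-super-population design this package mirrors) it
recovers F within ±0.02. Recovery checks therefore simulate four
populations of 200 diploids and 1,000 sites.

## Haplotype scan

**EHH** is computed exactly: carriers of the core allele are progressively
partitioned into identity classes site by site outward, and
EHH(s) = Σ_g C(m_g,2)/C(m,2). Curves are non-increasing and bounded in
[0,1] by construction (asserted in tests).

**iHS** integrates each EHH curve by trapezoid over cM distance (a genetic
map with constant extrapolation beyond its ends; without a map, 1 cM/Mb),
truncating after the first site below the EHH cutoff (default 0.05), that
site closing the last trapezoid. Cores whose EHH never reaches the cutoff
before the panel edge are *skipped* (status `edge`), not truncated:
truncation would bias iHH downward asymmetrically, and this deliberately
differs from tools that keep edge cores. Cores outside the MAF window
[0.05, 0.95] are skipped. Standardization is within 50 equal-width
derived-frequency bins; occupied bins with fewer than 20 scores merge into
their nearest occupied neighbour, and every final group has mean 0, sd 1.
The cutoff, MAF floor and bin count are configurable defaults in the style
of standard EHH software.

**β score** is the folded single-population variant: for window SNPs
within ±1,000 bp of the core (core excluded, both window half-width and
sharpness p = 2 configurable),

    w_i = (1 − |f̃_i − f̃_c| / 0.5)^p,
    θ̂_β = Σ w_i / Σ_{k=1..n−1} w(fold(k/n))/k,    θ̂_W = S_window / a_n,
    β = θ̂_β − θ̂_W,

with fold(x) = min(x, 1−x). S_window counts the window SNPs excluding the
core, consistent with the weight sum. An empty window yields β = 0, a
monomorphic core an error. β is invariant to flipping the 0/1 coding of
any window site (folding absorbs orientation; tested). Chromosome-wide
significance flags scores strictly above the top-1% quantile; with N
scored cores this flags at most ⌈0.01·N⌉ and, at N a multiple of 100,
exactly 1%.

## Unusual LD

r² is the squared Pearson correlation of dosages over samples called in
both SNPs (≥ 3 required; constant vectors undefined and the pair skipped).
Cluster pairs are all unordered pairs among SNPs with MAF strictly above
0.05, annotated with the containing gene (or `intergenic`) and the genetic
distance |cM_i − cM_j|.

Null windows are anchored at every gene start: [start, start+L) is kept
iff exactly k genes are fully contained and the window does not overlap
the excluded target cluster; overlapping survivors are all retained. The
anchoring rule is a declared choice among several defensible screens;
gene containment, not overlap, defines the count, and the
supplied gene table defines what counts as a gene. Null pair r² values are
binned at 0.01 cM; a bin needs ≥ 100 pairs before it contributes its
99th-percentile threshold — a tail quantile from fewer pairs is noise — and
pairs falling in threshold-less bins can never be flagged (no
extrapolation beyond the covered distance range). Flagging is strict.

Calibration note: the exceedance probability of a fresh draw over an
empirical 99th percentile from m samples is ≈ (1 + 1/m)·1%, so thin bins
over-flag slightly; with ≥ 2,000 pairs per bin the held-out flagged
fraction sits within [0.005, 0.015] (verified on 10,000 held-out pairs
drawn from the same process as a 40,000-pair null).

## eQTL association

One OLS fit per (SNP, gene, tissue): design [1, dosage, covariates], p
two-sided from the t distribution of the dosage coefficient (fits are
delegated to statsmodels; tests verify them against closed-form normal
equations). Covariates — expression PCs, PEER factors, technical terms —
are consumed as given; re-deriving upstream normalization is out of scope.
Rank-deficient designs raise with the offending column named. The 10⁻⁸
genome-wide threshold is used verbatim with no further correction, and
dosage is the non-reference allele count so the effect sign is
per-non-reference-allele.

## Mendelian randomization

Instruments pass F = (b_X/se_X)² > 10 and p_X < 0.001, then greedy pruning
by ascending p_X removes any SNP with r² > 0.8 against an already-kept
SNP. With Ω_ij = se_{Y,i} se_{Y,j} ρ_ij:

* IVW: β̂ = (b_Xᵀ Ω⁻¹ b_X)⁻¹ b_Xᵀ Ω⁻¹ b_Y, se = √(b_Xᵀ Ω⁻¹ b_X)⁻¹ —
  fixed-effect by default (a random-effects option scales se by
  max(1, √(Q/(J−1)))); with ρ = I this reduces exactly to textbook IVW.
* MR-Egger: GLS of b_Y on [1, b_X] with weight Ω⁻¹; the intercept tests
  directional pleiotropy (two-sided normal), and when p < 0.05 the
  combined report marks IVW unreliable and foregrounds Egger.
* Weighted median: ratio estimates b_Y,j/b_X,j with weights
  ∝ (b_X,j/se_Y,j)², estimate at the 0.5 crossing of the centered
  cumulative weight with linear interpolation between adjacent ratios; SE
  by parametric bootstrap (default 1,000 draws) resampling b_X and b_Y
  from their stated errors. It deliberately ignores ρ: it is run as a
  sensitivity test on the pruned, weakly correlated set, which is weaker
  than a fully correlation-aware median.

Estimators are scale-agnostic; standardizing exposure and outcome (SD
units) is the caller's responsibility. The PheWAS arithmetic is the one
computation retained from that analysis: α divided by the summed category
counts, e.g. 0.05/(90+11+603+62+11) = 6.44×10⁻⁵ over 777 tests.

## Synthetic generators: what they emulate, and what they do not

* **Balding–Nichols** (`sim_balding_nichols`): per population and site,
  allele frequency ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F), genotypes
  Binomial(2, freq) — known F, Hardy–Weinberg within populations,
  independent sites. No LD, no shared drift topology across populations.
* **Neutral windows** (`sim_neutral_windows`): a standard coalescent per
  window (pairwise coalescence at rate k(k−1)/2), Poisson mutations at
  rate θ/2 per unit branch length, infinite sites, uniform positions; no
  recombination within a window and full independence between windows,
  matching the 1 Kb window scale of the analysis. Defaults for
  calibration: n = 50 chromosomes, θ = 10.
* **Sweeps** (`sim_sweep_panel`): constructive, not a forward simulation —
  derived carriers copy one founder haplotype with per-site probability
  fidelity^(d/decay) (defaults 0.99 per 100 bp over 201 sites at 100 bp
  spacing), ancestral haplotypes are independent background draws. It
  forces the haplotype-length asymmetry iHS detects without claiming
  sweep realism; allele-frequency trajectories, recombination and
  demography are not modelled.
* **Balanced clusters** (`sim_balanced_cluster_panel`): window SNP folded
  frequencies tightly clustered around the core's (signal) or drawn from
  a ~1/f neutral folded spectrum (control). Sites are frequency-assigned
  independently — no genealogical correlation.
* **LD pairs** (`sim_ld_pairs`): two-locus haplotype frequencies solved so
  the expected r² hits a target (D = ±√(r²·p(1−p)q(1−q)), feasibility
  checked), 2N haplotypes drawn i.i.d., paired into diploids. The
  background profile decays exponentially in cM with a heavy-tailed
  multiplier; planted pairs get r² far above their bin's background.
  Pairs are mutually independent, unlike real windows where pairs share
  SNPs.
* **Expression** (`sim_expression`): dosage effects + standard-normal
  covariates with known coefficients + Gaussian noise. No counts, no
  library-size structure, no hidden confounders beyond the declared
  covariates.
* **MR** (`sim_mr_dataset`): true instrument effects uniform on
  [0.2, 0.5] with random sign; b_X observed with N(0, se_X²) error,
  b_Y = β·γ + intercept + MVN(0, Ω). Weak-instrument bias is negligible
  at the default se_X = 0.02.

Because each generator isolates exactly the structure its stage assumes,
passing tests demonstrate correctness and calibration of the estimators —
not robustness to the confounders real cohorts add (population
stratification in eQTLs, phasing error in iHS, ascertainment in summary
statistics).

## Problem sizes and budgets

Default validation runs: 2,000 + 2,000 coalescent windows for the Tajima
null calibration (two-sided outlier rate 0.03–0.07 accepted around the
nominal 0.05, binomial + threshold-estimation noise); 40,000-pair uLD
nulls with 10,000 held-out pairs; 500 neutral β cores; 60-replicate sweep
and balanced-core panels; 200 replicates for eQTL unbiasedness and MR
recovery/coverage; 200–500 random instances per estimator-vs-oracle
check. The full test suite runs in well under a minute; the acceptance
script in ~15 s.

## Known limitations

* The uLD matched-window search anchors candidates at gene starts;
  sliding or tiled anchoring would find different (overlapping) null
  windows. Sensitivity to anchoring is testable but not explored here.
* iHS edge handling (skip, don't truncate) means cores near panel
  boundaries or in long homozygosity tracts produce no score.
* Genetic-map extrapolation clamps to the end cM values, so distances
  outside the map collapse to zero — flagged as a divergence risk when
  comparing against tools that extrapolate the terminal rate.
* The external replication on real cohort data (the filtered
  61,739-SNP/2,157-individual cohort; 8.1% vs 4.7% flagged-pair fractions
  for the two clusters) needs the public 1000 Genomes phase 3 genotypes,
  Ensembl v87 annotation and population genetic maps (hours of download
  and compute). The procedure is exactly the CLI chain in the README
  (`uld` with L = 430 Kb, k = 6, per-subpopulation maps); it is not part
  of the test suite.
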