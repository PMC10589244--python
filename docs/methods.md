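# Methods

## The pyroptosis potential index

The index summarizes, per sample, how strongly a curated set of pyroptosis
regulator genes is expressed relative to the rest of the transcriptome. The
catalog is directional: 46 positive regulators (inflammasome sensors and
adaptors, inflammatory caspases, gasdermins, effector cytokines and
granzymes) and 12 negative regulators. The curators' prose states a total of
57 genes while enumerating 58 distinct symbols; the package ships the
enumerated lists verbatim and documents the discrepancy in the catalog
docstring rather than guessing which symbol to drop (CD274/PD-L1, which
appears both as a positive regulator and as a checkpoint gene, is the likely
ambiguity).

Each direction is scored with single-sample GSEA. Within one sample, genes
receive ranks 1..N (1 = lowest expression; ties share average ranks).
Walking genes in decreasing rank order, the score accumulates the difference
between a rank-weighted in-set ECDF and the uniform out-of-set ECDF:

    P_in(i)  = Σ_{set genes at positions ≤ i} r^α / Σ_{set genes} r^α
    P_out(i) = #{non-set genes at positions ≤ i} / (N − |set|)
    ES       = Σ_{i=1..N} [P_in(i) − P_out(i)]

- **α (rank-weight exponent), default 0.25.** The documented default of the
  standard single-sample implementation; α = 0 gives unweighted steps.
  Configurable.
- **Normalization, default on.** Each set's ES column is divided by the
  range (max − min) of that set's scores across the samples of the run.
  Whether to subtract raw or normalized scores is genuinely open — the index
  is defined simply as a difference of two enrichment scores — so both are
  exposed; the default subtracts normalized scores (per direction), and the
  antisymmetry property (swapping directions negates the index exactly)
  holds in raw mode, where no cross-sample coupling exists.
- ES depends on expression only through within-sample ranks, so any strictly
  monotone per-sample transform (normalization, log scale changes) leaves
  raw scores unchanged. Missing values are rejected at validation, never
  imputed.

## Cohort statistics

- **Tumor vs normal.** Wilcoxon rank-sum per cancer type, exact null for
  combined n ≤ 20 without ties, normal approximation with continuity
  correction otherwise; paired analysis uses the signed-rank test on
  within-patient differences with zero differences dropped.
- **Grouping.** Within each cancer type, samples strictly above the median
  (or mean) PPI form the high group; samples exactly at the threshold go
  low, which keeps the rule deterministic. The trimmed design keeps the
  ceil(0.3·n) highest and lowest samples. Strata with a resulting group
  smaller than 2 are skipped and logged; the scans always continue past
  skipped strata so drops are auditable.
- **Survival.** Two-group log-rank test (deaths pooled at tied times;
  delegated to lifelines) on the dichotomized groups, and a univariate Cox
  proportional-hazards model on the continuous score. The Cox fit is
  written in-package: 1-D Newton iteration on the Breslow partial
  likelihood (Breslow chosen as the simplest well-defined tie convention),
  with the covariate standardized internally for stability and the
  estimate rescaled. A coefficient escaping |β| > 50 flags monotone
  likelihood (perfect separation) and returns no estimate. Survival times
  of zero are shifted to 0.5 days to keep the first risk set well defined;
  negative times are rejected. Both hazard ratios — group-based (log-rank
  side) and continuous — are computed and labeled, since either reading of
  "association with survival" is defensible.
- **Multiple testing.** Raw p-values drive the conventional p < 0.05 star
  annotation; Benjamini–Hochberg-adjusted values are always reported
  alongside, adjusted within each endpoint (survival) or variable family
  (association scans).

## Enrichment

Between high- and low-PPI groups, genes are ranked by signal-to-noise
(mean_high − mean_low)/(sd_high + sd_low) with each sd floored at
max(0.2·|group mean|, 0.2) — the classic desktop behavior that stops
near-constant genes from exploding the metric. Ties in the metric break by
gene symbol so ranked lists are reproducible.

Gene-set enrichment uses the weighted Kolmogorov–Smirnov running sum
(hit increment |metric|^p / Σ_hits |metric|^p with p = 1, miss decrement
1/(N − hits)); the ES is the signed maximum deviation from zero, with exact
ties resolving positive. Significance comes from a **gene-label permutation
null** — once only a ranked list is retained, sample-label permutation is no
longer possible — with 1000 permutations by default and a mandatory seed:

- NES divides the observed ES by the mean |null ES| of matching sign.
- The permutation p is the +1-smoothed tail proportion among matching-sign
  nulls. Matching-sign conditioning is what makes null p-values uniform on
  (0, 1): against the pooled two-sided null, a statistic compared to the
  tail of its own sign would concentrate below ½.
- FDR is the GSEA-style ratio of null to observed tail proportions over the
  pooled sign-normalized distributions, clipped to [0, 1], then made
  monotone by a BH-style running minimum from the least extreme |NES|
  upward, so a more extreme set never carries a larger FDR.
- Null scores are computed from sorted hit positions only (the extrema of
  the walk occur adjacent to hits), which makes the permutation engine
  O(k log k) per permutation and lets identically sized sets share a null.

Over-representation analysis is the upper-tail hypergeometric test per
annotation set against a stated universe, BH-adjusted across sets.

## Associations, TMB, drug response

Correlations are Spearman by default (Pearson for checkpoint genes and
cell-line drug response); for n ≤ 9 complete pairs the Spearman p-value is
exact, from exhaustive enumeration of all n! pairings. Missing values are
pairwise-deleted per test.

TMB counts rows whose MAF variant classification falls in the documented
nonsynonymous vocabulary (Missense/Nonsense/Nonstop, Frame_Shift_Del/Ins,
In_Frame_Del/Ins, Splice_Site, Translation_Start_Site) divided by the
exome size — 38 Mb by default, a common whole-exome convention, exposed as
a parameter since only the per-Mb definition is fixed. Unknown
classification strings are excluded with a QC count; samples absent from
the table score 0. Mutation frequency counts each sample once per gene
(nonsilent rows by default, configurable).

Tumor/normal expression ratios back-transform the log2(x+1) input to the
linear scale before averaging, then report log2 of the mean ratio; a zero
normal-tissue mean receives a 1e-9 pseudocount and a flag.

Drug-sensitivity prediction is a deliberately simple, fully documented
pipeline: intersect genes between the cell-line panel and the tumor matrix
(floor 200 shared genes), z-score each matrix independently per gene
(dropping constant genes), then fit a ridge regression of IC50 on the
homogenized expression per drug. The penalty is chosen by seeded 10-fold
cross-validation over 10^{−3..3} in half-decade steps. Model metadata
(penalty, genes, training n, seed) is recorded with every prediction so the
output is not mistaken for the more elaborate transfer-learning tools used
on real panels (power-transformed IC50, empirical-Bayes batch adjustment),
which are out of scope. Orientation is stated everywhere: lower IC50 =
more sensitive.

ESTIMATE and CIBERSORT are consumed as precomputed per-sample score tables;
their internal algorithms are cited tools, not part of this package.

## Synthetic cohorts

The generator emulates the shapes and couplings the analysis assumes: a
log2(FPKM+1)-like expression matrix (per-gene means ~ N(4, 1.5) clipped at
0, per-sample noise sd 1.0 — typical between-sample spread on that scale)
containing the packaged catalog symbols plus background genes; clinical
tables with four survival endpoints; a MAF-like mutation table; immune and
molecular score tables; and a 60-line cell-line panel.

Every tumor sample draws a latent activation a ~ Uniform(0, 1) (normals:
a = 0) — uniform rather than binary so the index behaves as a continuous
score while binary recovery metrics remain available by thresholding.
Couplings, all driven by a:

- positive regulators shift by +δ·a (δ = 1.5 log2 units by default),
  negative regulators by −κ·δ·a (κ = 1);
- survival is exponential with log-hazard β·a (β = 0.8 by default, sign
  configurable per stratum) with independent exponential censoring whose
  rate is calibrated to the requested marginal censoring fraction (0.3);
- immune scores and three planted cell fractions (CD8 T cells, M1
  macrophages, Tregs) increase additively in a; tumor purity decreases;
  stemness and MSI decrease mildly; fractions are renormalized to stay on
  the simplex;
- per-drug IC50 decreases in the line's activation (slope 1, noise 0.5);
- immune subtypes C1–C6 threshold a with 10% label noise.

All randomness flows from one seed through `SeedSequence` spawning, so each
block regenerates independently and two runs are bitwise identical. The
latent activation is stored for recovery tests only and never consumed by
an analysis stage.

What the generator does **not** emulate: batch structure and platform
effects, gene–gene correlation beyond the planted sets, realistic survival
shapes (a single exponential), copy-number/methylation modalities, and
tumor subclonality. Passing tests therefore demonstrate that the machinery
recovers the statistical structure it assumes, not that the biological
conclusions transfer to any real cohort.

## Problem sizes and numerical conventions

The test and acceptance workloads use cohorts of 60–300 samples with
200–1500 genes, 10 simulation seeds for recovery metrics, 100–200
replicates for calibration checks, 1000 permutations for GSEA, and a
50-gene/60-line panel for ridge recovery — sizes at which every planted
effect is comfortably detectable while the whole battery runs in seconds.
Oracle comparisons are asserted at 1e-9 (running sums) or 1e-12 (closed
forms); Newton iteration stops at |Δβ| < 1e-10 with a 100-iteration cap.
Degenerate inputs (constant vectors, empty groups, zero-event strata,
all-zero paired differences) are skipped with logged reasons or flagged in
the output rather than silently dropped.
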