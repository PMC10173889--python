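# Methods

This note documents the statistical machinery, the synthetic study it is
exercised on, and the design decisions taken where the published
operating points leave the implementation open.

## Rank-aggregation meta-analysis

Each activation dataset contributes two ranked lists (up- and
downregulated genes, ordered by signed log2 fold-change; ties break on
gene id so rankings are reproducible).  Differential expression behind
the ranking is deliberately simple — CPM on raw library sizes, Welch
t-test on log2(CPM+1) with a pseudocount of 1, BH across genes — because
the aggregation consumes only fold-change *ranks*, which are robust to
the choice of test.  TMM-style composition correction is omitted: the
synthetic generator does not create composition bias, and a precomputed
differential-expression table can be substituted wherever a `DETable` is
accepted.

The aggregation score for a gene with sorted normalized ranks
r₍₁₎ ≤ … ≤ r₍ₙ₎ over n lists is ρ = min₍ₖ₎ P(Beta(k, n−k+1) ≤ r₍ₖ₎);
the per-gene p-value is min(1, ρ·n) (Bonferroni over the choice of k,
the published default of the robust-rank-aggregation algorithm).
Normalized rank is position / universe size *of the contributing
dataset* — lists from different datasets may have unequal universes.  A
gene absent from a list contributes normalized rank 1 (no evidence).

Stability averaging: the aggregation is repeated once per leave-one-out
subset of the lists; the **corrected** p-value is averaged over the
repeats (averaging the raw ρ instead is available via `score="rho"`),
and the averages are BH-adjusted across genes.  The consistency filter
keeps genes at FDR ≤ 0.05 appearing in the given direction in at least
two-thirds (inclusive boundary) of the datasets in which they were
*detected*, where detection means presence in the dataset's tested gene
table, not membership in a direction list.

Null behaviour: on uncorrelated permutations the corrected p-values are
conservative (stochastically ≥ uniform), so the realized false-positive
rate at FDR ≤ 0.05 is far below 5%; the calibration tests check the ≤ 5%
bound.

## ChIP TSS-window annotation

Coordinates are BED conventions throughout: 0-based, half-open.  The
distance from a peak to a TSS is 0 if the interval covers the TSS and
otherwise `min(|start − tss|, |end − 1 − tss|)` — the nearest *covered*
base.  A gene is bound in a dataset when that distance is ≤ the window
(default 10 kb, inclusive boundary, symmetric around the TSS since the
rule is direction-free); whole intervals are used, not summits.
`min_tss_distance` is the most proximal peak over all datasets.  The
direct-target rule requires binding in ≥ 5 datasets overall including
≥ 1 Nutlin-class and ≥ 1 non-Nutlin-class treated dataset; treatment
class is dataset metadata, never inferred from content.  Group
comparisons of binding metrics use the one-sided Wilcoxon rank-sum test
(exact null for tie-free totals ≤ 25, tie-corrected normal approximation
otherwise).

## Multi-omics regression networks

Expression filters: an mRNA enters the model when ≥ 75% of samples have
normalized expression ≥ 1 (both boundaries inclusive); a lncRNA when its
median is > 0 and its 90th percentile is > 0.1 (strict inequalities,
linear-interpolation percentiles).  When a promoter carries several
methylation probes, the representative is the probe whose β-values have
the most negative Spearman correlation with the mRNA's expression;
constant probes are skipped, and if none is usable the methylation term
is omitted for that mRNA (degrees of freedom adjust accordingly).

Each retained pair is fit by OLS of mRNA expression on
[1, DM, CNV, lncRNA]; the lncRNA coefficient's two-sided t-test p-value
(n − 4 df) is BH-adjusted across **all pairs tested in the cancer
type**.  Expression enters untransformed by default (the cohort bundle
documents its scale); a log2(x+1) switch is provided.  The production
scan uses a Frisch–Waugh–Lovell residualization path (one QR per mRNA,
vectorized over lncRNAs) that is tested equal to the per-pair OLS to
1e-8.  Significant pairs (FDR < 10⁻³) split by coefficient sign into
each lncRNA's positive and negative sets, ordered by (FDR ascending,
|β| descending, gene id) and truncated to the top 200 a side — the
published top-200 rule does not state a sort key, so this one is fixed
here.

## Dependency-screen GSEA

Screens score every gene per cell line; lower scores mean stronger
dependency.  For enrichment the genome is ordered score-descending, so
the bottom of the list holds the strongest dependencies.  The running
sum increments by |score|^p (p = 1 by default; p = 0 supported for
exact small-case tests) normalized by the set's total weight at hits
and decrements by 1/(N − |set|) at misses; ES is the signed maximum
deviation, with magnitude ties resolved to the positive extreme.  The
permutation null draws random gene sets of matched size (1000 by
default, seeded); NES divides ES by the mean |ES| of same-sign
permutations, p-values use the same-sign permutation tail (ties counted
as extreme), and the batch FDR follows the standard pooled-null
pre-ranked procedure across all sets scored together.  A set whose null
has no same-sign ES receives p = 1/(n_perm + 1).

Classification per (lncRNA, cell line): *suppressive* iff only the
negatively associated set has NES < 0 at FDR ≤ 10⁻³, *oncogenic* iff
only the positive set, *excluded* iff both, *unclassified* otherwise —
exhaustive and mutually exclusive.

## Cohort statistics

The p53-LOF test is a per-lncRNA Welch t-test (LOF vs WT expression);
the one-tailed "downregulated in LOF" p-value (lower t tail) feeds
Fisher's combined probability across cancer types: −2Σln p ~ χ²(2k)
under the null.  The tail direction is configurable; zero p-values are
clamped to the smallest positive float (BH-adjusted zeros occur in
floating point) rather than erroring.

The survival scan splits samples at the median expression (ties to the
low group, deterministically), then runs the standard two-group log-rank
O−E tabulation with hypergeometric variance at each distinct event time.
The Z-score is (O_low − E_low)/√V, signed so z > 0 means the low group
has more events than expected; the feature is then *favorable* (high
expression → better survival).  |z| > 1.96 — the two-sided normal
critical value at α = 0.05 — flags significance.  z² is the usual
log-rank chi-square (verified against an independent tabulation oracle
to 1e-9 and against lifelines).  Constant features are skipped with a
logged reason; median splits depend only on ranks, so the scan is
invariant under monotone transforms of expression.

## Synthetic study

The generator plants truth in every layer; all generators are pure
functions of (config, seed), with per-stage seeds derived by stable
CRC32 hashing of stage names so stages are independently reproducible.

* **Annotation** — genes on a 100 kb TSS grid with ±10 kb jitter across
  22 chromosomes, so distinct genes never share a 10 kb window and peak
  attribution in tests is unambiguous.
* **Activation counts** — negative binomial parameterized by mean and
  dispersion (variance μ + φμ², φ = 0.1), baseline means log-normal
  around 100, library sizes log-normal (sd 0.3) to exercise
  normalization.  Planted targets' treated means shift by 2^2 (default
  effect 2 on the log2 scale).  Defaults: 14 datasets, 4 treated + 4
  control samples each.
* **ChIP peaks** — treated datasets place a 50–150 bp peak uniformly
  within 900 bp upstream of each target TSS (strand-aware) with
  probability 0.9; every gene receives background peaks near its locus
  (±50 kb) at rate 0.02; control datasets are background-only.
  Defaults: 7 Nutlin-class + 7 non-Nutlin-class + 3 control peak sets.
* **Cohorts** — mRNA expression follows the regression model exactly
  (β₀ = 8, β_DM = −2, β_CNV = +1, planted β_lnc = ±1.5, Gaussian noise
  sd 1); methylation β-values in [0,1] with 3 probes per promoter of
  which exactly one tracks the true promoter methylation (so probe
  selection has a unique right answer); CNV scores are integers in
  {−2…2}.  lncRNA contributions enter mean-centered so a gene targeted
  by several lncRNAs keeps its baseline and still passes the expression
  filter — only the intercept is reparameterized, the slopes are the
  planted coefficients.  p53-LOF samples (fraction 0.3) have target
  lncRNA expression multiplied by 0.5 (a free parameter, not an
  empirical value).  Survival is exponential with administrative
  censoring at a fixed horizon — the simplest model that exercises the
  log-rank scan; hazard multipliers apply per standardized unit of
  lncRNA expression, and the helper
  `per_unit_multiplier_for_group_hr` converts a desired median-split
  group hazard ratio (the gap between median-split halves of a normal
  covariate is 2√(2/π) sd) into the per-unit multiplier.
* **Dependency screens** — growth-promoting genes (the union of the
  planted negative association pools) score N(−3, 0.5), everything else
  N(0, 0.5), per cell line and screen type (RNAi-like and CRISPR-like,
  20 lines each by default).

What the generator does *not* emulate: read-level artifacts and mapping
bias, composition/batch effects, copy-number segmentation structure,
probe chemistry, competing risks, and correlated lncRNA co-expression
modules.  Passing recovery tests therefore demonstrates that the
statistical chain is implemented correctly and calibrated under its own
model assumptions — not that those assumptions hold in any particular
real dataset.

## Problem sizes and numerical choices

The default study (2,000 genes / 200 lncRNAs / 40 targets, 14 activation
datasets, 17 peak sets, 3 cohorts of n = 300, 2 × 20 dependency screens)
was chosen as the smallest scale at which every stage operates in its
intended regime — enough datasets for the two-thirds rule to bind,
enough samples for the regression FDR < 10⁻³ to be reachable, enough
cell lines for the cross-line summary.  Null calibrations use 2,000-gene
permutations, 100-sample regressions and 500-feature survival scans.

Degenerate inputs are handled explicitly rather than propagated: all-zero
count genes get p = 1 via the pseudocount; constant expression features
are skipped (survival) or flagged with p = 1 (LOF test); constant
methylation probes are excluded from selection; a peak chromosome absent
from the annotation is skipped with a warning.  Ties break
lexicographically everywhere a total order is needed (rankings, probe
ids, dependency ranks), and the GSEA ES sign tie-break (positive on
magnitude ties, tolerance 1e-12) is part of the documented convention.
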