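# Methods

This note documents the models and procedures implemented in `cscmosaic`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish.

## Population definitions

All populations are called from a genes × cells TPM matrix after gene
filtering: a gene is kept when its mean TPM across all cells exceeds 0.2
**and** it is expressed (TPM > 0, the only unambiguous notion of
non-expression) in at least 30 cells.  The two rules are applied jointly;
applying them sequentially gives the same result.

A population is the top fraction *f* of cells under a ranking score, with
`k = ⌈f·N⌉` members (default f = 0.02; 0.02 × 1091 = 21.82 → 22 — ceiling
never under-selects, and matches the published group size).  Boundary ties
are broken toward the lexicographically smallest cell id so calls are
deterministic.  The seven populations are:

- **SCC** — ranked by the lipid-metabolism ssGSEA score;
- **FCC** — ranked by CCS = G1S + G2M module scores (raw sum, no rescaling);
- **CD133 / SOX2 / PTPRZ1 / ITGB8 / CD44-high** — ranked by the marker
  gene's expression.  Cells must express the marker (TPM > 0) to be
  eligible; if fewer than k cells do, the call errors rather than padding
  with zero-expressers, since "highest expression" is meaningless among
  zeros.

Group homogeneity is screened by the max/min ratio (MMR) of the within-group
ranking scores: a group is flagged when its MMR falls outside the Tukey
box-plot fences (type-7 quartiles, 1.5 × IQR) of the MMR distribution across
groups.  Flags are reported, not auto-applied; an optional mode
(`shrink_to_homogeneous`) iteratively drops the weakest member of each
flagged group until no flags remain.  A single group is never flagged
(outliers are undefined for n = 1).

## Signature scoring

**ssGSEA.**  Per cell, genes are ranked by expression (average ranks for
ties; the most expressed gene has rank G) and walked in decreasing order
with stable gene-index tie-breaks.  In-set genes step the running sum up by
`rank^α` normalized over in-set weights; out-of-set genes step down by
`1/(G − |S|)`; the score is the sum of the running-sum difference over all
positions, making it a pure function of ranks (hence invariant to any
strictly monotone per-cell transform).  Defaults α = 0.25 with min–max
normalization across cells, the common single-sample-enrichment defaults;
both are exposed because the upstream analysis does not pin them.

**Cell-cycle module scores.**  On log2(TPM+1), all genes are ordered by mean
expression and split into 25 equal-occupancy bins; each program gene draws
100 control genes from its bin (with replacement when the bin is smaller),
and a cell's score is the mean program expression minus the mean over the
pooled controls.  This cancels cell-wise depth/complexity effects: a global
shift of the matrix changes nothing because bins, controls and both means
shift together.  CCS is the plain sum of the G1S and G2M scores.

## Overlap decomposition

Set arithmetic over group memberships is exact: pairwise intersection
counts, private cells (members of exactly one group — the cohorts used for
differential expression), per-cell membership lists, and the Combo_CSC
group of cells simultaneously high for at least two of the five markers,
each annotated with its marker pairs.  Both the raw shared fraction
(relative to the smaller group) and the Jaccard index are reported for each
pair, since published overlap percentages can refer to either.

## Differential expression

Moderated t on log2(TPM+1) (log-scale data is what the empirical-Bayes
variance model assumes, and a fold-change cutoff of ±2 reads naturally as
log2 units): per gene, `logFC = mean_A − mean_B`, pooled residual variance
s² with d = |A|+|B|−2 degrees of freedom, and posterior variance
`(d₀s₀² + d·s²)/(d₀ + d)`.  The prior (d₀, s₀²) comes from method of
moments on the log sample variances: the excess variance of
`log s² − ψ(d/2) + log(d/2)` over the trigamma term determines d₀ by
Newton inversion of the trigamma function (tolerance 1e-8, ≤ 100
iterations, d₀ capped at 1e6); when there is no excess spread the cap
applies and the prior scale is the geometric-mean variance, so the
moderated t collapses to the ordinary pooled-variance t.  p-values use a
t distribution with d₀ + d df, Bonferroni-adjusted over the tested genes;
a DEG requires adjusted p < 0.005 and |log2 FC| > 2.  Genes with zero
sample variance in both cohorts have no defined statistic and are reported
with p = 1 and a flag.  DEG cohorts are the private cells of each group.

Companions: variance-ranked variable-gene selection (ties by gene id);
PCA on centered (optionally scaled) genes with the sign of each component
fixed by its largest-magnitude loading; agglomerative clustering
(average/complete linkage, Euclidean/correlation distance) with Newick
export; row z-scores with sample sd (constant rows become zeros with a
warning); and two-sided Wilcoxon rank-sum comparisons of a reference
group's scores against each other group, normal approximation with tie and
continuity correction (exact enumeration under a flag for n ≤ 10),
Bonferroni over comparisons.  Cells shared with the reference are removed
from the comparator so the two samples are independent.

## Bulk deconvolution and survival

The signature matrix selects, per population, genes over-expressed versus
all other populations (one-vs-rest moderated t, Bonferroni q < 0.01,
positive logFC, up to 200 genes by t); profiles are mean TPM over the
selected union.  Bulk samples are scored by **non-negative least squares**
against the profiles.  The published analysis used an external
deconvolution service in absolute mode; NNLS is this package's deliberate
methodological substitution — it preserves the absolute-mode contract
(non-negative, scale-carrying scores: multiplying a sample by c multiplies
its scores by c) while being fully inspectable and testable.  Batch
correction and quantile normalization are not performed anywhere in the
module.  Per-sample significance is the fraction (with +1 smoothing) of
100 gene-label permutations of the bulk vector whose refit matches the
permuted data at least as well as the real fit.

Samples are stratified high/low around the mean score (median available;
ties go low), and the strata are compared by Kaplan–Meier estimation and
the two-group log-rank test (hypergeometric variance with tie correction,
two-sided p from the chi-square(1) tail; deaths processed before
censorings at tied times).  Both are delegated to `lifelines` behind the
module's validated interface.  Records censored at time 0 are dropped as
uninformative.  Survival-time units are dataset metadata; the module is
unit-agnostic.

## Drug-target enrichment

The ranking statistic is the moderated t of a DEG contrast.  The
enrichment score is the signed maximum deviation of the weighted KS
running sum (hits weighted `|t|^p` normalized, default p = 1; misses
`1/(G−|S|)`); with p = 0 it reduces to the classic unweighted KS
statistic.  The null is **gene-label** permutation (1000 draws): the small
group sizes (≤ 22 cells) make phenotype permutation too coarse, a
documented deviation from phenotype-permutation GSEA.  NES divides ES by
the mean same-sign null magnitude; FDR follows the positive/negative NES
pooling procedure (Benjamini–Hochberg over permutation p-values available
by flag).  Sets are called toward one side at FDR < 0.05.  Reproducing the
published 13 drug identities requires the proprietary December-2021
drug-target snapshot and is out of scope; a planted-truth recovery test
stands in.

## Synthetic data: what it emulates and what it does not

The generator draws baseline TPM from log-normal(meanlog 0, sdlog 1),
plants +3 log2 multiplicative effects on a 50-gene lipid program (22 SCC
cells), on 43 G1S + 54 G2M genes (22 FCC cells — the Tirosh list sizes),
and a +6 log2 boost of the marker gene in each 22-cell marker-high group
(markers use a tighter sdlog 0.5 baseline, emulating the bimodal on/off
expression of surface markers), then renormalizes every cell to a constant
TPM sum of 1e6.  The 2000-gene space is a scaled-down transcriptome chosen
to keep the full pipeline fast while leaving programs a small minority of
genes.  Pairwise population overlaps are realizable as disjoint shared
blocks (no cell in three populations); the deterministic
`printed_overlap_fixture` uses exactly the published pairwise counts,
whose private counts then follow arithmetically (privates = 22 − pairwise
shares).

Bulk samples are `f·profile_SCC + (1−f)·profile_FCC` with per-gene
multiplicative log-normal noise (sd 0.2, 50 samples, f ~ Uniform(0,1));
survival times are exponential with hazard `h₀·exp(β·f)` (h₀ = 1/365,
β = 1.5) and non-informative censoring: with probability 0.2 a subject is
censored at a uniform fraction of its event time.

Not emulated: dropout/zero-inflation, batch effects, gene–gene correlation
beyond the planted programs, and realistic library-size variation.
Passing tests therefore demonstrate correctness of the algorithms and
calibration of the statistics under clean planted structure — not
robustness to scRNA-seq technical noise.

## Numerical choices and limitations

- Quartiles everywhere use linear interpolation (type 7).
- All randomness flows through seeded `numpy.random.Generator` instances;
  every generator is a pure function of (config, seed).
- Ties: average ranks in scoring; lexicographic cell ids at selection
  boundaries; smallest item index in clustering merges.
- The MMR-based group-size refinement is an interpretation (iterative
  shrink by one member, re-checking); the original appendix procedure is
  not public.
- Calibration suites use scaled-down problem sizes (200-gene null
  matrices, 200 subjects per survival arm, 100–500 replicates), the
  package's own balance of precision against runtime.
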