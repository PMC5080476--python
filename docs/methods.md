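# Methods

## Model

For each modeled gene g, expression across the n tumor samples is regressed
on a gene-specific design matrix X_g with columns

- `CNV` — the gene's continuous copy-number value (GISTIC-like, centered at
  0); values are used as-is, not thresholded into calls;
- `METH` — Beta-values of the methylation probe mapped to g whose Spearman
  correlation with g's expression is most negative (the correlation type is
  configurable; Spearman is the default because rank correlation is used
  throughout the evaluation);
- one column per TF and per miRNA whose binding bit for g is 1 (promoter
  motif hit for TFs, 3′UTR site for miRNAs). Columns are exact copies of the
  regulator-expression rows — the binding matrix gates which regulators are
  *eligible*, and the forest decides which matter.

The learner is a random forest: `ntree` CART regression trees, each grown on
a bootstrap resample of the samples (with replacement, size n), choosing the
best variance-reducing split among `mtry` features drawn uniformly at each
node. Defaults `ntree = 100`, `mtry = 70` (capped at the gene's feature
count — most genes have far fewer than 70 features, in which case splits are
effectively unrestricted), `min_node_size = 5` (the conventional regression
default). Tree growing is delegated to scikit-learn's
`DecisionTreeRegressor`; bootstrapping, OOB bookkeeping and importance are
implemented here so their semantics are explicit:

- **OOB prediction** for sample i is the mean prediction of trees whose
  bootstrap excluded i (~36.8% of trees in expectation). Samples never out
  of bag (probability (1 − 1/e)^ntree ≈ 1e-20 at 100 trees) are excluded
  from OOB metrics. Accuracy is the Spearman correlation of aggregated OOB
  predictions with measured expression — aggregated predictions, not
  per-tree correlations, following standard OOB practice.
- **Permutation importance** is per-tree: for each tree, each feature's
  values are permuted among that tree's OOB samples and the increase in that
  tree's OOB MSE recorded; importance is the mean increase over trees and
  over `importance_repeats` permutations (default 5). The raw (unscaled)
  ΔMSE is reported; permuting a constant feature gives exactly 0, and pure
  noise features may come out slightly negative.

Per-gene seeds are derived as SHA-256(master seed, gene id) mod 2³¹, so
per-gene results are independent of gene order and of subsetting.

## Regulator ranking and target inference

Within each gene, importances become fractional ranks (rank 1 = largest,
ties averaged); the defined ranks of a gene with m features always sum to
m(m+1)/2, which is asserted in tests. A feature's **average rank** is taken
over the genes where the feature is present. Averaging over *bound genes
only* is the single most consequential interpretation choice: treating
absence as a worst rank would conflate binding coverage with importance, so
coverage is instead reported separately as `support`, and features with
support below `min_support` (default 10) are excluded from the ordering to
stop one-gene features topping the list by chance. The ordering is invariant
to gene order and to any within-gene monotone transform of importances.
TFs and miRNAs are ranked in one global ordering with a class annotation,
not within class. All ties break lexicographically by id.

Targets of a regulator r are the genes where r attains its best within-gene
ranks (ascending rank, ties by gene id, top min(k, available), default
k = 500). Overlap with an experimental list is the intersection of the two
top-k sets, with a hypergeometric tail p-value on (universe, k, k, overlap).

## Differential expression

Paired tumor/normal counts go through: a low-count filter (a gene is dropped
iff its count is below `min_reads` = 4 in strictly more than 70% of samples;
the miRNA variant uses `min_reads` = 2 — both thresholds read literally and
strictly); TMM normalization (reference = library whose scaled upper
quartile is closest to the mean; two-sided trimming of 30% on M and 5% on A;
inverse-variance-weighted mean of the retained log-ratios; factors rescaled
to geometric mean 1); and a per-gene negative-binomial GLM likelihood-ratio
test of the tumor indicator with patient fixed effects and log effective
library sizes as offsets, fit by IRLS (statsmodels GLM), with p-values from
χ²(1) and log₂FC = tumor coefficient / ln 2 (tumor relative to normal).
Non-converging genes are flagged with p = 1. Benjamini–Hochberg adjusts the
p-values, and genes are labeled up/down by strict thresholds |log₂FC| > 1,
FDR < 0.05.

Dispersion is estimated per gene by maximizing the Cox–Reid adjusted profile
likelihood — the NB log-likelihood penalized by −½ log det(XᵀWX) — over a
bounded log-dispersion range, then shrunk toward the pooled mean with a
fixed prior weight of 0.25 and floored at 1e-8. The CR adjustment matters
here: plain moment estimators are biased low when ~half the degrees of
freedom go to patient effects (measured median α̂ ≈ 0.16–0.18 at a true 0.2
in a 20-pair design), which inflates the null rejection rate to 7–9%; with
the CR estimate the measured null type-I error is ~0.054 at α = 0.05 with
uniform null p-values. No mean–dispersion trend or empirical-Bayes
moderation is attempted — per-gene + fixed-weight pooling is deliberately
the simplest estimator that is calibrated under the paired design. DE status
is treated as annotation and an upstream gene filter, never as a feature
filter on regulators.

## Motif scanning

JASPAR-format PFMs (parsed with Biopython) are converted to log₂-odds PWMs:
column counts plus a pseudocount of 0.1 distributed by the background
composition (uniform by default), normalized and divided by background. The
null score distribution of a background word is computed *exactly*: column
scores are discretized to a 1e-3-bit lattice and convolved position-wise
into a PMF (total mass 1 within 1e-9), whose survival function gives the
p-value of any window score. At motif lengths ≤ 30 the discretization error
(≤ L·1e-3 bits) is negligible against the 1e-4 site threshold; tests verify
exact agreement with 4^L enumeration on the same lattice and bracketing of
the real-score enumeration. Windows are scored on both strands (minus-strand
hits reported at their forward-strand offset), windows containing N are
skipped, and a site is kept iff p < 1e-4 (strict). The binding matrix sets
bit (r, g) = 1 iff at least one site survives — idempotent under duplicate
hits. Promoters are the ±`flank` window around the TSS (default 2000,
i.e. 4000 nt — the superset of an "upstream-only" or "downstream-only"
reading), 0-based half-open, reverse-complemented for minus-strand genes,
truncated with a warning at chromosome ends. miRNA binding matrices are
ingested as precomputed inputs, not computed (site prediction in 3′UTRs is a
different problem).

## Survival

Samples split at the median of the candidate driver's expression; values
equal to the median go to the low group (a documented, configurable
convention). Kaplan–Meier curves and the two-group Mantel–Haenszel log-rank
test come from lifelines; tests pin the product-limit identity without
censoring and a hand-tallied 4-observation table (χ² = 8/13). Only KM +
log-rank are offered — no Cox model, no optimal-cutpoint search.

## Synthetic cohort: what it emulates, and what it does not

`generate_cohort` draws TF and miRNA expression and CNV as Gaussians,
methylation Beta-values as logistic-transformed Gaussians (3 probes per
gene, one causal, so probe selection is exercised), and binding bits as
i.i.d. Bernoulli(`binding_density`), forced to 1 for planted
(regulator, target) pairs. Expression follows

    baseline_g + cnv_effect·CNV + meth_effect·Beta(causal probe)
      + Σ_r β_{r,g}·f_r(expr_r) + N(0, noise_sd²)

with β nonzero only for planted pairs, miRNA effects strictly negative
(repression), TF effects of either sign, and a `hinge_fraction` (default
0.3) of TF effects passed through max(0, x − median) so the forest's
nonlinear capacity is actually exercised. Defaults — 200 genes × 150
samples, 40 TFs (5 active), 40 miRNAs (3 active), density 0.10, |β| in
[0.8, 1.5] on the log₂ scale, cnv_effect 0.5, meth_effect −2, noise 0.5,
30 targets per active regulator — are chosen so that regulator signal
dominates noise roughly as in a well-powered cohort while background-bound
regulators remain plentiful enough to measure false-positive behavior.
Companion generators produce NB paired counts (dispersion 0.2, lognormal
library and patient-baseline factors; tumor means shifted by the planted
log₂FC), knockdown-style p-value tables (targets ~ Beta(a, 1), a small;
non-targets uniform), exponential survival times with the planted driver
multiplying the hazard above its median expression, and background
promoters with consensus sites planted at recorded offsets. One master seed
feeds fixed per-generator substreams, so every artifact regenerates
bit-identically.

What the generator does *not* emulate: read-level sequencing noise, ChIP-seq
peaks, platform merges, batch effects, correlated binding structure
(bits are i.i.d.), regulator–regulator correlation, or feedback between
regulators and targets. Passing the recovery tests therefore shows the
pipeline recovers planted additive/hinge effects under NB and Gaussian
noise — not that it would resolve collinear regulators or confounded real
cohorts.

## Numerical and design choices

- Strict inequalities wherever a threshold is stated ("greater than 1",
  "less than 1e−4", "less than 4 reads in more than 70%").
- Forest features are never standardized (forests split on order), and OOB
  Spearman of a constant vector is defined as 0 with a flag.
- Wilcoxon signed-rank (ablation vs full model) uses the normal
  approximation with tie correction; identical paired vectors return p = 1.
- The Wilcoxon/ablation, tuning and recovery evaluations all reuse the same
  derived per-gene seed so full and reduced models differ only in columns.
- Hyperparameter tuning minimizes mean OOB MSE over a gene sample, ties
  toward smaller ntree then smaller mtry.
- `infer_targets`/`average_feature_ranks` tie-breaks are lexicographic for
  reproducibility; rank matrices store absences as NaN, never as a rank.
- Evaluation problem sizes used by the test-suite and the acceptance script:
  recovery runs use the default 200 × 150 cohort over 10 seeds with 2
  importance repeats; null calibration uses 2000 (suite) or 1000 (script)
  genes at 20 pairs; log-rank calibration uses 1000 (suite) or 500 (script)
  generator seeds; survival power uses 100 seeds at n = 200.

## Known limitations

- The NB pipeline is not an edgeR replica: no trended or empirical-Bayes
  dispersion moderation, no quasi-likelihood F-test; exact per-gene results
  will differ even though thresholds and the test family match.
- The average-rank statistic favors regulators bound to many genes; support
  is reported but not modeled.
- Importance dilution: duplicated/correlated causal features split their
  importance, a property of permutation importance itself (checked
  directionally in tests).
- The exact-PMF scanner assumes an i.i.d. background; no higher-order
  background models, and no q-values (the binding matrix needs only the
  fixed p threshold).
- KM/log-rank handle right-censoring only, with no tied-time corrections
  beyond those lifelines applies.
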