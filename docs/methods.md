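# Methods

This note documents the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Preprocessing

Inputs are gene × sample tables of raw or RSEM-style normalized counts
(tab-separated, genes as rows; the matrix is transposed to samples ×
features only at model-fitting time). Genes with a zero fraction *strictly
greater* than `max_zero_fraction` (default 0.25) across the supplied
samples are removed before any log transform; the boundary case (exactly
25% zeros) is retained. The log2 transform uses a configurable pseudocount
(default +1, mapping 0 → 0); the pseudocount is a package choice, since a
bare "log2 transform" of counts is undefined at zero. Zero filtering only
operates on pre-log scales, and a second log2 transform is refused rather
than silently compounded. `harmonize_genes` restricts a collection of
tables to their common gene set in sorted order.

## One-vs-rest differential expression

The DE engine is a compact negative-binomial Wald test, not a DESeq2
re-implementation: the selection algebra downstream needs fold-change
rankings with a sensible significance filter, and a clean NB Wald supplies
exactly that while remaining fully testable against simulation truth.

* **Normalization.** Median-of-ratios size factors (reference = per-gene
  geometric mean over genes positive in every sample), rescaled to
  geometric mean 1; total-count fallback with a warning when no gene is
  everywhere-positive. Normalized (non-integer) inputs are rounded to
  integers before fitting, mirroring common practice for expected counts.
* **Dispersion.** NB parameterized as var = μ + αμ². Per-gene α is a
  method-of-moments estimate from within-group residual variance of
  normalized counts (accounting for the per-sample 1/s Poisson term). The
  default `trended_shrink` method fits a trend α(μ) = a₁ + a₀/μ by least
  squares with one round of outlier trimming, then averages gene and trend
  estimates in log space with the trend carrying 50 pseudo-degrees of
  freedom — per-gene moments at typical group sizes are noisy enough that
  the trend should dominate. `per_gene_mom` disables shrinkage. Dispersions
  are floored at `alpha_floor` (1e-8).
* **Test.** log2FC = log2 of the ratio of size-factor-normalized group
  means; group means are floored at 0.5/n_group normalized counts so the
  estimate stays finite when a group is all-zero. The delta-method standard
  error uses Var(group mean) = (μ·mean(1/s) + αμ²)/n; the Wald statistic
  log2FC/SE is referred to a standard normal, and p-values are BH-adjusted
  within each one-vs-rest run (the runs for different target classes are
  treated as independent analyses). Independent filtering, outlier
  refitting and LFC shrinkage are deliberately omitted.

On simulated null NB data (20 vs 20 samples, α = 0.1, 2000 genes) the test
is close to nominal (type-I error ≈ 0.05 at the 0.05 level; the acceptance
script recomputes this) and planted log2FC = 2 effects are recovered with
mean absolute error well under 0.3.

## Panel construction

For each class the DE records are filtered to `p_adjusted ≤ 0.05`
(configurable, disable with `None`) and to positive log2FC, then sorted by
signed log2FC descending with ties broken by smaller p-value and then gene
id; the first k genes form S_i. The positivity filter is a deliberate
design choice: a class marker is a gene *over-expressed in* the class, and
on small gene universes an unfiltered signed sort lets significantly
*down-regulated* genes (typically other classes' markers) pad a short
list, which then evicts those genes from their own difference sets. With
the filter, short lists stay short instead of filling with anti-markers.

D_i removes from S_i every gene present in any other class's list; the
panel U concatenates the D_i with classes in lexicographic order and genes
in within-class rank order, so downstream feature indices are
reproducible. Disjointness of the D_i and |U| = Σ|D_i| are asserted on
every build. An empty U raises with advice rather than returning a
degenerate panel.

## Classifiers

All three models consume log2(normalized count + 1) features restricted to
U, samples × features.

* **OvR logistic regression** — one binary L2-penalized logistic model per
  class, fitted by scikit-learn's SGD on z-scored features (zero-variance
  features dropped with a warning). Defaults: lr 0.01 with inverse-scaling
  decay, L2 1e-4, ≤1000 epochs, tolerance 1e-5; deterministic per seed.
  Prediction evaluates the stored weights directly (sigmoid per class,
  per-sample normalization to sum 1, which cannot change the argmax), so a
  JSON round trip reproduces predictions bit-exactly.
* **MLP** — input → 128 sigmoid units → softmax over classes,
  cross-entropy, SGD (lr 0.001) with weight decay, fitted by scikit-learn;
  the forward pass is re-implemented from the serialized weights. The
  default epoch budget (500, with plateau-based early stopping) is far
  below a production 10k-epoch run and is sized for desk-scale problems;
  raise `MLPConfig.epochs` for full training. The training-loss trajectory
  is retained in the model for inspection.
* **k-TSP** — for each unordered class pair, every ordered gene pair (i, j)
  gets P_ij^C = fraction of class-C samples with V_i < V_j (strict
  inequality; ties count against), ΔP = |P¹ − P²|, with a secondary score
  equal to the between-class difference of mean within-sample rank gaps;
  the top pairs are selected greedily under gene-disjointness. Each binary
  classifier votes by pair majority (internal ties resolved by its
  top-ΔP pair); the final label maximizes votes with ties broken by summed
  ΔP, then lexicographically. The greedy-disjoint rule and rank-gap
  tie-break follow the classical k-TSP literature. Everything is rank-based,
  hence invariant to strictly monotone per-sample transforms.

## Evaluation

Per-class precision/recall/F1 derive one-vs-rest from the confusion
matrix; a zero denominator yields an explicit `None` (excluded from
macro-F1 with a reported exclusion count) rather than a coerced zero,
which matters for rare classes. Stratified folds (scikit-learn, per-class
counts within 1 across folds, deterministic per seed) default to 5; 10 is
a config value away. The k-grid search refits the *entire* pipeline — DE,
panel, classifier — inside every training fold; the label-permutation
control in the acceptance suite verifies the resulting estimates sit at
chance when labels are shuffled, i.e. that no selection leakage exists.
Selection maximizes pooled accuracy with smallest-k, then lexicographic
tie-breaks.

## Interpretation

The explained output is the raw per-class linear score (not the normalized
probability): for a linear model with an independence/interventional value
function the Shapley value is exactly w_j·(z_j − z_bg,j), so attributions
are deterministic and satisfy local accuracy to machine precision. The
background defaults to the training feature means and is configurable.
Per-class importance averages |SHAP| over samples whose *true* label is
the class. The beeswarm export bins each feature's values into rank-based
terciles (group sizes within 1) for plotting by any external tool; no
rendering is bundled.

## Simulator

`simulate_dataset` draws per-gene baseline means 2^U(low, high) (default
(3, 9): means 8–512, typical mid-expression genes), per-sample depth
multipliers lognormal(0, σ = 0.15), and NB counts with a single global
dispersion (default 0.1, a realistic bulk RNA-seq value). Each class owns
`markers_per_class` genes whose mean is multiplied by 2^log2FC in samples
of that class; markers are strictly up-regulated, matching the panel's
positivity convention. Defaults (10 classes × 60 samples, 2000 genes, 20
markers/class, log2FC 2) define the package's standard study conditions.

Sibling pairs emulate histologically related tumor types. At overlap
fraction f, a designated pair shares round(f·m) marker genes outright,
and — because relatedness in real tumors is graded, not binary — each
sibling also expresses its partner's remaining markers at f·log2FC. The
second mechanism is what makes the phenomenon observable: the
set-difference algebra removes from both difference sets every gene that
climbs into both siblings' top-k lists, so the pair's mutual information
shrinks and held-out errors concentrate almost exclusively between the
siblings (≈50 errors between siblings vs ≤3 between any other pair at
f = 0.5 under the standard conditions), while all other classes remain
near-perfectly classified. With identity-sharing alone, the residual
disjoint markers at log2FC 2 keep the pair perfectly separable and no
confusion structure exists to observe.

What the simulator does *not* model: batch effects, platform mixing,
FFPE degradation, metastatic drift, correlated gene modules, or per-gene
dispersion heterogeneity (optional hooks exist for the latter). Passing
tests therefore demonstrate correctness of the algebra, the statistics and
the pipeline's discipline (no leakage, determinism) — not performance on
real cohorts.

## Problem sizes and determinism

The bundled experiments run at the standard study conditions above
(single-digit minutes on one CPU in total; the DE stage is fully
vectorized). All randomness flows from explicit seeds; CLI JSON artifacts
are written with sorted keys and no timestamps, so identical inputs and
seeds give byte-identical outputs, and every artifact embeds a provenance
block (seed + parameters).

## Known limitations

* The NB Wald test's calibration degrades for very small groups (< ~10
  samples per side) and very low counts, where the normal reference for
  the Wald statistic is optimistic.
* The strong trend-shrinkage of dispersion can over-smooth datasets with
  genuine per-gene dispersion heterogeneity; switch to `per_gene_mom` at
  the cost of noisier p-values.
* OvR sigmoid scores are normalized for reporting but are not calibrated
  probabilities.
* k-TSP's ΔP treats expression ties as "not less than"; on heavily
  zero-inflated data many pairs tie at zero and the secondary rank score
  drives selection.
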