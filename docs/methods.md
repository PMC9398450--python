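# Methods

This note records the models implemented in `trophonet`, the choices made
where the procedure was underdetermined, and what the synthetic-data
generators do and do not emulate.

## Interface construction

Differential expression between the two receptivity phases is per-gene
one-way fixed-effects ANOVA. With two groups this reduces to the F-form
of the two-sample t-test; it is implemented for general k so multi-group
contrasts work. Significance is strict p < alpha (default 0.01) with no
multiple-testing correction — the construction is a discovery filter,
not an inference, and downstream steps (localization, interaction,
expression) act as orthogonal filters. Expression is log(1+x)-transformed
before the F-test so bulk RNA-seq values are roughly homoscedastic; the
transform is switchable. Degenerate genes (zero variance within and
between groups) are flagged and never called significant; zero
within-group variance with distinct means is the F → ∞ limit and is
called significant with p = 0.

Two under-specified points, both config-exposed:

* "Expressed in Day 6 TE" → detected (count > 0) in ≥ 10% of the cells of
  the relevant subset. 10% is the common single-cell detection heuristic;
  the filter's purpose is only to drop partners with no evidence of
  presence.
* The localization refinement is applied to both sides of the interface
  with the same four admissible terms (extracellular space, extracellular
  matrix, proteinaceous extracellular matrix, cell surface), since only
  surface or secreted products can span the embryo–uterus interface.

## Hypernetworks

For interface genes S and transcriptome T over a chosen cell subset, the
correlation matrix is Pearson on log(1+x) counts (Spearman available).
Pearson-on-log is the minimal reading of "correlation matrices" that is
robust to single-cell count skew. The incidence threshold is
|r − mean(r)| > m·SD(r) with m = 1, both tails, where mean and SD are
computed per analysis (polar and mural each get their own) over all
entries excluding self-pairs; self-pairs are forced to 0 in M so a gene
cannot count itself as a shared connection. Note that a ±1 SD rule keeps
roughly the strongest ~30% of correlations by construction; the
statistic's meaning comes from *sharing*, not from the marginal keep
rate.

H = M·Mᵀ. The central cluster is the denser branch of a two-way cut of
the average-linkage tree (Euclidean distance between H rows): the branch
with the higher mean off-diagonal H value wins, ties going to the larger
branch and then to the branch whose first member sorts lexicographically
first. Linkage, distance and cut were not dictated; average linkage on H
rows is the simplest rule that reliably isolates a planted module in
simulation (exactly recovering the planted 11- and 21-gene memberships at
default generator settings), and all three pieces are arguments.

Connectivity is the multiset of off-diagonal H entries over unordered
within-cluster pairs. Organization is the Shannon entropy (bits) of those
pair weights normalized to sum 1; zero-weight pairs contribute nothing,
and a zero-total cluster has undefined entropy (NaN). Because entropy
scales with log2(#pairs), absolute values are not comparable across
clusters of different size; the headline quantity is therefore the
*relative* entropy, observed minus the median of a permutation null.

The null redraws gene sets of the interface-set cardinality (39 by
default) uniformly from the nonzero-variance transcriptome and reruns the
entire pipeline — correlation, binarization, H, cluster extraction,
metrics — so observed and null numbers are computed identically. It is
fully reproducible from its seed. One behavior worth knowing: the null's
connectivity distribution is right-skewed, because a random draw that
happens to contain a few mutually correlated genes (e.g. members of any
strong co-expression module in the data) can yield a small, tight central
cluster with a high pairwise mean. Observed-vs-null percentile
comparisons are therefore only sharp when the structure of interest is a
small fraction of the transcriptome; the subset-vs-subset comparison
(polar vs mural) is the robust contrast and is the one emphasized.

The rank-sum comparison is an in-house Wilcoxon/Mann-Whitney: exact
enumeration of all C(n, n_a) assignments when n_a + n_b ≤ 12 without
ties, else the normal approximation with tie correction and continuity
correction. It is cross-checked in the tests against both
`scipy.stats.mannwhitneyu` and a Monte-Carlo permutation oracle.

Connected gene sets (for external enrichment) default to transcriptome
genes incident to ≥ 1 central-cluster gene; an "all cluster genes" mode
is available.

## Shadow-feature random forest

The STB-classifier question — do interface genes discriminate TSC from
STB transcriptomes (n = 4 + 4)? — is answered with an iterated
shadow-feature (Boruta-style) procedure. Per iteration: every gene gets a
shadow copy with independently permuted sample values; a bagged forest of
decision trees (default 300, mtry = √p) is fit on the augmented matrix;
importance is Breiman's permutation importance — the mean per-tree drop
in out-of-bag accuracy when the feature's column is permuted. Two details
matter at n = 8:

* **Out-of-bag evaluation is essential.** On training samples, a tree
  that split on a shadow also degrades when that shadow is permuted, so
  shadows are indistinguishable from real features. On OOB samples a
  shadow-split tree predicts at chance either way, while a tree using an
  informative gene loses real accuracy.
* **Per-tree evaluation keeps correlated informative genes visible**:
  each tree that used the gene degrades even when the ensemble vote is
  rescued by correlated siblings.

A gene scores a hit when its importance exceeds the best shadow's. Hits
over n_iterations are tested two-sided against Binomial(n, ½) with
Bonferroni over genes: significantly many → confirmed, significantly few
→ rejected, else tentative (kept as its own category, not forced). The
per-iteration Z-score retained for plotting is importance divided by the
iteration's best-shadow importance (an eps-guarded noise floor).

Known limitation: with only eight samples, a shadow permutation aligns
with the class partition by chance with probability ≈ 2/70 per bimodal
feature, so a fraction of iterations contain a genuinely predictive
shadow. This caps the hit rate of even perfectly separating genes well
below 1 and makes confirmation conservative at small iteration counts;
genes whose realized group separation is modest tend to end tentative
rather than confirmed. The forest size (default 300 trees) stabilizes
importance estimates; iteration count defaults to 1000 with ≥ 100
recommended for desk-scale runs.

Status mapping onto the interface table: confirmed → yes, rejected → no,
tentative → nd (ran, undecided), gene absent from the contrast →
nd_not_expressed, never run → nd.

## Velocity display transform

The transform is f(v) = sign(v)·ln(1+|v|) — the signed
logarithm, continuously extended to f(0) = 0 — rather than the literal
product v·|v|·ln(1+|v|), which would inflate rather than compress
magnitudes and defeat the purpose of a display transform. The literal
form is available behind a flag. f is odd, strictly monotone and
contractive (|f(v)| ≤ |v|). Heatmap rows are ordered by average-linkage
clustering of transformed profiles; an all-tied matrix keeps input order.
Columns are grouped by (day, subset), stable within blocks. Velocity
estimation itself is out of scope — values are consumed, not inferred.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
with ground truth recorded for every planted element; they do not try to
match any real dataset gene-by-gene.

* **Receptivity bulk** (default 2000 genes, 4 + 4 samples): log-normal
  baseline (log-mean ~ N(3, 1)), within-group log-SD 0.5; planted DEGs
  shift by effect_sd × 0.5 log units with random sign (default
  effect_sd = 5, at which per-gene ANOVA power at alpha 0.01 is ≈ 0.99).
* **Day 6 TE single cells** (default 2000 genes, 86 polar + 245 mural
  cells, mirroring the study's subset sizes): a per-cell latent factor
  drives module genes with loading √ρ on the log-rate scale (signal
  amplitude 1.2, measurement noise SD 0.1), counts are
  Poisson(exp(log-rate)). The within-module correlation of latent
  log-rates is exactly ρ; Poisson noise and the measurement term
  attenuate the observed log-count correlation by
  A²/(A² + σ_noise² + E[1/λ]) ≈ 0.96 at the default module expression
  level (λ ≈ 50). Module membership mirrors the packaged interface
  table's cluster structure: 11 interface genes in the polar-analog
  module, 21 in the
  mural-analog, 7 shared, plus 40 background module genes; ρ defaults to
  0.8 (polar) vs 0.4 (mural), reproducing the directions of the
  subset comparison (higher polar connectivity, lower polar relative
  entropy). Sparsity (fraction of zeros, ~0.27 at defaults) is reported
  in the truth record.
* **Interaction graph**: one-to-one true edges from planted EEC surface
  DEGs to planted TE interface genes (optional same-symbol self pairs),
  plus decoy edges among non-planted genes.
* **TSC/STB bulk** (4 + 4): as receptivity, with a planted informative
  subset shifted by effect_sd × 0.5 (default effect_sd = 3).
* **Velocity**: day-increasing signed velocities of magnitude ~amplitude
  for dynamic genes, near-zero noise elsewhere; day 5 cells are
  unassigned, days 6 and 7 have polar and mural blocks.

Every generator is bitwise reproducible from its seed; the pipeline
derives all stage seeds from one master seed through fixed offsets
(`pipeline.STAGE_OFFSETS`), making a result bundle reproducible from its
config alone.

What passing tests on these data do *not* show: robustness to empirical
single-cell artefacts (batch effects, dropout beyond Poisson sparsity,
cell-cycle structure), to annotation errors in the localization table, or
to the literature bias of curated interaction databases. The planted
module is a single latent factor; real co-expression has overlapping
modules at many scales, which in particular makes permutation nulls
heavier-tailed than a single-module simulation suggests.

## Problem sizes

Default test and acceptance runs use the study-scale dimensions
(39 interface genes, 86/245 cells, 4 + 4 bulk samples) with 100–200
permutations/iterations for the resampling stages; the full 1000 of both
is the package default for real analyses. Calibration checks shrink the
transcriptome (500–3000 genes) — every size is a parameter.
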