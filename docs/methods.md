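# Methods

This note documents the statistical machinery implemented in `ebmeta`, the
choices made where the design was genuinely open, and what the bundled
synthetic data can and cannot establish.

## Classification pipeline

The unit of analysis is a `ProfileDataset`: a nonnegative sample × feature
abundance matrix in one namespace (taxonomic, KEGG ortholog, eggNOG
orthologous group) with per-sample metadata (project id, condition, a
comorbidity flag). The binary task is always healthy (0) vs CRC (1);
probabilities are P(CRC).

Fitting proceeds in four stages, all learned on training rows only:

1. **Log transform.** Elementwise `log(1+x)`. Abundances are heavily
   right-skewed; the transform keeps zeros at zero and compresses the tail.
2. **Univariate screening.** Per-feature one-way ANOVA F-test (equivalent to
   the two-sample t on two groups), Benjamini–Hochberg FDR control, keep
   features with q ≤ α = 0.05. Constant features get p = 1. An empty
   selection raises `EmptySignatureError` rather than silently falling back —
   a silent fallback would corrupt the stability statistics downstream;
   `select=False` bypasses the stage explicitly, and the evaluation loops
   record an empty-selection split as an undefined (NaN) score.
3. **Discretization.** Equal-frequency (quantile) bins per feature: 2 for
   taxonomic profiles (mostly a presence/absence split at the median), 20 for
   functional ones. Tied quantiles collapse, so the realized bin count can be
   smaller; a cut at the column maximum is dropped (it would create an empty
   top bin, and for a constant column this collapses to a single bin), while a
   cut at the minimum is kept because it isolates the zero mass of sparse
   features. At prediction time values outside the training range are clamped
   into the first/last bin.
4. **EBM.** The additive classifier described next.

In o-LOPO mode an externally supplied feature mask replaces stage 2 verbatim.
This is a deliberate, documented information leak (the mask is computed on the
pooled data) that makes the design comparable to reference meta-analysis
methodologies which pre-select features on the joined dataset.

## Explainable boosting machine

The model is `logit P(y=1|x) = β₀ + Σⱼ fⱼ(xⱼ)` with one shape function per
feature over its discrete bins. Training:

* initialize β₀ to the log-odds of the base rate and all graphs to zero;
* per epoch, visit features round-robin; for feature j compute the current
  probabilities p, and update each bin b of its graph by
  `lr · Σ_{i∈b}(yᵢ − pᵢ) / Σ_{i∈b} pᵢ(1 − pᵢ)` — the Newton (hessian-weighted)
  per-bin step, i.e. the standard gradient-boosting leaf value for the
  logistic loss. Because features arrive pre-binned, this *is* the depth-1
  tree on that feature. Empty bins receive no update;
* after the last epoch, re-center every graph to zero mean under the training
  bin distribution, folding the shifts into β₀.

The Newton step was chosen over the plain per-bin residual mean because it has
the same fixed point — per-bin empirical log-odds in the single-feature limit,
which the tests verify against the closed-form saturated MLE — but contracts
geometrically at rate (1 − lr) per epoch, so the model is numerically converged
at the default budget; the plain-mean step contracts only at rate
(1 − lr·p(1−p)) and would still be ~1% away after thousands of epochs.

Defaults: learning rate 0.01, 2000 epochs, no bagging (available behind
`n_bags`). The round-robin schedule with a small learning rate spreads credit
nearly evenly across collinear features (duplicated features end up with
graphs equal to within ~lr in relative terms) instead of letting the first one
absorb the effect. The test suite and the bundled examples use lr 0.1 with
200 epochs, which is past convergence for the shallow per-bin updates at the
bundled data sizes; the slower default is the conservative choice for unknown
data.

Local attribution of sample s on feature j is `fⱼ(bin(s,j))`; attributions plus
β₀ reproduce the logit to machine precision (asserted at 1e−10). Global
relevance is the mean |attribution| over the training set; it is nonnegative
and zero iff the graph is flat.

## Validation designs

* **Repeated CV** — stratified k-fold (default 10-fold, 20 repeats), screening
  and binning refit inside every training fold; k is reduced with a warning if
  the minority class is smaller than k. Reported as mean plus 0.25/0.75
  quantiles of per-fold AUROCs.
* **Cross-dataset matrix** — cell (r, c): train on project r, test on project
  c; diagonal: the project's CV mean; optional LOPO and o-LOPO rows.
* **LOPO / o-LOPO** — hold out each project, train on the union of the rest.
  Each run also records its global-relevance vector over the *full* feature
  space (zeros for unselected features) for signature building.

AUROC is the Mann–Whitney probability that a random positive outranks a random
negative, ties counted ½. Cells where the test set lacks a class are reported
as NaN (serialized as JSON null), never imputed as 0.5, so averages of matrix
summaries are not biased toward chance.

## Stability estimation

Selection stability uses the Nogueira estimator on the M × d binary selection
matrix Z across splits:

```
Ŝ = 1 − mean_f s_f² / ((k̄/d)(1 − k̄/d)),   s_f² = M/(M−1) p̂_f (1 − p̂_f)
```

with p̂_f the selection frequency of feature f and k̄ the mean number selected
per split. Ŝ is 1 for identical subsets, ~0 for uniformly random selection,
and can be negative (two disjoint selections give −1). The confidence interval
comes from the estimator's asymptotic normality, with variance
`(4/M²) Σᵢ (φᵢ − φ̄)²`,

```
φᵢ = [ mean_f(Z_if p̂_f) − kᵢk̄/d² + (Ŝ/2)(2kᵢk̄/d² − kᵢ/d − k̄/d + 1) ] / denom,
```

taken from the estimator's source publication. The conventional agreement
thresholds 0.4 / 0.7 are echoed in the result object for reporting. The
estimator is undefined when every split selects nothing or everything; this
raises.

Rank stability compares the relevance vectors of all split pairs with the
hyperbolic-weighted Kendall tau: exchanges between items at ranks r and s cost
w(r) + w(s) with w(r) = 1/(1+r), so disagreements at the top of the ranking
dominate and the long uninformative tail (many near-zero relevances) barely
contributes. The statistic is symmetrized by averaging over which vector
indexes the weights and normalized so self-agreement is 1 and exact reversal
−1 (implemented via `scipy.stats.weightedtau`, which is exactly this
statistic; the tests check it against an independent exhaustive weighted-pair
enumeration). Tied scores — common at the zero tail — are resolved by the
exchange-counting itself: pairs tied in both vectors are neither concordant
nor discordant. Reported as the mean over all M(M−1)/2 pairs with 0.25/0.75
quantiles.

Splitting schemas: RSSS (default 100 random class-stratified half splits;
stratification prevents degenerate one-class training halves) or the training
folds of the repeated CV (larger training sets, same estimators).

## Consensus signature and permutation significance

Each LOPO run's relevance vector is min-max rescaled to [0, 1] (relevances are
nonnegative with minimum typically exactly 0, so this coincides with division
by the maximum); the consensus score of feature i over p runs is
`Σ_runs rescaled_i / (p − nz_i + 1)` where nz_i counts runs with relevance
strictly above a configurable epsilon (default 0 at machine precision).
Features screened out in a run contribute 0 to that run, so a feature selected
everywhere with maximal relevance scores p and one selected in a single run is
divided by p — the divisor rewards cross-cohort recurrence. The score is
invariant to run order and monotone in any run's relevance.

Significance of the validation score on the signature support uses label
permutation: the pipeline (screening bypassed, features fixed to the support)
is scored once with true labels and B times with shuffled condition labels;
`p = (#{perm ≥ observed} + 1)/(B + 1)`. "Greater or equal" with add-one
smoothing is the only reading consistent with the attainable extremes — with
B = 100 the worst p is exactly 1 and the best 1/101 ≈ 0.0099. The score is
the mean AUROC of a repeated stratified CV on the pooled samples (default
10×10-fold, configurable up to the 100×10 schema) or, alternatively, the mean
o-LOPO AUROC; CV is the default because rescoring the full o-LOPO loop B times
is an order of magnitude more expensive for the same decision.

Metabolite scores sum the consensus scores of the KEGG orthologs mapped to
each compound (user-supplied two-column TSV); orthologs absent from the
signature contribute 0.

## Adenoma risk-ordering test

Per repeat: the non-comorbid healthy/CRC samples of the pooled dataset are
split 0.7/0.3 (stratified) into learning and validation; everything else —
adenomas, small adenomas, `other`, comorbid CRC — forms the test set. The
pipeline is fitted on the learning set only, and P(CRC) is predicted for
validation ∪ test. One-sided Mann–Whitney tests then compare group
distributions; healthy and tumor probabilities are taken from the *validation*
split, so every compared group is unseen by the model. Default comparisons
(radar-plot axes): A < T, H < A, H < S, S < A, H < T, where T denotes
validation CRC. The direction of the healthy/small-adenoma comparison is
genuinely ambiguous in the source material; `ComparisonSpec` makes every
direction explicit rather than hard-coding one. The Mann–Whitney p-value uses
exact enumeration for combined n ≤ 12 without ties and the normal
approximation with tie correction otherwise.

Hit ratios are fractions of repeats (default 100) with p < 0.05. A repeat
where a group is empty is skipped for that comparison with the denominator
adjusted. Note that repeats re-partition the *same* cohort: the adenoma test
set is identical in every repeat, so repeats are correlated and the
per-cohort hit ratio of a genuinely null comparison has substantial
cohort-level variance around α. Claims about the α-level behavior of a null
comparison should therefore be averaged over independent cohorts, which is how
the test suite checks them.

## Synthetic data generator

The generator emulates the structure that motivates the analysis: several
projects with project-specific batch offsets, zero-inflated skewed abundances,
one low-depth cohort, and a small planted signal set. Feature j in sample i:

```
a_ij = B_ij · exp(μ_j + b_{p(i),j} + log e_{c(i),j} + ε_ij)
```

with μ_j ~ N(0, base_log_mean_sd), b_{p,j} ~ N(0, batch_sd),
ε ~ N(0, noise_sd), B_ij ~ Bernoulli(1 − zero_inflation), and e the condition
multiplier on the n_signal signal features (1 for null features). Everything
is drawn from one seeded generator; the same seed reproduces the dataset
bitwise.

Defaults (chosen once as the package's study conditions): 7 projects × 60
samples (25 healthy / 25 CRC / 5 adenoma / 5 small adenoma), 500 features, 30
signal, base_log_mean_sd = 1.0, batch_sd = 0.3, noise_sd = 1.0 (all on the
natural-log abundance scale), zero_inflation = 0.3. Condition multipliers
double per stage — functional mode 1 / 2 / 4 / 8 for healthy / small adenoma /
adenoma / CRC, taxonomic mode 1 / 1 / 1 / 8 — reflecting the
near-order-of-magnitude enrichment reported for flagship CRC biomarkers and,
in functional mode, a graded shift of functional activity along the
progression; a 2-fold effect on this scale is essentially invisible to a
per-project univariate screen after log1p compression and 30% dropout and
would describe a different (much harder) study than the one the downstream
analyses assume. Effects are applied to a single nested signal set, so the
adenoma signature is a weakened CRC signature — the structure the risk-ordering
test requires. Project 1 is the low-depth cohort: values scaled by
depth_factor = 0.5 and dropout raised to 0.55. The degradation is deliberately
mild because the upstream profile pipelines are depth-normalized, so low
sequencing depth manifests mostly as extra dropout of low-abundance features
rather than as a raw global rescaling; its expected library size is still the
smallest of all projects.

What the generator does *not* emulate: compositional (sum-to-one) coupling
between features, correlated feature blocks (co-occurring taxa or linked
pathway members), overdispersed integer counts, heterogeneous per-project
sample sizes and class ratios, and real batch structure beyond additive
per-feature log offsets. Passing tests on this testbed therefore demonstrate
that the machinery is correct and recovers planted structure under realistic
noise, skew, dropout and batch magnitudes — not that real cohorts will reach
the same scores; on real data cross-cohort transfer is far harder.

## Numerical conventions and degenerate inputs

* Reports serialize to JSON with a schema version; NaN ↔ null round trips.
* Undefined AUROCs (one-class test sets) and undefined CV folds are NaN.
* Selection mask is exactly `q ≤ α`; monotone in α.
* Unseen bins clamp to the nearest realized bin; unseen samples never
  influence fitted state (asserted by refit-identity tests).
* Seeds: every stochastic entry point takes an explicit seed; nested seeds are
  spawned with `numpy` SeedSequence semantics and stay below 2³¹.
* Test and example problem sizes (4–7 projects, 40–500 features, 150–200
  boosting epochs at lr 0.1, CV with 5 repeats, 100-repeat hit-ratio loops)
  are the package's chosen desk-scale defaults: large enough for every
  estimator to operate in its intended regime, small enough to iterate on.

## Known limitations

* Binary outcome only; no multiclass link, no pairwise interaction terms
  (the classical EBM extension), no survival endpoints.
* The F-test screen is marginal: jointly informative but marginally null
  features are invisible to it, and the stability statistics inherit that.
* The Nogueira CI is asymptotic in the number of splits; with very few splits
  it can overcover or undercover.
* `metabolite_scores` requires a user-supplied compound→ortholog map; no
  database access is attempted.
* Dense matrices throughout; profiles beyond ~10⁴ features × 10⁴ samples
  would want a sparse backend.
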