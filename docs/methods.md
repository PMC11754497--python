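# Methods

This note documents the statistical machinery implemented in `ocrnet`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Consensus signed co-expression network

For each cohort the similarity between genes *i* and *j* is the signed
weight `s_ij = (1 + cor(x_i, x_j)) / 2` (Pearson), mapped to an adjacency
`a_ij = s_ij^β`. The signed transform keeps positively and negatively
correlated pairs distinguishable before powering; the soft threshold β
(default 12, the standard choice for signed networks) suppresses weak
similarities so that strong co-expression dominates. A scan
(`pick_soft_threshold`) reports, per power, the fit of the connectivity
distribution to a power law (R² of log-frequency on log-connectivity over
10 equal-width bins, plus the slope sign) and returns the smallest power
reaching a target fit (default 0.75) with negative slope, falling back to
the best-fitting power with a warning. The pipeline keeps β fixed at 12;
the scan is diagnostic. Note that the packaged synthetic fixture — three
rank-1 modules over unstructured background — is *not* scale-free by this
measure at β = 12: its connectivity distribution is bimodal by
construction. The scale-free criterion describes real transcriptome
networks; the fit computation itself is verified on constructed power-law
input.

The adjacency is converted to the topological overlap matrix
`TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
`l_ij = Σ_u a_iu a_uj` and connectivity `k_i = Σ_u a_iu`, a similarity that
rewards shared neighborhoods and is more robust than raw adjacency. TOM is
*not* bounded below by the adjacency (a high-degree gene paired with a
low-degree neighbor can have overlap below their direct weight); the test
suite verifies the matrix against the elementwise definition rather than
asserting that folk bound.

Per-cohort TOMs are made comparable by full quantile normalization of their
off-diagonal upper-triangle entries: each cohort's sorted values are
replaced by the across-cohort mean of order statistics, with ties receiving
the average of the target values their positions span. The consensus TOM is
the component-wise **mean** of the calibrated TOMs. The component-wise
minimum — the conservative convention — is available via
`consensus_tom(..., operator="min")`, but the mean is the default here
because it is the stated operator of the workflow this package
re-implements.

### Module detection

Genes are clustered by average-linkage hierarchical clustering of
`1 − TOM`. Clusters smaller than `min_size` (default 30) are relabeled
"grey" (unassigned); surviving clusters are named along the canonical color
sequence (turquoise, blue, brown, …) by decreasing size.

The cut rule deserves explanation. Quantile calibration piles consensus-TOM
dissimilarities up just below 1 — on the packaged fixture the dendrogram
root sits at 0.9989 — so a *static* cut at the conventional height 0.999
returns a single all-gene cluster, while cuts anywhere in [0.95, 0.99]
recover the planted modules essentially perfectly. This is precisely the
regime dynamic tree-cutting was invented for, where 0.999 serves as a
*ceiling* on merges rather than a literal cut. `detect_modules` therefore
defaults to an adaptive rule: treating `cut_height` as a ceiling, it tracks
the number of clusters of size ≥ `min_size` along the merge sequence (a
single union-find pass; average-linkage heights are monotone) and places
the cut in the middle of the height interval over which that count is
maximal — the most stable rich module structure the tree exhibits. The rule
is deterministic, scale-free, and reduces to the obvious answer in
degenerate cases (an all-ones TOM yields one module; an undersized tight
cluster among noise ends grey). `method="static"` gives the literal
fixed-height cut. Optional eigengene-based module merging was considered
and omitted: on rank-1 synthetic modules it is a no-op, and it adds a
tuning parameter the rest of the pipeline never uses.

### Eigengenes and module membership

A module's eigengene is the first right singular vector of its standardized
(per-gene mean 0, sd 1) gene-by-sample block, unit norm, with the sign
chosen so the mean correlation with the module's genes is positive — making
results reproducible across platforms, since the SVD sign is otherwise
arbitrary. The explained-variance fraction is reported. Module membership
kME(g, m) is the Pearson correlation of gene *g* with eigengene *m* within
a cohort; the consensus kME is the unweighted mean across cohorts. Genes
with zero variance yield missing kME and are excluded from hub selection.

## Dual module filter and hub genes

Module relevance is tested twice, on the tissue cohort:

* **Survival:** one univariate Cox proportional-hazards fit per eigengene
  per outcome (overall and recurrence-free survival; Efron tie handling via
  lifelines), Wald p-values. A module passes if p < α (default 0.05) in
  *either* outcome. Fits are unadjusted at this stage; covariate adjustment
  belongs to the per-gene baseline.
* **Concordance:** Spearman correlation between the tissue and
  matched-organoid eigengenes of the module, paired by sample identifier;
  p < α required. For n ≤ 9 pairs an exact permutation p-value replaces the
  t-approximation.

No multiple-testing correction is applied at the module stage (an `fdr`
flag exists, default off): the number of modules is small and the two
filters are conjunctive, which already makes the null selection rate ≈ α²
per module (verified by simulation in the test suite). The concordance
threshold reuses the survival α because no separate value is specified in
the source workflow; its text reports module correlations with an "R²"
symbol while calling them Spearman correlations — whether the printed 0.7
is ρ or ρ² is ambiguous, so this package always reports plain ρ.

Hub genes are the members of selected modules with
|consensus kME| ≥ 0.5, boundary inclusive.

## Drug-response models

Trained on hub-gene expression (samples × genes) in the drug-response
organoid cohort against IC50, used as provided (a `--log-ic50` flag
log-transforms first; whether IC50 should be modeled on a log scale is left
to the user because the convention varies between assays).

* **Ridge:** genes standardized internally; the penalty λ minimizes the
  mean k-fold (default 3) cross-validated MSE over a 100-point log-spaced
  grid from a data-driven maximum (`max|Xᵀy|` on standardized data) down to
  10⁻⁴ of it; the final fit uses all data at the chosen λ, and coefficients
  are returned on the original expression scale. The solution path is
  computed by one SVD per fold (exactly `(XᵀX + λI)⁻¹Xᵀy`; verified against
  the closed form to 10⁻⁸). An elastic-net mixing grid is available
  (`alpha_grid`), default pure ridge.
* **Random forest:** bagged regression trees (default 500) with
  `mtry = ⌈p/3⌉` and a minimum leaf of 5. Bootstrap indices are drawn by
  the wrapper, not the tree learner, so out-of-bag sets are exact and the
  Breiman-style permutation importance — mean increase in OOB MSE over 10
  permutations per feature — is fully deterministic given the seed.
* **Ensemble:** genes with strictly positive OOB permutation importance are
  refitted by ridge; the ridge coefficients define the exported signature.
  If no gene has positive importance the ensemble refuses with an error
  suggesting the plain forest.

Candidates are compared by (a) repeated k-fold CV (folds redrawn per
repetition with seed `base + rep`; fold MSEs pooled into mean ± sd),
(b) the Mann–Whitney AUC of the tissue-cohort score against the
survival-event indicator (ties count one half; orientation: probability
that a deceased patient scores higher), and (c) the log-rank p of the
maxstat-dichotomized tissue cohort. Selection: restrict to log-rank-significant
candidates; prefer the one best on both CV error and AUC; if neither
dominates, rank by CV error with AUC as tie-break (warned); if none is
significant, fall back to the CV-error minimum (warned). The linear fit
uses an intercept internally for prediction, but the exported patient score
omits it — a constant shift cannot change maxstat groups or any rank-based
downstream statistic.

## Scoring and survival validation

`Score = Σ_i β_i · Exp_i` over the signature genes (forest models score by
predicted value). Cutpoints are maximally selected rank statistics:
candidates are midpoints between consecutive distinct scores whose split
keeps at least `minprop = 0.1` of the cohort on each side (the common
default; none is specified by the source workflow), the statistic is the
absolute standardized two-sample log-rank statistic, and ties go to the
smallest cutpoint. Patients with score ≥ cutpoint form the *resistant*
group (boundary resistant). Group survival is summarized by Kaplan–Meier
curves (censored subjects at an event time remain at risk for that event)
and compared by the two-sample log-rank test with the hypergeometric
variance under ties.

The log-rank p at the maxstat split is reported **raw**, matching the
practice this package mirrors. Because the cutpoint maximizes the very
statistic being tested, this p is optimistic under the null; the test suite
quantifies the inflation (null rejection well above α) rather than hiding
it, and cutpoints are re-estimated per cohort, never transferred.

## Baselines and enrichment

* Per-gene Cox fits of overall survival on each gene adjusted for age and
  sex; per-gene Spearman tests against IC50 and between paired
  tissue/organoid expression. Criterion 1 keeps genes with all three
  p < 0.05; criterion 2 additionally requires the survival log hazard ratio
  and the drug correlation to agree in sign.
* Alternative network variants: tissue-only and matched-pair consensus
  networks with Cox-based module relevance, and a drug-panel-only network
  whose modules are judged by eigengene–IC50 Spearman correlation; all use
  the |kME| ≥ 0.5 hub filter and no concordance filter. Where a survival
  outcome must serve as a regression response (variants without drug data),
  the binary event indicator is used; modeling OS time among uncensored
  samples is a documented alternative reading, exposed but not default.
* Over-representation analysis: upper-tail hypergeometric p of the overlap
  between a query list and each GMT set intersected with the universe
  (sets outside [10, 500] genes dropped; zero overlap gives p = 1), with
  Benjamini–Hochberg FDR across the retained sets, applied per GMT file.
  The default universe is the network's filtered gene list.

## The synthetic benchmark

`ocrnet.simulate` plants exactly the structure the pipeline assumes: each
module is rank-1 (one latent factor per module, matching the
eigengene-as-first-PC summary), matched-organoid factors are
`ρ_m f + √(1−ρ_m²) ε`, IC50 is linear in the drug module's factor, and
survival times are exponential with rate
`h₀ · exp(log-HR · f_drug)` under uniform censoring — the simplest model
satisfying proportional hazards. Age and sex are generated independent of
outcome so adjusted baselines can be checked for type-I error.

The canonical study (`default_fixture`, seed 20240101) has modules of
60/50/40 genes over 150 background genes, cohorts of 60 tissue / 60 matched
organoid / 40 drug-panel samples, concordances (0.9, 0.8, 0.2), loadings
uniform on (0.5, 1.0) with noise sd 0.6, drug effect 2.0 (noise 0.75), log
hazard ratio 1.0 with baseline hazard 0.04/month and censoring uniform on
(0, 90) months (≈ 35 % censoring). These sizes mirror a realistic
single-center matched study; the held-out validation cohorts used in tests
and the acceptance script have 200 patients.

What passing these tests shows: the numerical primitives match independent
oracles; the pipeline recovers planted modules, loadings, drug genes and
survival stratification under its own model assumptions at realistic sample
sizes. What it does not show: robustness to count-based (negative binomial)
noise, batch effects, multi-factor modules, nonlinear drug response, or
non-proportional hazards — none of which the generator emulates. Results on
real cohorts additionally depend on normalization and probe annotation
steps that are out of scope here (only IQR-based probe collapsing, log2
transform and the top-50 % variance common-gene filter are provided).

## Numerical conventions

* IQR for probe collapsing uses type-7 (linear interpolation) quantiles;
  probe ties break to the lexicographically smallest probe id.
* log2 transform offset defaults to 1 and is configurable.
* Quantile-normalization ties take the average of tied order statistics.
* Expression round-trips through TSV preserve full double precision
  (shortest-repr formatting, round-trip parsing).
* All stochastic components (generator, fold draws, bootstrap, permutation
  importance) consume a single integer seed; equal seeds give bit-identical
  outputs.
* Problem sizes in the test suite and acceptance script (50 replicates for
  selection/recovery rates, 2000 null simulations for type-I error,
  300-tree forests and 10 CV repetitions inside replicated runs) were
  chosen to give stable Monte-Carlo estimates at interactive runtimes.
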