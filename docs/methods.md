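# Methods

This note documents the models, estimators and numerical choices behind
`m6ascore`, and what the synthetic cohorts do and do not establish.

## The synthetic cohort model

Every recovery test runs on cohorts from `m6ascore.syndata`, which encode
the statistical structure the analysis assumes:

* **Latent clusters.** Each sample is assigned to cluster A or B with
  probability 1/2. A continuous latent severity score is drawn per sample,
  `L = ±cluster_shift/2 + N(0, latent_sd²)` (A positive), so the
  between-cluster mean difference on informative genes equals
  `cluster_shift` while the score stays continuous within clusters.
* **Expression.** Per-gene baselines are `N(8, 1)` on a log2 scale — the
  typical microarray log-intensity range — with unit within-gene noise, so
  all effect sizes are in SD units. The 16 regulator genes (named with the
  standard writer/reader/eraser symbols so the default panel resolves) and
  an `n_deg`-gene block add `L` to their baseline; all other genes are pure
  noise. Cohort `i` adds `i × batch_shift` to every gene.
* **Survival.** Event times are exponential with hazard
  `baseline_hazard × hazard_ratio_true^(cluster==A)`; censoring times are
  independent exponentials with rate `censor_rate` (expected censored
  fraction ≈ censor_rate/(censor_rate + hazard)). Defaults
  (`baseline_hazard=0.05/yr`, `hazard_ratio_true=2`, `censor_rate=0.04/yr`)
  give medians near 14 vs 7 years and ~40% censoring, the scale of an
  indolent-lymphoma cohort. Default cohort geometry is 3 × 117 = 351
  samples and 2000 genes.
* **Response cohorts.** `P(response) = logistic(logit(0.25) +
  response_effect × z(L))`, i.e. a 25% marginal response rate at zero
  effect; neoantigen burden is log-normal with latent correlation
  `neoantigen_corr` to `L` (default −0.4, i.e. negative against the latent
  severity score).

Truth (cluster, latent score, true hazard ratio, truly differential genes)
is stored apart from the observables so no analysis stage can read it.

What the generator does **not** emulate: gene–gene correlation beyond the
shared latent factor, heavy-tailed or count-based noise (RNA-seq
overdispersion), informative censoring, covariate-confounded batch effects,
and mutation data. Passing recovery tests therefore demonstrates
correctness of the estimators under the assumed model, not robustness to
real-data violations of it.

## Batch correction

Parametric empirical-Bayes location–scale adjustment: genes are standardized
against the batch-design grand mean and an n-denominator pooled variance;
per-batch location (`γ`) and scale (`δ²`, n−1 denominator) estimates are
shrunk toward a normal and an inverse-gamma prior with moment-matched
hyperparameters, solved by the standard fixed-point iteration (convergence
1e-4); the data are adjusted and back-transformed. No covariate terms. The
implementation is verified against the Bioconductor reference to ~1e-14 on
a fixture in the test suite.

Two consequences of the reference conventions are documented rather than
"fixed": per-gene batch means after adjustment agree to machine precision
only when the batch effect itself is noise-free (the EB shrinkage otherwise
leaves O(1/√n) residuals), and re-applying the adjustment contracts the
scale by √((n−1)/n) per pass, so it is idempotent only up to O(1/n).
A degenerate-prior branch handles batches whose per-gene scale estimates
are all identical (hyperprior variance 0), where the moment match would
divide by zero.

## Consensus clustering

For each k in 2..kmax and each of `reps` replicates (study-scale default
1000), a fraction `subsample=0.8` of samples is drawn without replacement
— features are never subsampled — and k-means (Euclidean, 20 restarts,
best inertia) is run on z-scored features. The consensus matrix divides
co-cluster counts by co-sample counts (0/0 → 0, diagonal 1); final labels
cut an average-linkage tree of 1 − M at k. PAC is the fraction of
off-diagonal consensus entries in the open band (0.1, 0.9); k is chosen as
argmin PAC with ties to the smaller k, and the consensus-CDF delta-area is
reported alongside for inspection. Replicate seeds spawn from a single
root `SeedSequence`, so runs are bit-reproducible.

Subsampling is without replacement at 0.8; a bootstrap (with replacement)
reading of the resampling scheme is possible, but the without-replacement
fraction is the convention of the standard consensus-clustering tooling and
is used here.

The two-cluster partition (the pairwise comparison every downstream stage
needs) is always taken from k=2; the PAC-chosen k is reported separately.
The cluster with the shorter Kaplan–Meier median survival is named "A"
(restricted mean survival over observed follow-up when a median is not
reached; ties to the smaller cluster index).

## Differential expression

Per gene, a two-group linear model; sample variances `s²` (d degrees of
freedom) are modeled as scaled-F around a prior `s₀²` with d₀ prior df,
estimated by moment-matching the log variances (digamma/trigamma; the
trigamma inverse is solved by bracketed root-finding; zero variances are
excluded from the fit and handled by the shrinkage, never NaN). The
moderated t uses the posterior variance on d + d₀ df. Significance is
BH-adjusted p < 0.01 with no fold-change filter, applied to the
batch-corrected merged matrix. Verified against the Bioconductor reference
to ~1e-14 in the suite; `prior_df=0` reproduces the ordinary pooled t
exactly.

## Signature and score

* **Redundancy filter.** A 500-tree random forest (√p features per split)
  predicts the cluster labels from the DEG matrix; genes with permutation
  importance above the median (quantile configurable) are kept. Importance
  uses log-loss scoring: with strongly redundant informative genes,
  permuting a single gene rarely flips a hard class prediction, which makes
  accuracy-based importances identically zero; probability-based scoring
  keeps the ranking informative. Fewer than 10 DEGs skip the filter.
* **Prognostic filter.** Per-gene univariate Cox on standardized
  expression — Newton–Raphson with step-halving on the Efron partial
  likelihood (a fast single-covariate solver; the multivariate fits use
  lifelines) — keeping Wald p < 0.05. Non-converging genes are dropped
  with a warning.
* **Scoring model.** Signature genes are z-scored on the training cohort
  (mean/SD frozen into the model); PCA of the standardized samples×genes
  matrix gives unit-norm orthogonal PC1/PC2 loadings, each sign-fixed so
  its largest-magnitude loading is positive (deterministic fits). The score
  is the sum of the PC1 and PC2 sample projections — the one reading of
  "sum of both components over the prognostic genes" that yields a single
  number per patient.
* **New cohorts** are scored by per-cohort z-scoring and projection onto
  the frozen training loadings (portable across platforms); a refit mode
  re-runs PCA on the new cohort instead. If up to 20% of signature genes
  are missing, loadings are renormalized to unit norm over the present
  genes; more missingness is an error.
* **Cutpoint.** Maximally selected log-rank: every split leaving ≥ minprop
  (default 0.1) of samples on each side is scored by the standardized
  log-rank statistic (vectorized O–E/√V accumulation over event times,
  verified against a per-split brute force); the argmax wins. Note the
  small-sample edge preference of maximally selected statistics: in tiny
  toys the statistic can peak at an unbalanced split rather than the
  visually "perfect" one — this is a property of the statistic, and
  minprop is the control for it. Published cutoffs are scale-dependent and
  are always re-derived on the data at hand.
* **Orientation.** If the high-score group survives shorter on the
  training data, the scores, cutoff and both PC signs are negated so that
  LOW score ⇔ worse prognosis. The operation is idempotent.

## Survival statistics

Kaplan–Meier, log-rank and multivariate Cox (Efron ties, Wald inference)
are delegated to lifelines; Greenwood variances are accumulated from the
event table, medians use the first time S ≤ 0.5 with log(−log) CIs.
Non-convergence or separation in Cox fits is flagged, never silently
returned. The time-dependent ROC is the cumulative-case/dynamic-control
estimator: cases at horizon t (events by t) weighted by 1/G(T⁻), controls
(followed past t) by 1/G(t), with G the Kaplan–Meier estimate of the
censoring distribution; AUC is the weighted concordance over case–control
pairs (verified against exhaustive enumeration). Binary ROC is
concordance-based (ties ½); the rank-sum test is exact for groups ≤ 10
without ties and tie-corrected normal otherwise.

## Enrichment

ssGSEA: per sample, genes are ranked by expression; the score integrates
the difference between the rank-weighted (weight `rank^0.25`) in-set ECDF
and the unweighted out-set ECDF over the whole ranking; the score matrix is
scaled by its overall range. A constant-expression sample carries no
ranking information and scores 0 by convention. The simpler single-sample
estimator is used deliberately in place of the kernel-CDF variant: the
pipeline only compares pathway activity between groups, which this
estimator supports, and it is hand-verifiable.

Two-group GSEA ranks genes by signal-to-noise (SDs floored at
max(0.2·|mean|, 1e-8), the convention that keeps near-constant genes from
dominating); the enrichment score is the extremum of the weighted KS
running sum (weight exponent 1). NES divides the observed ES by the mean
|ES| of same-sign phenotype permutations; the nominal p is the same-sign
permutation tail with a +1 correction, so the attainable floor is
1/(1 + same-sign count). Groups smaller than 3 fall back to gene-set
permutation with a warning. Significance defaults to |NES| > 1 and nominal
p < 0.05.

TIS is the per-sample mean of log10(linear expression + pseudocount) over a
configured 18-gene panel (the panel is an input, not hardcoded; the
pseudocount defaults to 0 so that an all-tens input scores exactly 1, and
must be raised for data containing zeros). Immune-infiltration scoring is
ssGSEA over user-supplied marker sets — a transparent, self-contained
abundance proxy reported with Spearman correlations and rank-sum group
comparisons against the m6A score.

## Pipeline, problem sizes and reproducibility

Stages write plain TSV/JSON artifacts; the summary embeds the seed and a
config hash, and identical configs reproduce bit-identical outputs. All
randomness flows from integer seeds through `numpy` `SeedSequence`
spawning (k-means, subsampling, forests, permutations, simulation).

The default demo and the acceptance script run the simulation at the
study's cohort geometry (351 samples, 2000 genes) with the resampling
reduced to 200 consensus replicates, 300 forest trees and a k scan to 6 —
sizes chosen so a full from-scratch run completes in about a minute on a
single CPU while leaving all statistical conclusions unchanged; the
replicate counts are configuration knobs for study-scale runs (1000
replicates, k to 10, 500 trees).

## Known limitations

* The consensus inner loop is k-means only (no PAM/hierarchical variant);
  item- and cluster-consensus diagnostics are not computed.
* The DE model is two-group only — no covariate adjustment (cohort is
  removed upstream by the batch correction, not modeled in the DE fit).
* Cox fits assume proportional hazards; no diagnostics, competing risks or
  restricted-mean comparisons are provided.
* Whether the redundancy filter should be a classification forest against
  cluster labels or a survival forest is ambiguous in principle;
  classification against cluster labels is implemented.
* External web estimators for immune deconvolution and immune-dysfunction
  scoring are out of scope; marker-set ssGSEA stands in functionally but is
  not a deconvolution.
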