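# m6ascore

Condensing m6A-regulator expression signatures into a per-patient
prognostic score.

N6-methyladenosine (m6A) is the most common mRNA modification; its level
tracks the expression of the "writer" methyltransferases, "reader" effector
proteins and "eraser" demethylases that regulate it. In follicular lymphoma
(and other tumors), the joint expression pattern of these 16 regulator genes
separates patients into subgroups with different prognosis and different
tumor-microenvironment states — including an inflamed-but-exhausted state
(high CD8⁺ T-cell infiltration with upregulated PD-1/PD-L1) that predicts
benefit from anti-PD-L1 immunotherapy. `m6ascore` implements the full
analysis that turns bulk expression cohorts into that stratification:

1. **Cohort merging + batch correction** — parametric empirical-Bayes
   location–scale adjustment (ComBat): per-gene standardization, per-batch
   effects shrunk toward normal / inverse-gamma priors, back-transform.
2. **Consensus clustering** of samples on the 16-regulator panel —
   resampled k-means (Euclidean), consensus matrix
   *M<sub>k</sub>(i,j)* = co-cluster count / co-sample count, final labels by an
   average-linkage cut of 1 − *M<sub>k</sub>*, and *k* selected by PAC (proportion of
   ambiguous clustering). The cluster with worse survival is named **A**.
3. **Differential expression** between the two clusters — per-gene linear
   model with empirical-Bayes variance shrinkage (moderated *t*), BH control,
   significant at adjusted *p* < 0.01.
4. **Signature construction** — random-forest permutation importance removes
   redundant DEGs, a univariate Cox filter (Efron ties) keeps prognostic
   genes at Wald *p* < 0.05, and PCA on the z-scored signature genes defines
   the score: for sample *j*,

   ```
   m6A score_j = PC1_j + PC2_j
   ```

   the sum of the first two principal-component sample scores. The sign
   convention is fixed so that a LOW score means worse prognosis.
5. **Stratification & survival statistics** — maximally selected log-rank
   cutpoint (minimum group proportion 0.1), Kaplan–Meier medians, log-rank
   test, multivariate Cox hazard ratios, time-dependent ROC
   (cumulative/dynamic AUC with Kaplan–Meier censoring weights).
6. **Enrichment & response** — ssGSEA per-sample pathway scores, two-group
   GSEA (|NES| > 1, nominal *p* < 0.05), the 18-gene tumor-inflammation
   signature (mean log10 expression), marker-set immune scoring, and binary
   ROC comparison of score vs response.

A synthetic-cohort generator (`m6ascore.syndata`) reproduces the statistical
structure this analysis assumes — two latent clusters driving a regulator
panel and a differential gene block, additive cohort batch effects,
cluster-dependent proportional hazards with independent censoring, and a
response cohort whose response odds follow the latent score — with the full
ground truth recorded for recovery testing.

## Worked example

```python
from m6ascore.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    simulation=dict(n_samples=60, n_cohorts=2, n_genes=400, n_deg=30),
    cluster_reps=50, related_cluster_reps=30, kmeans_restarts=5,
    rf_trees=100, kmax=4, seed=3,
)
summary = run_pipeline(cfg, "demo_out")
```

prints (abridged) in `demo_out/summary.json`:

```
 "chosen_k": 2,                       # PAC selects two regulator signatures
 "n_degs": 46,                        # genes at BH-adjusted p < 0.01
 "n_signature_genes": 17,             # survive RF + Cox trimming
 "cutoff": -2.3869,                   # maximally selected score cutpoint
 "logrank_p": 4.58e-05,               # low vs high score survival curves
 "median_low": 6.61, "median_high": 14.31,   # KM medians in years
 "cox_hr_low_score": 2.68,            # multivariate HR of the low group
 "time_auc": {"5.0": 0.645, "10.0": 0.696, "15.0": 0.708},
 "response_auc": 0.910,               # low score predicts responders
 "cluster_ari_vs_truth": 0.87,        # recovery of the simulated clusters
 "score_latent_spearman": -0.92       # score tracks the latent severity
```

The low-score group dies earlier (median 6.6 vs 14.3 years), the score is an
independent risk factor (HR 2.68), and — because the simulated responders
are the high-latent-severity/low-score patients — the score predicts
response (AUC 0.91). The same pipeline is scriptable from the shell:

```bash
m6ascore simulate --out cohort --seed 3
m6ascore run --seed 3 --out demo_out
m6ascore score apply --expression new_cohort.tsv \
    --model demo_out/signature_model.json --out new_scores.tsv
```

New cohorts are scored by z-scoring the signature genes within the cohort
and projecting onto the frozen training loadings, which keeps the model
portable across platforms (microarray vs RNA-seq FPKM).

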