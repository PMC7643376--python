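# rbppairsig

Rank-based gene-pair prognostic signatures for censored survival data,
built around the 33-pair RNA-binding-protein (RBP) signature for lung
adenocarcinoma overall survival.

## The problem and the method

Gene-expression prognostic models usually require cross-sample
normalization, which breaks down when cohorts come from different
platforms (RNA-seq FPKM vs microarray). Pair signatures sidestep this:
for a gene pair (A, B) and a single sample, the feature is the binary
indicator

    s(A, B) = 1  if  expr(A) > expr(B)   (strictly, within the sample)
            = 0  otherwise (including ties)

which depends only on the within-sample ranking and is therefore
invariant to any per-sample monotone transform — no normalization
needed. A patient's risk score is a weighted sum over signature pairs,

    r = Σ_k β_k · s(A_k, B_k),

with coefficients β_k from an L1-penalized Cox proportional-hazards fit
(penalty chosen by k-fold cross-validated partial likelihood). Patients
with r above a cutoff — chosen by maximizing Youden's J on a
Kaplan–Meier time-dependent ROC at a 3-year horizon — form the
high-risk group; the groups are compared by Kaplan–Meier curves,
log-rank tests, and univariate/multivariate Cox regression against
clinical covariates (age, gender 1/2, pathologic stage 1–4, T/N/M).

The full discovery pipeline mirrors the published modeling funnel:
exclude patients with under 30 days of follow-up → collapse duplicate
probes/samples by averaging → moderated-t differential expression
(tumor vs normal, BH FDR < 0.05, |log2FC| > 0.5) within an RBP gene
universe → keep candidates with mean expression > 0 and median absolute
deviation > 0.5 → build all candidate pair indicators → drop pairs
whose scores are >90% identical → lasso-Cox selection → ROC cutoff →
stratified survival validation. A published 33-pair / 49-gene signature
with cutoff −0.075 ships with the package and can be applied to any
expression matrix as-is. Tumor mutational burden (mutations per
megabase from MAF records) and rank-sum comparisons of any per-sample
quantity across risk groups are included.

## Worked example

```python
from rbppairsig import (
    generate_cohort, build_pair_matrix, filter_constant_pairs,
    fit_lasso_cox, score_samples, timedep_roc, choose_cutoff,
    stratify, km_logrank,
)

# synthetic tumor/normal cohort with 10 planted prognostic pairs
expr, clin, truth = generate_cohort(
    n_tumor=400, n_normal=20, n_genes=40, n_signal_pairs=10,
    gamma=0.8, lambda0=1e-5, seed=101,
)
tumors = expr.subset_samples(expr.tumor_samples())
pairs = filter_constant_pairs(build_pair_matrix(tumors, expr.gene_ids))
sig = fit_lasso_cox(pairs, clin, cv_folds=10, seed=1)
scores = score_samples(sig, tumors)
roc = timedep_roc(scores, clin, horizon=1095)
cutoff = choose_cutoff(roc)
groups = stratify(scores, cutoff)
km = km_logrank(groups, clin)
print(f"{len(sig)} pairs selected, 3-year AUC {roc.auc:.3f}")
print(f"high vs low HR {km.hr:.2f} ({km.ci_low:.2f}-{km.ci_high:.2f}), "
      f"log-rank p {km.p_value:.2g}")
```

Output:

```
34 pairs selected, 3-year AUC 0.922
high vs low HR 11.04 (7.67-15.91), log-rank p 3.1e-51
```

The fit selects 34 pairs — all 10 planted pairs among them, plus
correlated noise pairs, the usual lasso behavior at the minimum-CV
penalty; the 3-year time-dependent AUC of the risk score is 0.92, and
stratifying at the learned cutoff separates survival with a hazard
ratio of about 11 (in-sample; the independent-cohort HR in the
acceptance run is around 4–6).

Scoring a cohort with the packaged signature:

```python
from rbppairsig import load_packaged_signature, score_samples, stratify
sig = load_packaged_signature()      # 33 pairs, 49 genes, cutoff -0.075
scores = score_samples(sig, my_expression_matrix)
groups = stratify(scores, sig.cutoff)
```

Pairs whose genes are absent from the matrix contribute 0 and are
counted per sample in `scores.n_missing_pairs`.

A `rbp-pairsig` command-line interface wraps the same stages:
`simulate`, `prefilter`, `fit`, `score`, `validate`, `run-all`, each
with `--config` (YAML) and flag overrides.

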