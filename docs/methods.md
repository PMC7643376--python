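# Methods

## Model

The package treats prognosis prediction as feature selection over
within-sample gene-pair orderings. For candidate genes the feature of
pair (A, B) in sample i is s_i(A,B) = 1{expr_i(A) > expr_i(B)}, with
ties scoring 0. The hazard model is Cox proportional hazards on these
binary features,

    h_i(t) = h_0(t) · exp( Σ_k β_k s_i(A_k, B_k) ),

fit with an L1 penalty so that only a sparse set of pairs receives
nonzero β. The risk score r_i = Σ_k β_k s_i(·) is dimensionless (a sum
of log-hazard contributions); a fixed cutoff dichotomizes it into
high/low risk. Because every feature is a within-sample comparison, the
whole scorer is exactly invariant to per-sample strictly increasing
transforms of expression — the property that lets one cutoff transfer
across platforms without renormalization, and the property the test
suite asserts bit-for-bit.

## Pipeline stages and their parameters

All constants live in `RunConfig` with these defaults (units in
parentheses):

- `min_days = 30` (days): patients with shorter or missing follow-up
  are excluded before any modeling; survival times are kept in days
  throughout, with the 3-year horizon at `horizon_days = 1095`.
- Differential expression: tumor vs normal on log2(x+1)-transformed
  values using a moderated t-statistic — per-gene pooled variances are
  shrunk toward a scaled-inverse-chi-square prior whose degrees of
  freedom and scale are moment-estimated from the log residual
  variances of the whole gene family (trigamma inversion by Newton's
  method). With prior df forced to 0 the statistic equals the ordinary
  pooled t exactly, which is how it is validated. Benjamini–Hochberg
  adjustment across the tested family; a gene passes at
  `fdr_max = 0.05` and `lfc_min = 0.5` (|log2 fold change|, so both
  up- and down-regulated genes qualify).
- Candidate filter: mean expression > `mean_min = 0` and unscaled
  median absolute deviation (no 1.4826 consistency factor) >
  `mad_min = 0.5`, both computed over tumor samples on the log2(x+1)
  scale. The scale is a package choice: for log-normal expression the
  0.5 threshold only discriminates between low- and high-variability
  genes on the log scale (raw-scale MADs grow with the expression
  level and would pass nearly everything); `transform="raw"` and
  `samples="all"` restore the alternatives.
- Pair space: all C(n,2) unordered candidate pairs, stored in canonical
  lexicographic orientation as a uint8 matrix (350 candidates × 500
  samples ≈ 30 MB). The reverse orientation is the deterministic
  complement away from ties, so carrying both would duplicate features
  with flipped sign. Pairs whose scores are identical in more than
  `max_identity = 90%` of samples are discarded (a pair at exactly 90%
  is kept). Published signatures keep their printed orientation, which
  overrides canonicalization during scoring.
- Lasso Cox: coordinate-descent penalty path (scikit-survival Coxnet,
  l1_ratio = 1, 50 alphas, alpha_min_ratio 0.01). The penalty is chosen
  at the maximum of the Verweij–van Houwelingen cross-validated partial
  likelihood, CV-PL = Σ_folds [PL(all; β_−k) − PL(train_k; β_−k)] with
  Breslow tie handling, over `cv_folds = 10` seeded folds. The minimum
  rule (not 1-SE) is used: the method's published use selects dozens of
  pairs from tens of thousands, which the denser rule matches.
  Reported coefficients are the penalized ones; `refit=True` optionally
  reports an unpenalized refit on the selected pairs instead.
- Time-dependent ROC at the horizon t*: the Kaplan–Meier estimator
  with S the overall KM survival at t* and S_hi/S_lo the KM survival
  within the score groups at cutoff c,
  sensitivity(c) = (1 − S_hi)·P(score>c)/(1 − S) and
  specificity(c) = S_lo·P(score≤c)/S, evaluated at midpoints between
  sorted unique scores plus ±∞, clipped to [0,1] (the KM ratio can
  marginally exceed the unit interval under censoring). AUC is the
  trapezoid over (1−specificity, sensitivity); with no censoring before
  the horizon the estimator reduces point-by-point to the classical
  binary ROC, which the tests assert. The in-loop KM evaluator is a
  small vectorized product-limit routine (hundreds of cutoffs × two
  group fits make per-fit library overhead the bottleneck); user-facing
  KM curves come from lifelines.
- Cutoff: maximizes Youden's J = sensitivity + specificity − 1, ties
  broken toward the smaller cutoff, finite candidates preferred over
  the ±∞ endpoints. High risk = score strictly above the cutoff,
  consistent with the packaged signature's convention (score −0.07 is
  high at cutoff −0.075).
- Survival statistics: log-rank via lifelines; the group hazard ratio
  from a single-covariate Cox fit (Efron ties). When that fit hits a
  monotone likelihood (a group without events, common in small null
  cohorts) it retries with a small ridge penalty (0.01), which
  preserves the HR(swap) = 1/HR symmetry. Uni/multivariate Cox
  regression is complete-case per model with numeric encodings:
  gender male = 1 / female = 2, pathologic stage I–IV → 1–4.
- Group comparisons of per-sample quantities (TMB, externally computed
  immune/stromal scores, …) use the unpaired Wilcoxon rank-sum test:
  exact enumeration when both groups have ≤ 10 untied observations,
  otherwise the tie-corrected normal approximation. (The published
  description names the signed-rank test, which is a paired test and
  cannot apply to independent risk groups; the rank-sum test is the
  appropriate unpaired analogue.)
- TMB: counted mutations per megabase, default denominator
  `exome_mb = 38` (a conventional exome footprint; the denominator is
  a flag). Counted classes default to non-silent coding mutations
  (missense, nonsense, nonstop, frameshift/in-frame indels, splice
  site, translation start); `classes=None` counts every record.

## The packaged signature

`load_packaged_signature()` returns the published 33-pair / 49-gene
lung-adenocarcinoma RBP signature with its risk cutoff −0.075 (chosen
in the source study by 3-year time-dependent ROC on TCGA-LUAD and
validated on GEO cohort GSE72094). It is stored as a diffable TSV plus
YAML sidecar and applied without refitting: pairs with missing genes
contribute 0 and are counted per sample. The source study's
cohort-level numbers (discovery HR ≈ 4.4, validation HR ≈ 1.6) are
external-replication context only — reproducing them requires the
original cohorts and the original penalty tuning; nothing in this
package asserts them.

## Synthetic cohorts

`generate_cohort` emulates the statistical structure the pipeline
assumes, not TCGA's empirical distributions:

- log2-expression per gene is Gaussian with mean ~ Uniform(1, 7) and SD
  ~ Uniform(0.3, 1.0); expression is 2^(log2-value), so values are
  log-normal and FPKM-like in scale. The SD range deliberately
  straddles the MAD > 0.5 filter so the candidate screen has both
  passers and failers.
- a fraction `frac_de` of genes is shifted by ±`log2fc` in tumor
  samples (planted truth recorded per gene).
- planted signal pairs: both members share mean and SD (indicator ≈
  Bernoulli(1/2), maximally informative), SD ≥ 0.9 (clears the MAD
  filter), and both members are shifted equally in tumors (the pair
  passes the DE screen with its indicator distribution unchanged).
- survival: exponential proportional hazards per tumor sample with
  rate λ0·exp(γ·Σ_k s_k + stage_loghr·(stage−1)); censoring
  independent Uniform(0, censor_max); observed times rounded up to
  whole days (producing realistic ties). Exponential hazards are the
  simplest model consistent with the Cox analyses, which keeps
  parameter-recovery targets well defined.
- covariates: age ~ round(Normal(65, 10)) clipped to 30–90, gender
  1/2, stage 1–4 with probabilities (0.55, 0.25, 0.15, 0.05), T/N/M
  loosely derived from stage, smoking ~ Bernoulli(0.75).
- `quantize_decimals` optionally rounds expression to create exact
  ties, exercising the ties-score-0 rule.

Study conditions used by the tests and the acceptance script were
fixed once: planted-signal experiments use λ0 = 1e-5/day — with 10
pairs at γ = 0.8 the mean planted log-hazard is ≈ 4, giving a cohort
median OS around 3.5 years so the 1095-day ROC horizon is observable —
and 40 candidate genes, so that well over 200 informative noise pairs
survive the 90% identity filter. Null-calibration experiments
(γ = 0) use λ0 = 1/1500/day (median ≈ 2.9 years). Problem sizes are
n = 400 discovery / n = 300 validation for recovery runs and n = 150
for the 50-replicate null pipeline runs.

What passing these tests shows: the selection machinery recovers
genuinely prognostic, balanced, platform-stable pair orderings at
realistic cohort sizes, and does not invent signal under the null.
What they do not show: behavior under correlated co-expression
modules, batch effects, heavy-tailed FPKM noise, informative
censoring, or unbalanced pair indicators — none of which the generator
emulates.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng(seed)`;
  identical inputs and seed reproduce cohorts, fits and written
  artifacts byte-for-byte.
- Ties in pair scoring give 0 (the indicator is strict); tied event
  times use Efron's approximation in Cox fits and grouped risk sets in
  the partial likelihood used for CV.
- Constant pair features are dropped before the lasso (they cannot be
  selected); an all-constant feature matrix is an error, as are
  cohorts with fewer than 2 events or a group with fewer than 2
  samples in differential expression.
- A penalty above the path maximum returns an empty signature rather
  than an error; an empty signature scores every sample 0 and the
  pipeline reports a single risk group without survival comparison.
- Samples whose signature is more than half unevaluable (missing
  genes) are flagged in the score object's warnings, not dropped —
  cross-platform validation stays usable with an explicit
  evaluability report.
- Expression round-trips are stable at 6 significant digits (`%.6g`);
  a second write/read cycle is exactly idempotent.

## Known limitations

- The moderated-t screen assumes roughly Gaussian log-expression;
  count-level models (limma-voom, DESeq2-style) are out of scope.
- The time-dependent ROC uses the KM method only (no nearest-neighbor
  smoothing), so the curve can be locally nonmonotone under heavy
  censoring; monotonicity is exact in the uncensored case.
- Pair orientation is canonicalized before fitting; the two
  orientations are complements, so this is lossless, but printed
  signatures from other sources must keep their own orientation (the
  packaged loader does).
- The CV partial-likelihood criterion with the minimum rule tends to
  select a superset of the truly prognostic pairs; users wanting
  sparser models can pass a larger fixed `alpha`.
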