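name: luad_rbp33
cutoff: -0.075
description: >
  33-gene-pair RNA-binding-protein prognostic signature for lung
  adenocarcinoma overall survival.  Risk score = sum of coefficients over
  pairs whose first gene's expression strictly exceeds the second's within
  the sample; scores strictly above the cutoff assign the high-risk group.
  Pairs are stored in their published orientation (not canonicalized).
provenance: >
  Transcribed from the published signature table of a TCGA-LUAD-derived
  L1-penalized Cox gene-pair model with a 3-year time-dependent-ROC cutoff,
  validated on GEO cohort GSE72094.
cutoff_criterion: 3-year time-dependent ROC, fittest cutoff
units: risk score (dimensionless sum of Cox log-hazard coefficients)
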