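# radbcr

MRI radiomics pipeline for predicting **biochemical recurrence (BCR)**
after radical prostatectomy, for imaging scientists and biostatisticians
studying texture-based prognostic markers in prostate cancer.

About half of patients with high-risk disease relapse biochemically (PSA
rising above 0.2 ng/mL on two successive samples) after surgery, and
clinical/histopathological factors select candidates for adjuvant therapy
poorly. This package implements a complete, testable version of a
radiomics workflow that asks whether the *spatial heterogeneity* of the
tumor on pre-operative MRI (T2-weighted and ADC) carries independent
prognostic signal:

1. **Wavelet sub-band filtering** — one undecimated pass of the coiflet-1
   low/high-pass filters along each axis gives eight sub-bands
   (LLL … HHH) plus the original: nine aligned images per sequence.
2. **Texture features** — gray-level size-zone (GLSZM), run-length
   (GLRLM) and co-occurrence (GLCM) matrices per (sequence × sub-band ×
   discretization), plus first-order and shape descriptors, following
   IBSI conventions. The headline statistic is **small zone emphasis**

   SZE = (1/N_s) Σ_{i,j} s(i,j) / j²,

   where s(i,j) counts connected zones of gray level *i* and size *j*:
   it weights zones by 1/size², so fragmented (heterogeneous) lesions
   score high and homogeneous lesions low (a single zone of size N gives
   1/N²).
3. **Harmonization and selection** — stratified 2:1 train/test split;
   per-scanner, per-side z-scoring; SMOTE rebalancing of the training
   side; then resampling stability selection: a feature variant survives
   only if its absolute point-biserial correlation with BCR exceeds 0.3
   in ≥ 95 of 100 stratified 2:1 subsamples, one variant per base
   feature is kept (max mean |PC|), and survivors correlated above 0.7
   are pruned greedily.
4. **Survival evaluation** — per-variable ROC/AUC with Youden-index
   cutoffs, and three additive risk models (clinical-only,
   radiomics-only, combined) evaluated with ROC, Kaplan–Meier/log-rank
   and Cox proportional hazards on both cohort sides, with every cutoff
   frozen on the training side.

Because no public cohort exists, `radbcr.synthetic` generates a full
in-silico study — ellipsoidal tumor ROIs over Gaussian random fields
whose correlation length ℓ controls zone size, a Weibull
proportional-hazards outcome loading on −ℓ, two scanner strata with an
affine intensity shift, and realistic clinical covariates — so the whole
chain is testable end-to-end with known ground truth.

## Worked example

```python
from radbcr import GeneratorConfig, RecurrenceStudy, generate_cohort

patients = generate_cohort(GeneratorConfig(), seed=1)   # 107 patients
study = RecurrenceStudy.from_cohort(patients)           # extract features
results = study.fit(seed=1)
print(len(results.selected_features))
print(results.models.summary_table().round(3).to_string(index=False))
```

prints (seed 1):

```
10
    model  side   auc  sensitivity  specificity  p_value  logrank_p     hr  hr_p
 clinical train 0.729       85.714       48.276    0.004      0.038  4.280 0.057
 clinical  test 0.768       85.714       75.000    0.022      0.001  0.061 0.010
radiomics train 0.912       78.571       93.103    0.000      0.000 24.033 0.000
radiomics  test 0.862       71.429       96.429    0.001      0.000 18.483 0.001
 combined train 0.914      100.000       63.793    0.000      0.000  4.763 0.002
 combined  test 0.625       71.429       60.714    0.297      0.221  2.680 0.239
```

Ten feature variants survive selection, most of them ADC-side zone/run
statistics (the first is an ADC small-zone-emphasis variant,
`ADC|LHL|FBN8|SZE`). The radiomics model separates both sides strongly
here (test AUC 0.86, hazard ratio ≈ 18 between the dichotomized risk
groups), while the combined model overfits its extra clinical factors —
small-cohort behaviour this workflow is designed to expose. Across seeds
the radiomics test AUC averages ≈ 0.78.
`results.summary()` gives the full report (selection evidence,
univariate tables, frozen cutoffs).

The same study can be driven from the shell over a directory of NIfTI
images:

```bash
radbcr generate study/ --seed 1
radbcr run study/ --seed 1
```

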