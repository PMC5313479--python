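# casco — quantitative staging of cancer cachexia

Cancer cachexia is a multifactorial wasting syndrome — loss of muscle and
fat mass with systemic inflammation, anorexia, reduced physical
performance and degraded quality of life. Most classification schemes for
it are qualitative (pre-cachexia / cachexia / refractory cachexia) and
cannot rank patients within a class. The **CAchexia SCOre (CASCO)** fills
that gap with a 0–100 composite of five weighted components:

| Component | Points | Inputs |
|---|---|---|
| Body weight loss & composition (BWC) | 40 | % weight loss bands + lean-body-mass depletion |
| Inflammation / metabolic disturbances / immunosuppression (IMD) | 20 | 11 blood markers (CRP, IL-6, albumin, pre-albumin, lactate, triglycerides, urea, hemoglobin, ROS, HOMA, lymphocyte count) |
| Physical performance (PHP) | 15 | 5-item questionnaire |
| Anorexia (ANO) | 15 | 4 SNAQ appetite items |
| Quality of life (QoL) | 10 | 25 QLQ-C30-derived items |

The total stages a patient as **no cachexia (≤ 14), mild (15–28),
moderate (29–46) or severe (≥ 47)**. **MiniCASCO (MCASCO)** is the
reduced variant for routine use: the same budgets and staging rule with a
four-marker blood panel (albumin, hemoglobin, CRP, lymphocytes) and a
14-question short form.

This package is aimed at clinical researchers and biostatisticians
working on cachexia staging. It provides:

- **`casco.instrument`** — declarative, validated instrument definitions
  (budgets, weight-loss bands, marker reference rules, ordinal items,
  staging cut-offs); presets `"casco"` and `"minicasco"`, or any YAML/JSON
  config with the same schema.
- **`casco.scoring`** — patient records → component points → total →
  stage, with an explicit missing-data policy (QLQ-C30-style proration,
  or strict).
- **`casco.psychometrics`** — Cronbach's α, Welch two-group comparison
  with effect size r, tie-corrected Spearman correlations, Bonferroni
  family-wise control.
- **`casco.cutoffs`** — staging cut-point estimation by Ward clustering
  of the 1-D score distribution (exact dynamic-programming partition
  available), with ANOVA separation and ε² effect size.
- **`casco.simulate`** — a seeded case–control cohort generator
  (186 patients + 95 controls by default) whose group score distributions
  are calibrated to means 32.54 ± 17.58 (cancer) and 8.72 ± 3.56
  (control), with a latent-severity factor driving every input.
- **`casco.validation`** — `CohortValidation(cohort).fit()` →
  `ValidationResults` with a `summary()` table and JSON/markdown export.
- a `casco` command line (`simulate`, `score`, `stage`, `validate`,
  `cutoffs`, `info`).

## Worked example

```python
from casco import CohortParams, CohortValidation, simulate_cohort

cohort = simulate_cohort(CohortParams(seed=11))
results = CohortValidation(cohort).fit()
print(results.summary())
```

prints

```
Cohort validation report
========================
instrument: CASCO (short form: MCASCO)

Total score by group (mean / sd / n):
  cancer     31.14 /  17.39 / 186
  control     8.96 /   4.45 / 95

Internal consistency (Cronbach's alpha):
  PHP  alpha =  0.850  (k = 5, n = 265)
  ANO  alpha =  0.844  (k = 4, n = 276)
  QoL  alpha =  0.891  (k = 25, n = 218)

Discriminant validity (patients vs controls, Welch t):
  t = 16.37, df = 228.1, p = 2.31e-40, r = 0.73
  95% CI of mean difference: [19.51, 24.85]

Concurrent validity (patients only, Bonferroni-adjusted):
  clinician_rating   spearman r =  0.466  p = 2.16e-11 * (n = 186)
  ecog               spearman r =  0.375  p = 1.33e-07 * (n = 186)
  mcasco_agreement   pearson  r =  0.981  p = 8.82e-134 * (n = 186)

Estimated staging cut-points (Ward clustering of patient scores):
  breakpoints: 9.5, 28.4, 43.1
  integer boundaries: (9, 28, 43)
  cluster sizes: (23, 60, 59, 44)
  ANOVA F = 631.50, df = (3, 182), eps^2 = 0.91
```

Reading it: the simulated cancer group averages 31 points (mild–moderate
range) against 9 for controls; the three questionnaire scales are
internally consistent (α 0.84–0.89); the Welch test separates the groups
with effect size r = 0.73; the total correlates positively with both
external criteria (oncologist rating and ECOG performance status) and
almost perfectly with the MiniCASCO short form; and clustering the
patient scores into four groups re-derives integer staging boundaries
close to the shipped (14, 28, 46) rule.

The same pipeline from the shell:

```sh
casco simulate --seed 11 --out cohort.csv --sidecar truth.json
casco score --input cohort.csv --out scores.csv
casco validate --input cohort.csv --out-json report.json
casco stage 33          # -> moderate
```

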