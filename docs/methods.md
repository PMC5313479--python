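# Methods

## The instrument as data

An `InstrumentDefinition` is a declarative object: component budgets
(BWC 40, IMD 20, PHP 15, ANO 15, QoL 10, summing to the 100-point scale),
a weight-loss band table, lab-marker reference rules, ordinal item
specifications, and the staging rule (no cachexia ≤ 14, mild 15–28,
moderate 29–46, severe ≥ 47). Validation checks every structural
invariant (budget sums, unique ids, monotone bands, ordered staging cuts)
and reports violations as data, so a config can be audited rather than
merely rejected.

The point allocation *within* each budget is a documented package default
rather than a published table:

- **BWC**: percent weight loss relative to pre-illness weight, banded
  0 / >0–5 / >5–10 / >10–15 / >15 % → 0 / 7.5 / 15 / 22.5 / 30 points,
  plus 10 points for confirmed lean-body-mass depletion. Weight gain
  clamps to zero loss. The weight-loss time window is recorded as
  metadata, not enforced.
- **IMD**: inflammation 8 (CRP 4, IL-6 4), metabolic disturbances 8
  (1 point per abnormal marker among albumin, pre-albumin, lactate,
  triglycerides, urea, hemoglobin, ROS, HOMA), immunosuppression 4
  (lymphopenia). The 4-point lymphocyte share is anchored by the
  instrument's published description of lymphocyte count as 4% of the
  scale. The glucose-tolerance/HOMA parameter is treated as a single
  binary marker.
- **Questionnaires**: each item maps its ordinal response linearly to
  [0, budget/k]; worst response scores the per-item maximum. PHP and
  QoL items 1–23 use 4 levels; the two QoL global items use 7 levels and
  are reverse-coded; the four SNAQ anorexia items use 5 levels and are
  reverse-coded because their printed anchors ascend from worst ("very
  poor") to best.

Marker reference thresholds are editable config, shipped with standard
adult ranges (CRP > 5 mg/L, IL-6 > 10 pg/mL, albumin < 3.5 g/dL,
pre-albumin < 20 mg/dL, lactate > 19.8 mg/dL, triglycerides > 150 mg/dL,
urea > 50 mg/dL, hemoglobin < 12 g/dL female / < 13 male,
ROS > 310 FORT U, HOMA > 2.5, lymphocytes < 1000 /µL).

**MiniCASCO** keeps the five budgets and the staging rule; its reduced
item and marker sets are rescaled to attain the full budgets (CRP 8,
albumin 4, hemoglobin 4, lymphocytes 4; two PHP items at 7.5; two SNAQ
items at 7.5; ten QoL items at 1.0). The short form's published
description is internally inconsistent about the QoL count (11 in prose
vs 10 in its item table); the preset follows the table.

## Scoring and missing data

Default policy (`prorate`): a component with fewer than half of its
inputs observed contributes 0 points and marks the result incomplete; a
questionnaire component with at least half of its items answered is
prorated to the full budget (mean answered-item severity × budget), the
QLQ-C30 scale-scoring convention. `strict` mode refuses a total whenever
any input is missing. Totals are real-valued; staging compares the real
total against the inclusive integer cuts, so a prorated 14.4 stages as
mild. Component points may be fractional by design.

ECOG performance status and the clinician severity rating are carried as
external validity criteria only; they never enter the score.

## Validation statistics

- **Cronbach's α** uses the variance formula
  α = k/(k−1)·(1 − Σσ²ᵢ/σ²ₜ) with population-variance (denominator n)
  convention for both item and total variances — only the ratio matters,
  and the coefficient is identical under the sample-variance convention.
  Deletion is listwise within a scale, with the usable n reported.
- **Discriminant validity** defaults to the Welch t test (the group
  spreads in this setting are grossly unequal, ~17.6 vs ~3.6); the pooled
  test is available by flag. Effect size r = √(t²/(t²+df)); a 95% CI of
  the mean difference accompanies the test.
- **Concurrent validity** uses tie-corrected Spearman ρ (Pearson on
  mid-ranks) with pairwise deletion; the full-vs-short-form agreement is
  Pearson. All correlations in one report form a Bonferroni family at
  α = 0.05 (reject iff p ≤ α/m).
- Construct validity by confirmatory factor analysis / SEM is out of
  scope; per-scale α and the inter-measure correlations stand in for it.

## Cut-point estimation

Scores are clustered into k = 4 groups by agglomerative Ward linkage on
the 1-D values; labels are ordered by cluster mean and must be
value-contiguous. Each breakpoint is the midpoint between adjacent
cluster extremes; its integer boundary is floor(midpoint), read as "the
lower stage while total ≤ b". One-way ANOVA F across clusters and the
ε² effect size quantify separation. Ward's agglomeration is greedy:
`method="dp"` computes the exact minimum within-cluster sum of squares
over contiguous partitions (Fisher's grouping, O(kn²)) and is the
optimality oracle in the tests. On well-separated four-component
mixtures the two coincide essentially always; on unstructured data Ward
can be several percent above the optimum, which is why the exact method
is exposed. The shipped staging rule keeps the published boundaries
(14, 28, 46) as fixed constants regardless of re-estimation; cut-point
estimation takes an explicit score vector, so the caller chooses the
subset (patients only, by default, in the validation pipeline).

## The synthetic cohort generator

No patient-level data are deposited, so the validation pipeline is
exercised on a generator that emulates the study's case–control
structure: 186 cancer patients and 95 controls with total-score targets
32.54 ± 17.58 and 8.72 ± 3.56.

Each subject has a latent severity s ∈ [0, 1]. A target total T is drawn
per group from a [0, 100]-truncated normal whose *truncated* moments are
solved to match the group targets, with the links' measurement-noise
variance (computed analytically on a severity grid by Gauss–Hermite
quadrature) subtracted from the target variance so the realized spread
stays on target. Severity is then s = m⁻¹(T), where m(s) is the exact
expected total under the links below — this makes the realized group
means unbiased by construction rather than hand-tuned:

- **weight loss**: a continuous monotone link with a half-band offset so
  the banded points track 40·s on average; pre-illness weight is drawn
  from the group weight distribution and current weight derived from the
  loss.
- **LBM depletion**: switches on when s (plus link noise) exceeds 0.75,
  matching the 10-point share at the top of the BWC budget.
- **markers**: marker m turns abnormal when s + noise crosses a
  per-marker severity cut; cuts are staggered (inflammation and
  hypoalbuminemia early, overt metabolic failure late) so expected IMD
  points grow linearly in s. Values are drawn on the correct side of the
  reference threshold; only the side matters to scoring.
- **items**: a graded-threshold model — item latent g = s + τ·ε with τ
  fixed by the factor loading (`item_loading`, default 0.8; loading 1 is
  noise-free) and the pooled severity spread, quantised to the item's
  levels with fixed per-item phase offsets (dithering, so aggregate
  scores vary smoothly in s rather than jumping in component-wide
  steps).
- **criteria**: ECOG and the clinician rating are Gaussian-copula
  discretisations with latent correlation `criterion_rho` (default 0.4)
  to severity among patients; controls carry ECOG 0 as in the study
  population. Discretisation attenuates the realized rank correlation
  slightly below the latent parameter.
- **missingness**: MCAR over lab and item cells (default rate 0.01,
  matching the near-complete per-contrast ns of the study); identifiers,
  group and criteria are never masked.
- **cosmetics**: sex, age, baseline weight and tumor site are sampled
  from the published group frequencies and do not influence severity.

What the generator does *not* emulate: within-subject correlation
between components beyond the single severity factor, informative
(MNAR) missingness, longitudinal change, site- or sex-specific disease
profiles, and real measurement error in weights and assays. Passing
tests therefore demonstrate that the scoring and validation machinery
behaves correctly under the study's distributional conditions, not that
the instrument is clinically valid on new data.

## Numerical choices and degenerate inputs

- Scores are quantised by bands and ordinal levels, so the total is a
  step function of severity: in the noise-free limit it is exactly
  monotone but has ties, and its rank correlation with severity sits
  slightly below 1 (≈ 0.98 at the default cohort size).
- α is undefined for a single item, fewer than two complete rows, or
  zero total variance; correlations require n ≥ 3 non-constant pairs;
  the two-group test requires n ≥ 2 per group; clustering requires
  n ≥ k. All raise typed domain errors.
- Cluster labels are relabelled by ascending mean; `derive_cutoffs`
  rejects partitions whose value ranges overlap.
- The truncated-normal moment match is solved with a hybrid root
  finder; the severity inversion grid is made strictly increasing with a
  1e-9 ramp to keep interpolation well-defined across flat stretches.
- CSV I/O is UTF-8, comma-separated, "." decimal, empty cell = missing;
  unparseable numeric cells flag the subject without aborting the
  cohort.

## Problem sizes

The test suite and the reproduction script use the study-scale cohort
(281 subjects) throughout; the calibration check averages 100 generator
seeds, and the clustering optimality check uses 150 random
separated-mixture instances of up to 30 scores, where exhaustive
dynamic programming is exact.
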