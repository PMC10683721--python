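# Methods

This package studies between-hospital variation in stroke thrombolysis
decisions with an explainable machine-learning pipeline: a synthetic
registry generator with known ground truth, gradient-boosted decision
models, exact SHAP decompositions, counterfactual hospital analyses, a
patient-mix vs hospital variance partition, and subgroup rate matrices.
This document records the models, parameters and numerical choices.

## 1. Synthetic registry generator

The generator emulates a national stroke-audit cohort of emergency
admissions arriving within 4 h of onset. Each patient record carries 10
features and a binary thrombolysis label:

| column | domain | marginal distribution (defaults) |
|---|---|---|
| `arrival_to_scan_min` | minutes ≥ 0 | lognormal(ln 35, 0.8) + per-hospital shift N(0, 6), clipped to [0, 360] |
| `infarction` | {0, 1} | 1 − Bernoulli(0.15) (0 = haemorrhage) |
| `nihss` | integers 0–42 | ⌊Gamma(1.8, 5)⌋ clipped |
| `precise_onset` | {0, 1} | Bernoulli(0.65) |
| `prior_mrs` | integers 0–5 | Binomial(5, σ(−2.0 + 0.48·(age−70)/10)) |
| `stroke_team` | identifier | allocation ∝ lognormal admission volume, ≥ 1 patient each |
| `anticoagulant` | {0, 1} | Bernoulli(0.12) |
| `onset_to_arrival_min` | (0, 240] | lognormal(ln 100, 0.45) truncated at 240 |
| `onset_during_sleep` | {0, 1} | Bernoulli(0.10) |
| `age_midpoint` | 5-year band midpoints 37.5–92.5 | N(73, 13) snapped to band grid |

Features are sampled independently except (a) prior mRS rises with age —
the default coupling of 0.48 yields a pairwise r² of about 0.146 at
registry scale — and (b) each hospital shifts its own arrival-to-scan
distribution (a process property). Optional `decoy_XX` columns are pure
standard-normal noise.

### Decision model (ground truth)

Labels are drawn from an additive log-odds rule

```
log-odds = intercept + Σ_k f_k(x_k) + hospital offset
```

with intercept 2.6 and piecewise-linear effects whose spans are stated
as odds ratios ("fold changes") between reference feature values:

| effect | shape | default span |
|---|---|---|
| arrival-to-scan | linear fall 0→120 min, 0.25× slope beyond | 9-fold over 0→120 min |
| NIHSS | rise 0→15, plateau 15–25, fall 25→42 | 30-fold rise; 5-fold fall |
| precise onset | step | 3-fold (estimated lower) |
| prior mRS | linear 0→5 | 6-fold |
| anticoagulant | step | 5-fold |
| onset-to-arrival | flat below 120 min, linear fall 120→240 | 3-fold |
| onset during sleep | step | 4-fold |
| age | flat below 80, linear fall 80→110 | 2-fold |

Haemorrhagic stroke is handled outside the log-odds scale: the label is
deterministically 0, mirroring the clinical contraindication.

Hospital offsets are drawn normal and then affinely rescaled so that the
odds ratio between the extreme hospitals equals
`hospital_offset_span_fold` (default 13) exactly, with mean offset 0.
`process_coupling` (default 8 min per log-odds unit) makes
thrombolysis-prone hospitals faster from scan to needle.

All randomness flows from one master seed through named
`numpy.random.SeedSequence` substreams (hospitals, patients, labels,
decoys), so adding decoy columns or relabelling does not perturb the
other draws.

**Emulation scope.** The generator reproduces the *structure* of a
registry — effect shapes, hospital heterogeneity, realistic marginals —
not any real hospital's data. Only the 10 modelled features are emitted
(plus decoys and hospital descriptors); it is not a general EHR
synthesiser.

## 2. Decision models

Gradient-boosted classification trees (XGBoost, `binary:logistic`) in
three training designs:

- **k-fold** (default 5 stratified folds): pooled out-of-fold accuracy,
  ROC AUC, the threshold where sensitivity equals specificity (linear
  interpolation between adjacent ROC points), and per-hospital agreement
  between mean predicted probability and observed rate (squared Pearson
  r and MAE in percentage points).
- **all-data**: a single fit used for all SHAP relationship analyses.
- **holdout**: a label-stratified cohort (default 5,000–10,000 patients)
  is excluded from training and used as the fixed "same patients at
  every hospital" cohort.

The stroke team is one-hot encoded; moving a patient between hospitals
is a pure rewrite of the indicator block. Default hyperparameters are
100 rounds, depth 4, learning rate 0.3, λ = 1. Depth 4 (rather than a
deeper default) is a deliberate trade-off: exact SHAP interaction
tensors cost roughly exponential-in-depth per tree, and depth 4 keeps
the full-cohort tensor near 3 minutes on one CPU while leaving the
fitted log-odds surface expressive enough to span the generator's
extreme odds ratios. Fewer than ~100 rounds visibly attenuates the
recovered effect spans.

## 3. SHAP decomposition

Per-patient attributions use exact TreeSHAP with path-dependent
expectations (training data as background) as implemented natively by
XGBoost (`pred_contribs` / `pred_interactions`), all in log-odds:

- additivity: base value + Σ contributions = raw margin, per row;
- the interaction tensor is symmetric with halved off-diagonal terms;
  its diagonal is the main effect and row sums recover total SHAP;
- the hospital one-hot block is aggregated by summation on every axis
  into a single `stroke_team` pseudo-feature.

An independent brute-force oracle certifies the fast path on small
models: it parses the booster's JSON dump and enumerates all feature
coalitions, computing v(S) by cover-weighted recursive descent, then
applies the Shapley and pairwise-interaction weightings directly. The
oracle refuses more than 12 features. One numerical subtlety: the JSON
dump prints float32 thresholds as shortest round-trip decimals, so both
thresholds and inputs are passed through float32 before comparison to
reproduce the booster's branching exactly. Agreement with the fast path
is ~1e-7; the acceptance tolerance is 1e-6.

**Subset SHAP.** Under a named feature partition, a feature keeps its
main effect plus interactions with same-subset partners only; crossing
interactions are excluded and tracked as `cross_subset_mass`. The
all-in-one partition therefore reduces to total SHAP values and the
singleton partition to main effects (both exact to 1e-9).

**Fold changes.** The relationship between a feature's values and its
SHAP values is summarised as binned medians/IQRs. For a span quoted
between feature-value endpoints (e.g. "over the first 120 min"), the
bin-median comparison is biased low — a bin's median SHAP sits at the
bin's median feature value, not its edge — so the package also reports
an endpoint estimate: a weighted least-squares line through the (bin
midpoint, median SHAP) points, evaluated at the endpoints.

## 4. Hospital analyses

- Mean SHAP main effect of the hospital attended, per hospital, with
  process-descriptor correlates (OLS slope, r², unadjusted p).
- Counterfactual cohort: the held-out cohort is sent to every hospital
  in turn and the mean predicted probability recorded. A leakage guard
  rejects cohorts overlapping the training rows. Because the interaction
  tensor is the expensive step, the counterfactual per-hospital main
  effect is averaged over a fixed seeded subsample (default 300 rows,
  identical rows at every hospital).

## 5. Variance partition

Each feature is assigned to a patient subset (characteristics of the
person) or a hospital subset (hospital attended and arrival-to-scan
time, a process the hospital controls). Subset SHAP sums are averaged
per hospital and the observed thrombolysis rate (percentage points) is
regressed (OLS, hospitals weighted equally) on the patient mean, the
hospital mean, and both. The combined fit's r² is never below either
single fit by nesting.

## 6. Subgroups

Eleven subgroups: one "ideally thrombolysable" profile, nine single
sub-optimal features, and low-severity-with-estimated-onset. Time
windows are half-open, the NIHSS 10–25 band inclusive, and "age 80+"
means a band midpoint ≥ 80. Observed matrices use label means per
hospital/subgroup (cells under 5 patients are masked); predicted
matrices reuse the counterfactual reassignment. Rates are summarised
across hospitals as five-number summaries.

## 7. Problem sizes and numerical choices

Defaults were chosen for a single-CPU desk machine; all are package
choices, configurable in `GeneratorConfig` / `ModelConfig` / `RunConfig`:

- default study: 30 hospitals × 700 patients ≈ 21,000 rows;
- holdout cohort 5,000 in the pipeline (configurable up to 10,000);
- repeated-seed analyses use seeds 1–5; the variance-partition null
  experiment runs at 30 × 150 per seed to keep five interaction tensors
  affordable; the selection-recovery experiment uses 3-fold pooled AUC,
  30 rounds, and a 10-round selection cap at the full default scale;
- float64 throughout the analysis layer (XGBoost's float32 outputs are
  upcast on entry); structural identities (additivity, row sums,
  symmetry) hold to ~1e-5 in float32 accumulation, asserted at 1e-3;
  algebraic reductions (subset SHAP) are exact to 1e-9.

## 8. Limitations

- SHAP attributions are in-sample for the relationship analyses (a
  deliberate design choice: the quantities of interest are descriptive
  decompositions of the fitted surface, not out-of-sample estimates).
  With many one-hot team indicators the booster
  absorbs part of each hospital's label noise, so hospital-subset SHAP
  means correlate with observed rates even when all true hospital
  effects are zero; the variance partition is therefore a descriptive
  decomposition, not a causal test against a null of no hospital effect.
- The two weakest generator effects (age, onset-to-arrival) contribute
  odds spans of only ~1.3–1.6× over their observed ranges; greedy
  forward selection cannot reliably rank them above the best of many
  pure-noise candidates, which bounds what decoy-recovery experiments
  can demonstrate at this scale.
- Effect recovery shrinks toward zero at the extremes of sparse feature
  ranges (boosting regularisation), so recovered fold changes sit at the
  low end of their theoretical bands.
- The generator's hospital offsets act additively on log-odds; real
  hospitals may differ in feature-conditional policies that an additive
  offset cannot represent.
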