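# Methods

## Study design emulated

The package implements a population-based case-control analysis of acute
kidney injury (AKI) risk from drug-class co-initiation. Patients are
screened for an eligible serum-creatinine (SCr) run — at least 3
measurements within 14 days, consecutive gaps ≤ 7 days, and a < 50% change
between the 1st and 2nd measurements (|SCr₂−SCr₁|/SCr₁; drops and rises
both disqualify, since the direction is a design choice the rule leaves
open). The 2nd measurement of the earliest eligible run is the baseline.
A patient is a **case** when any post-baseline measurement rises ≥ 0.3
mg/dL within 48 h of baseline or reaches ≥ 1.5× baseline within 7 days
(the SCr arms of the KDIGO definition); the earliest qualifying
measurement date is the event (index) date. Controls take the 3rd
measurement of the eligible run as their reference date. Records with age
< 18, baseline SCr strictly above 5.0 mg/dL, or a pre-existing
kidney-disease code (configurable ICD-10 list; default CKD stage ≥ 3,
diabetic nephropathy, unspecified kidney failure) strictly before baseline
are excluded. Conventions the rules leave open and our resolutions:

* "increased by 0.3 mg/dL" is inclusive (≥ 0.3), the usual KDIGO reading;
* time is resolved in integer study days, so "within 48 h" means
  index − baseline ≤ 2 days and the 7-day ratio window means ≤ 7 days;
* with several eligible runs the earliest is used;
* when both criteria fire on the same (earliest) date the 48-h delta
  criterion is recorded as the trigger.

## Features

A drug class is "use" when newly started 1–7 days (default window) before
the index date; a start on the index date itself is non-use (reverse-
causality guard), as is a start 8+ days before. "Newly started" is
operationalised as the earliest recorded event of the class on or before
the index date that has no same-class event within the preceding washout
(180 days by default); under the package's unbounded lookback this is the
patient's first recorded event of the class, and later events are treated
as continuations of that course. Product terms are the elementwise AND of
the two class indicators over all C(32,2) = 496 unordered pairs; product
columns with no case support are dropped (496 − 88 = 408 in the emulated
study, giving the 32 + 408 + 5 + 7 = 452-column width). Covariates: age in
years untransformed, a male indicator, three hospital one-hot columns, and
seven pre-baseline comorbidity indicators (hypertension, diabetes, heart
failure, anemia, sepsis, CKD stage ≤ 2, chronic liver disease). The
empty-case filter runs after the exclusion criteria, i.e. on the final
cohort.

## Penalized logistic core

The lasso uses the glmnet objective `(1/n)·NLL + λ‖β‖₁` with an
unpenalised intercept. Columns are scaled to unit population SD without
centering — with a free intercept this is exactly equivalent to full
standardization for an L1-penalised linear model — and coefficients are
reported back on the original scale with exact zeros preserved. λ descends
a log grid of 100 values (default) from the data-driven maximum
`max|x_jᵀ(y−ȳ)|/n` (the smallest all-zeroing penalty) over three decades,
and is selected by stratified 10-fold cross-validation minimising
misclassification error at the 0.5 probability cutoff. At ~8% prevalence
this error curve can have flat stretches (the all-negative classifier is a
local plateau), so exact ties are broken toward the **largest** λ: with
pure noise every λ ties and the intercept-only model is returned, while
any real signal that moves the error selects the penalty that earns it.

Numerics: liblinear coordinate descent (the fastest exact solver for this
sparse binary design by a wide margin); the intercept rides along as a
pseudo-feature with `intercept_scaling=100` and is then refined by an
unpenalised 1-D Newton step, which removes the residual intercept
shrinkage that otherwise appears at very large penalties. At a fixed λ the
fit matches R glmnet (`standardize=TRUE`, `thresh=1e-12`) to < 0.015 on
every coefficient with identical zero patterns (tested). The CV path runs
at tolerance 1e-2 — fold-level misclassification counts are insensitive to
late solver digits (verified: identical error curves at 1e-4) — and the
final and bootstrap fits at 1e-7 and 1e-2 respectively.

Comparators (unpenalised logistic regression, random forest,
gradient-boosted trees, linear- and RBF-kernel SVMs with fold-calibrated
sigmoid probabilities) share a uniform fit/predict-probability contract
and are tuned by grid-search CV; they exist for metric comparison and SHAP
interpretation, not for the interaction inference itself.

## Interaction inference

`RERI = e^(β̂₁+β̂₂+β̂₃) − e^(β̂₁) − e^(β̂₂) + 1`; zero means no additive
interaction. RERI is invalid when either individual adjusted OR is below 1;
a coefficient shrunk exactly to zero gives OR = 1.000, which passes.
CIs come from a percentile bootstrap: B resamples of the training set
(each of the original size) are refit **at the λ selected on the original
training set** — re-tuning λ inside each resample would multiply the cost
by the grid size for no stated benefit, and the refit-at-fixed-λ variant
is the documented default. For B = 2,000 the 95% CI is the 50th and
1,950th order statistics; for general B the 1-based indices are
⌈0.025·B⌉ and ⌊0.975·B⌋, consistent with 50/1950 at B = 2,000. A pair is
flagged as a positive interaction iff the product-term OR CI lower limit
exceeds 1 and the RERI CI lower limit exceeds 0. Candidate pairs default
to all retained product terms with nonzero β̂₃.

SHAP attributions for the tree model are computed with the
tree-path-dependent TreeSHAP algorithm on the margin (log-odds) scale —
no background dataset is needed — and aggregated as mean |SHAP| per
feature; the additivity identity (per-patient SHAP sum + base value =
margin) is asserted in tests.

## Evaluation battery

Brier score = mean squared error between outcome and predicted
probability, bootstrap CI over patients. AUROC is the tie-aware rank
statistic with a DeLong-variance Wald CI; AUPR is average precision with a
bootstrap CI. Calibration is assessed by logistic recalibration —
regressing the outcome on the logit of the prediction (probabilities
clipped at 1e-6) — whose slope and intercept carry the usual targets of 1
and 0; a slope below 1 means predicted risks are too extreme. (A
calibration plot described with "actual probability on the X-axis and log
odds on the Y-axis" is nonstandard; standard logistic recalibration is
implemented because it carries exactly the stated 1/0 targets and
interpretation.) Classification metrics are confusion-matrix rates at a
configurable threshold, defaulting to Youden's J resolved on the training
set, since no operating threshold is otherwise specified. Robustness
curves refit on stratified training subsamples (10%…100%) against a fixed
test set. Model comparisons use the paired DeLong test for AUROC and a
paired percentile-bootstrap test for AUPR.

## Synthetic-data generator

The generator is first-class, tested code; it defines the study
conditions for every downstream check.

* **Outcome model.** `logit p = α + log(or_a)·x_a + log(or_b)·x_b +
  log(or_product)·x_a·x_b + covariates`, with defaults or_a = 2.018,
  or_b = 1.000, or_product = 1.639 for the planted loop-diuretic ×
  H2-blocker pair (implied true RERI = 1.2895). α is calibrated by root
  finding so the realized case fraction matches the 8.1% target.
  Covariate effects (age 0.02/yr, male 0.50, seven comorbidities with
  log-ORs 0.36–1.98) are the conditional effects implied by the emulated
  case/control marginals.
* **Planted exposures.** The pair's start indicators share a mean-one
  lognormal co-prescription frailty (σ = 0.9, co-start lift ≈ 2.2),
  reflecting that in-hospital drug starts cluster within sick patients;
  marginal start probabilities are 0.025 and 0.122.
* **Other 30 classes** are drawn conditional on the realized label with
  the emulated case/control prevalences. Because they are independent of
  everything else given the outcome, Bayes' rule keeps the conditional
  outcome model exactly logistic-additive in every feature — the planted
  coefficients remain the estimands, no spurious product effects are
  induced, and two strong risk factors still show the positive additive
  RERI that multiplicative joint effects imply (which the dual rule's
  product-OR condition correctly refuses to flag).
* **SCr trajectories** are constructed directly (no rejection sampling):
  case series receive a criterion-satisfying post-baseline value (Δ ∈
  [0.32, 0.9] mg/dL within 2 days, or 1.55–2.2× baseline within 3–7
  days), control series stay below min(0.29, 0.45·baseline) above
  baseline so neither criterion can fire even after rounding to the 2-dp
  assay resolution. 10% of patients are decoys violating the eligibility
  screen (two tests only, an 8-day gap, or ≥ 50% baseline instability);
  small fractions carry exclusion-triggering ages, baselines > 5 mg/dL,
  or pre-existing kidney-disease codes so every filter is exercised.
  Dates are integer study days; identical seed and config give
  byte-identical tables.

**What the generator does not emulate:** real measurement-frequency
patterns (the inter-test gap distribution is a free parameter), seasonal
or calendar structure, dose/duration/route, hospital-specific coding
practice, time-varying confounding, or misclassified exposures from care
received elsewhere. Passing tests therefore demonstrate that the pipeline
recovers the quantities its own assumptions define — not that those
assumptions hold in any particular hospital system.

## Problem sizes used in the test suite

Unit fixtures use an 8,000-patient study; the planted-interaction
recovery check runs the full pipeline at 50,000 generated patients
(≈ 44,000 eligible after decoys and exclusions) with a 40-value λ grid,
10-fold CV and B = 500 bootstrap refits, and checks the planted pair plus
20 null pairs; bootstrap coverage is verified over 500 Monte-Carlo
repeats at B = 2,000. The end-to-end pipeline smoke test runs at 1,200
patients with reduced grids.

## Known limitations

* The validity rule gates RERI on the point estimates of the individual
  ORs; pairs near OR = 1 can flip validity across reruns.
* Bootstrap CIs inherit lasso shrinkage: RERI point estimates are biased
  toward 0 at small n or large λ (visible as ~0.14 underestimation at the
  50,000-patient test scale).
* The washout parameter only matters under a finite lookback horizon; with
  the default unbounded horizon the first recorded event of a class is its
  start.
* SVM probabilities come from sigmoid calibration and are approximate;
  the SVMs are comparators only.
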