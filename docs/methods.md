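# Methods

## The screening question

Single-measurement qSOFA on arrival at the emergency department (ED) is a
specific but insensitive sepsis screen. This package evaluates a two-point
alternative: score qSOFA once from ambulance (prehospital) vitals and once
from ED-arrival vitals, and screen on their sum — the *combined qSOFA*
(range 0–6, positivity at ≥ 3). The analysis compares prehospital, ED and
combined qSOFA as predictors of sepsis (and, as secondary outcomes, septic
shock and in-hospital mortality) in an ambulance-transported
suspected-infection cohort, using c-statistics with DeLong variances, paired
DeLong tests against ED qSOFA, per-cutoff sensitivity / specificity / PPV /
NPV with Wilson CIs, a prehospital→ED score-transition table, and the
*added capture* statistic: outcome-positive patients with combined qSOFA ≥ 3
but ED qSOFA < 2, i.e. patients a single ED measurement would miss.

## Pipeline and stage order

`run()` / `QsofaScreeningModel.fit()` execute: cohort construction →
surveillance outcome labelling → random-forest imputation → qSOFA scoring →
evaluation. Labelling precedes imputation because the imputer uses the
outcome labels as predictors (see below); scoring follows imputation so that
no score is computed from a null vital.

### Cohort construction

Inclusion: age ≥ 18 (completed years, boundary inclusive) and suspected
infection — chief complaint of fever OR body temperature ≥ 37.5 °C OR an ED
infection diagnosis. The temperature clause is evaluated on the ED value by
default; `bt_stages` can widen it to either stage (the source data leave the
stage ambiguous). A null temperature simply fails the clause. Exclusions, in
a fixed precedence order that affects only reason attribution, never
membership: trauma, cardiac arrest, death on arrival, transfer to another
hospital, and ≥ 6 of the 7 vital parameters (sBP, dBP, HR, RR, BT, GCS,
SpO2) missing at either stage. The flow object proves conservation: every
input record lands in exactly one bin.

### Surveillance sepsis labelling

Retrospective cohorts rarely support the operational Sepsis-3 definition
(ΔSOFA ≥ 2), so sepsis is labelled by the EHR-computable clinical
surveillance definition of Rhee et al.: *presumed serious infection* (blood
culture obtained AND ≥ 4 qualifying antimicrobial days) AND ≥ 1 acute
organ-dysfunction criterion within ± 2 days of the culture day — vasopressor
initiation, mechanical-ventilation initiation, lactate ≥ 2.0 mmol/L,
creatinine doubling (ESRD excluded), bilirubin ≥ 2.0 mg/dL and doubled, or a
platelet nadir < 100 ×10³/µL with ≥ 50 % decline from a baseline ≥ 100.
Every threshold and the window are named `SurveillanceConfig` entries, so a
locally modified variant of the rule can be expressed exactly. All
boundaries are inclusive (lactate exactly 2.0 qualifies). `criteria_met`
records rule provenance per patient. Septic shock is not defined by the
surveillance rule; the package's documented default is Sepsis-3-consistent:
sepsis AND vasopressor AND lactate ≥ 2 mmol/L. In-hospital mortality is the
recorded disposition, never inferred.

### Imputation

Missing vitals (2–33 % per column in the motivating data) are imputed with
iterated conditional random forests (missForest-style): initial mean fill,
then per-column RandomForestRegressor fits in order of increasing
missingness, iterating until the normalised change between successive
imputations stops decreasing (the previous iterate is kept when it rises)
or `max_iterations` is reached. Defaults: 100 trees, ≤ 10 iterations, single
completed dataset. Predictors: age, sex, all 14 stage-vitals, oxygen
therapy, and the three outcome labels. Including outcomes as predictors is
deliberate and matches the analysis this package reproduces; it leaks
outcome information into the scores and can flatter discrimination, so
`include_outcomes_as_predictors=False` is available for leakage-sensitive
use. GCS is imputed on its ordinal scale, then rounded and clipped to
[3, 15]; altered mental status (AMS) is derived afterwards as GCS ≤ 14.
Observed cells are preserved bitwise; tree predictions are convex
combinations of observed values, so imputations stay within each column's
observed range. `multiple_impute` produces several independently seeded
completed datasets, but pooling across them is out of scope.

### Scoring and evaluation

qSOFA components: sBP ≤ 100 mmHg, RR ≥ 22 /min, GCS ≤ 14 — all inclusive,
all config-exposed constants. The c-statistic is the Mann–Whitney pair
probability with ties counted ½; an ROC built over all observed integer
thresholds with trapezoidal integration equals it, and the test suite
asserts that equivalence against exhaustive pair counting. AUC variance and
the paired comparison of two correlated AUCs use DeLong's
structural-components method (implemented here; verified against R pROC,
a delete-one jackknife, and a stratified-bootstrap oracle). AUC CIs use the
normal approximation clipped to [0, 1] (logit-scale CI by flag); proportion
CIs default to Wilson (exact/Wald selectable). p-values are two-sided with
no multiplicity adjustment. A note on conventions: per-cutoff rows report
sensitivities, while the c-statistic is the cutoff-free AUC — the two are
kept strictly distinct in all outputs. Report tables round to 2 decimals.

## The synthetic cohort generator

No patient-level data are deposited for this problem, so the generator is a
first-class, tested module that emulates the *marginal* structure of the
motivating cohort and makes the joint structure explicit and tractable:

- **Latent outcomes.** Sepsis ~ Bernoulli(0.15); septic shock nested within
  sepsis (marginal 0.06); death probabilities 0.35 / 0.20 / (solved to give
  a 0.09 marginal) given shock / non-shock sepsis / neither.
- **Continuous vitals** (sBP, dBP, HR, RR, BT, SpO2, each at both stages):
  truncated normals parameterised by the cohort's published medians and
  IQRs (scale = IQR/1.349), with wide physiologic truncation bounds. The
  prehospital and ED values of one vital share a Gaussian copula with
  `stage_correlation` (default 0.6 — vitals measured roughly an hour apart).
  SpO2 marginals (median 96, IQR 93–98 ED; 95, 92–98 prehospital) and its
  2 % missingness are simulator choices; the source tables omit them.
- **Sepsis effect sizes** are additive location shifts (sBP −10, dBP −5,
  HR +5, RR +2.5, BT +0.2, SpO2 −1.5) plus an AMS probability shift of
  +0.18. The magnitudes are not published anywhere; they were calibrated
  once, analytically, so that the combined-qSOFA AUC for sepsis at default
  settings is ≈ 0.68 (the realistic operating point for this screen), then
  frozen. AMS per-status probabilities are back-solved from the marginal
  targets (45 % ED, 47 % prehospital).
- **GCS** is a two-part mixture: 15 when not AMS, else a geometric-decay
  distribution over 3–14 mapped from the same latent normal that triggers
  AMS, so stage-to-stage GCS changes are coherent.
- **Missingness** is MCAR at the published per-column rates (printed
  percentages, e.g. 33 % for ED AMS) by default; a MAR option multiplies
  the missingness odds of AMS-positive patients (`mar_odds_factor`) for
  robustness testing.
- **ICU courses** are generated conditionally on the latent state so the
  surveillance labeller recovers it with configurable fidelity
  (`labeler_sensitivity`/`labeler_specificity`, default 1.0/1.0: latent
  sepsis cases always receive a qualifying course — lactate ≥ 2 in-window,
  vasopressors reserved for latent shock — and controls never do). Exact
  label recovery at fidelity 1.0 is a tested invariant.

Because every qSOFA component is a threshold indicator of a Gaussian-copula
pair, the joint law of (prehospital, ED) qSOFA given sepsis status has a
closed form in bivariate-normal orthant probabilities
(`stage_score_joint_pmf`, `true_auc`, `true_sensitivity`). This exact law —
for scores computed from complete, pre-missingness vitals, which the
generator also records as `*_true` columns — is the oracle for the
coverage and sensitivity recovery tests.

**What the generator does not emulate:** ambulance transport-time dynamics,
physiologic time-series structure, real joint dependence between different
vitals (they are independent given sepsis status), MNAR missingness, and
mortality risk beyond its dependence on the sepsis/shock state (given the
latent state, death is independent of the vitals, so the simulated scores
discriminate mortality more weakly than real cohorts do). Passing tests
therefore validate the *machinery* — rules, imputation behaviour, estimator
correctness, CI coverage — not the transportability of any particular
accuracy number to real patients.

## Numerical and design choices

- Truncated-normal location is set to the published median and scale to
  IQR/1.349; for these mild truncations the induced median/IQR distortion is
  negligible, and threshold indicator probabilities are computed exactly
  through the truncated CDF, so the closed-form score law is exact, not
  approximate.
- Cohort CSVs are written with `%.17g` floats and read with round-trip
  float parsing, so file-mode and in-memory pipelines agree bitwise; nulls
  are empty strings; booleans are 0/1.
- A single `RunConfig.seed` fans out via `numpy.random.SeedSequence` to the
  simulation and imputation seeds; stages rerun individually with those
  seeds reproduce the monolithic run exactly (tested).
- DeLong test with zero variance of the AUC difference (e.g. identical
  scores) reports z = 0, p = 1, with a warning when the AUCs differ.
- PPV/NPV with empty denominators are reported as undefined (NaN, flagged),
  never as 0.
- Degenerate inputs (single-class labels, empty cohorts, duplicate ids)
  raise typed errors before any computation.

## Problem sizes used in the shipped checks

The test suite exercises cohorts of 400–2 500 patients (one 40 000-patient
draw for the closed-form cross-check) with 15–50 trees for the imputer; the
full-scale reproduction script (`scripts/acceptance.py`) runs the complete
default analysis — n = 2 407, 100 trees — in a few minutes on one core.
These sizes are the package's own defaults for a fast, deterministic check;
all of them are configuration, not code.

## Known limitations

- The "modified" clause of the surveillance definition used by the
  motivating study is not fully public; this package ships the published
  Rhee criteria as defaults and exposes every threshold for exact local
  alignment.
- Whether the motivating analysis generated one or several completed
  datasets is ambiguous; the default here is one (`n_datasets` supports
  more, without pooling).
- Single-stage evaluation of the temperature inclusion clause (ED) is an
  assumption; configurable but unverifiable from the source.
- The alluvial presentation of score transitions is replaced by an exact
  counts table (`transition_table`); plotting is intentionally minimal.
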