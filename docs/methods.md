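# Methods

This note records the statistical model behind each pipeline stage, the
assumptions that make claims data interpretable, the choices in the
synthetic-claims generator, and the numerical conventions used throughout.

## 1. Case identification

A patient is a UC case if they have at least one non-suspicion-flagged
ICD-10 K51.x diagnosis and no K50.x (Crohn's disease) code anywhere in
their record. Suspicion flags ("rule-out" diagnoses) are a standard
feature of Japanese-style claims; counting them as cases would inflate
the cohort with diagnostic work-ups. The Crohn's exclusion is applied
over the whole record, not just before onset, because a later K50 code
usually reflects diagnostic reclassification rather than a second
disease. Malformed ICD-10 strings are skipped and counted, never
silently coerced.

## 2. New-user design and the onset proxy

Claims do not record disease onset. The proxy used here is the earliest
**new** prescription of a UC induction drug (5-aminosalicylate, systemic
steroid, or topical steroid), where *new* means no same-drug
dispensation in the preceding 26 weeks (182 days). The washout
comparison is strict: a prior dispensation exactly 182 days earlier
leaves the prescription new; only gaps shorter than 182 days mark it
old.

A patient with *any* old prescription of a qualifying class is excluded
as prevalent rather than new-onset. This is deliberately conservative:
it refuses to guess an onset date for patients whose induction-drug
history predates or straddles the observation window. Patients whose
estimated onset falls within 182 days of their observation start are
additionally flagged (`lookback_short`), since their washout window is
not fully observable.

Consequence worth stating plainly: under this rule a patient on
ordinary maintenance 5-ASA refills (e.g. monthly) accumulates old
prescriptions and is excluded. Identification of new-onset cases
therefore leans on the washout structure of the data, and the synthetic
generator (section 6) must dispense qualifying drugs in long-cycle
supplies for its new-onset patients to survive their own refills.

## 3. Exposure episodes

Dispensations of one drug are chained into episodes by comparing each
dispensation date with the previous **next scheduled date**:

- fixed-cycle biologics: 8 weeks (infliximab, vedolizumab) or 12 weeks
  (ustekinumab) after the last dispensation, regardless of quantity;
- self-injected anti-TNFs (adalimumab, golimumab): dispensed count × 14
  days;
- all other drugs: dispensed days of supply.

Weeks are exactly 7 days. Same-day dispensations of one drug are merged
with quantities summed before scheduling. A refill on or before the
scheduled date + 91 days (13 weeks) continues the episode; a strictly
longer gap closes it as **discontinued** with the episode end set to the
scheduled date (the last day the regimen was still covered/expected).
The trailing episode is **ongoing at censoring** when the administrative
censor date falls within the same 91-day grace window. `covered_days`
is the size of the union of per-dispensation coverage intervals clipped
at the censor date, so overlapping early refills are not double-counted.

The engine is verified against a brute-force oracle that replays the
rules prescription by prescription, over randomized configurations of up
to 5 claims per drug-rule class, with exact (not approximate) agreement
required.

## 4. Cohort and outcome definitions

- **EO** (elderly onset): age ≥ 65 completed years at onset.
- **NEO**: onset before 65, age ≥ 65 by the end of observation.
- Ages use month-granular birth dates with the day fixed to 1, so the
  birthday is counted as passed from the first of the birth month.

Outcomes are measured from onset: time to first systemic-steroid
episode, first MTD (molecular-targeting drug: biologic or small
molecule) episode, surgery, and death. Death is primarily an indicator
outcome (logistic model); the death date, when present, censors the
time-to-event outcomes.

## 5. Statistical methods

- **Kaplan–Meier** product-limit curves per onset group, read at the
  5-year mark (1826 days); pointwise standard errors by Greenwood's
  formula. Group curves are compared with the **log-rank** test.
- **Cox proportional hazards** (partial likelihood, Efron tie handling —
  claims dates are day-granular with heavy ties) for steroid, MTD, and
  surgery; covariate sets follow the conventional adjustment ladder
  (sex, onset group, facility type, then prior steroid / MTD use for the
  downstream outcomes). Hazard ratios carry Wald 95% intervals.
- **Logistic regression** for death, reporting odds ratios with Wald
  intervals. When the default covariate set is used, covariates that
  are constant in the sample or completely separated from the outcome
  are dropped with a warning; explicitly requested covariates instead
  fail loudly (`DegenerateFitError`), because silently altering a
  requested model would hide an error.
- **Categorical comparisons** between onset groups use the Pearson
  chi-square without continuity correction; Fisher's exact test is also
  exposed because the two can differ materially on sparse mortality
  tables (for the EO/NEO death table the Pearson p is ≈ 0.0029 while
  Fisher's exact p is ≈ 0.0011).
- Medians and interquartile ranges use linear interpolation
  (`numpy.percentile` default).
- Percentages are reported to one decimal with half-up rounding.

## 6. Synthetic-claims generator

The generator emits a realistic claims bundle whose defaults are
calibrated to the headline findings for elderly-onset UC:

- onset ages from a two-component normal mixture (young and elderly
  components) so both onset groups are populated;
- 5-year steroid-free survival 0.576 (EO) and 0.686 (NEO), implemented
  as exponential time-to-steroid hazards, λ = −ln S₅ / 5 per year;
  analogous calibrations for MTD use and surgery;
- death as a Bernoulli draw from a logistic model with baseline
  probability 0.72%, odds ratio 6.18 for elderly onset and 1.65 for
  steroid exposure; a drawn death truncates all later records and closes
  the observation window;
- first-MTD choice from a realistic market-share breakdown (infliximab
  ≈ 31%, vedolizumab ≈ 20%, …), refill trains per catalog rule with
  small one-sided jitter, a second-line switch probability, and
  azathioprine combination therapy anchored at the infliximab start.

Realism choices forced by the onset rule (section 2): new-onset
patients receive 5-ASA as 27-week (189-day) supplies so that every
refill clears the 182-day washout, and steroid courses are dispensed as
single prescriptions. Non-qualifying drugs (biologics, small molecules,
azathioprine) use ordinary short-cycle refill trains. Prevalent
patients, by contrast, are given monthly-style 5-ASA refills precisely
so the washout rule excludes them.

Limitations: the generator does not model dose tapering, switching back
to an earlier drug, informative censoring, or within-patient correlation
between outcomes beyond the steroid→death pathway; steroid exposure
affects death but MTD exposure does not. Event-time distributions are
exponential, so the proportional-hazards assumption holds by
construction — the Cox recovery checks validate the estimator, not the
assumption.

## 7. Numerical conventions

- All dates are `pandas.Timestamp` at day granularity; durations are
  integer days. A "week" is exactly 7 days; 26 weeks = 182 days,
  13 weeks = 91 days; the 5-year readout is 1826 days.
- Episode construction merges same-day claims first, then applies the
  grace-window comparison with closed inequality (≤ scheduled + 91 d
  continues).
- Randomness flows from a single `numpy.random.default_rng(seed)` per
  generator run; the acceptance script derives per-experiment seeds as
  `default_rng([seed, k])` so experiments are independent and
  individually reproducible.
- Stochastic calibration checks accept a Greenwood 95% band (KM) or
  three Wald standard errors (effect recovery); by construction a 95%
  band check fails for ≈ 5% of seeds even when the implementation is
  exact.
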