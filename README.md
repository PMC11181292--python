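# ucclaims

Cohort construction and outcome analysis for **elderly-onset ulcerative
colitis (UC)** from administrative prescription/diagnosis claims, together
with a calibrated synthetic-claims generator so the whole pipeline can be
run, tested, and benchmarked without access to any proprietary database.

## The scientific problem

Administrative claims databases record diagnoses and drug dispensations but
not clinical onset, disease activity, or treatment decisions. Studying
elderly-onset UC from claims therefore requires a chain of algorithmic
proxies, each with sharp, auditable rules:

- **Case identification.** UC cases are patients with a confirmed (not
  "suspicion-flagged") ICD-10 K51.x diagnosis and no K50.x (Crohn's
  disease) code anywhere in their record.
- **New-user design.** A prescription is *new* if the same drug was not
  dispensed in the preceding 26 weeks (182 days); the washout window is
  half-open, so a prior dispensation exactly 182 days earlier still counts
  as new. Disease onset is proxied by the earliest new prescription of a
  UC induction drug (5-aminosalicylate, systemic or topical steroid); a
  patient with any *old* prescription of those classes is treated as a
  prevalent (not new-onset) case and excluded.
- **Onset groups.** Elderly onset (EO) = age ≥ 65 at onset; non-elderly
  onset (NEO) = onset before 65 in a patient who reaches 65 during
  observation. Ages are completed years from a month-granular birth date.
- **Exposure episodes.** Dispensations of one drug are chained into
  episodes using drug-specific refill schedules (fixed 8- or 12-week
  cycles for most biologics, count × 14 days for self-injected
  anti-TNFs, dispensed days for oral drugs). An episode ends in
  *discontinuation* when no refill arrives for more than 13 weeks
  (91 days) past the next scheduled date; a gap of exactly 91 days still
  continues the episode.
- **Outcomes.** Time from onset to systemic steroid initiation, first
  molecular-targeting drug (MTD: biologic or small molecule), and surgery
  are analysed with Kaplan–Meier curves, log-rank tests, and Cox
  proportional-hazards models; death is analysed with logistic
  regression. Persistence on the first MTD is measured from episode
  start to discontinuation.

The synthetic generator emits a full claims bundle (patients, diagnoses,
prescriptions, events) whose default parameters reproduce the headline
findings of the elderly-onset UC literature: ~34% MTD use, ~4.5% mortality
in the EO group, 5-year steroid-free survival of 57.6% (EO) vs 68.6%
(NEO), an EO→steroid hazard ratio of 1.38, and death odds ratios of 6.18
(elderly onset) and 1.65 (steroid use).

## Running the tests

```bash
python -m pytest -q tests/
```

The suite contains unit tests, property-based tests (hypothesis,
derandomized), brute-force oracle comparisons for the episode engine and
every statistical routine, and end-to-end calibration checks.

## Worked example

Generate a 3 000-patient synthetic claims bundle, extract the cohort, and
analyse steroid-free survival:

```bash
$ ucclaims simulate --n 3000 --seed 0 --out demo/claims
wrote 3000 patients to demo/claims

$ ucclaims build-cohort --claims demo/claims --out demo/cohort
retained 1895 of 3000 patients

$ ucclaims survival --cohort demo/cohort/cohort.tsv --outcome steroid --out demo/km
log-rank chi-square 16.71, p = 4.353e-05

$ ucclaims fit --cohort demo/cohort/cohort.tsv --outcome steroid --out demo/steroid.tsv
outcome               family     covariate  estimate   ci_low  ci_high        p   se_log
steroid proportional_hazards        female  1.011724 0.892120 1.147362 0.855916 0.064190
steroid proportional_hazards elderly_onset  1.422910 1.200975 1.685857 0.000046 0.086517
steroid proportional_hazards      academic  0.843164 0.271360 2.619865 0.768054 0.578438
```

Reading the Kaplan–Meier output (`demo/km/km_steroid.tsv`) at five years
gives steroid-free survival of 0.558 (EO) versus 0.657 (NEO) — the
generator's calibration targets are 0.576 and 0.686, and the fitted
elderly-onset hazard ratio of 1.42 matches the ratio those two survival
levels imply (ln 0.576 / ln 0.686 ≈ 1.46) within its confidence interval.

The same run as a single command, writing every artifact (cohort,
episodes, KM curves, model tables, summary tables, run log):

```bash
ucclaims run-all --out demo/run --seed 0 --n 3000
```

Or from Python:

```python
from ucclaims import GeneratorConfig, generate_claims, build_cohort, default_catalog

catalog = default_catalog()
bundle = generate_claims(GeneratorConfig(n_patients=3000, seed=0), catalog)
cohort, episodes, tally = build_cohort(bundle, catalog)
```

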