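# Methods

## Case-definition engine

A case definition is a conjunction of criteria over one patient's
date-stamped coded events (`AlgorithmSpec`):

1. at least `min_core_dx` **distinct calendar dates** bearing a core eczema
   diagnosis code (two core codes on one day are one coded occasion;
   `core_dx_distinct_dates=False` switches to counting events, since
   published wording does not settle the same-day case);
2. at least `min_treatment_dates` distinct dates bearing any
   eczema-directed treatment code ("two treatment codes on separate dates"
   is read as distinct dates: two drugs on one date count once);
3. of those, at least `min_specific_treatments` dates bearing a topical
   steroid or topical calcineurin inhibitor (TCI) code;
4. optionally a temporal window: some steroid/TCI event within
   `[dx − days_before, dx + days_after]` of some core diagnosis event,
   endpoints inclusive. "3 months" is mapped to 91 days and "1 year" to
   365 days (the source wording gives no day counts);
5. optional record-level flags: no exclusionary-condition code ever (the
   published wording carries no window, so the whole record is scanned),
   ≥1 atopy code, ≥1 dermatology-consult code.

Treatment events may precede the diagnosis; nothing is windowed to the
registration period by default (an opt-in `within_registration` filter
exists because source descriptions leave this open). The ten presets
(`baseline`, `steroid1`, `steroid2`, `window`, `twocodes`,
`twocodes_steroid1`, `twocodes_steroid2`, `no_exclusion`, `atopy`,
`derm_consult`) encode the published baseline and its nine variants. Every
variant only adds constraints, so variant positive sets are provably subsets
of the baseline positive set; the tests assert this on random cohorts and
check the engine against a subset-enumeration brute force on small patients.

Decisions carry per-criterion evidence (the events that satisfied — or, for
the exclusion criterion, violated — each rule), so a positive can always be
audited.

## Code lists

Codes are matched by exact string equality after trimming; an optional
alias table maps the print variants "M1120.0"→"M112.00" and
"M11400"→"M114.00". Categories: three nesting diagnosis tiers (core /
likely / possible), six treatment classes along British National Formulary
lines, exclusion, dermatology consult, atopy, procedure. Classification
precedence is fixed (diagnosis tiers, then steroid, TCI, emollient,
anti-infective, systemic, phototherapy, then exclusion, consult, atopy,
procedure), making classification deterministic and total. Cross-list
invariants (tier nesting; no code in both a diagnosis tier and the
exclusion list) are checked by `CodeRegistry.validate()`. Only the five
core codes are built in; supplementary lists are user files because they
are not part of the public record. Prefix matching for Read-code
hierarchies is deliberately absent: the definitions enumerate literal
codes.

## Ages and strata

Age is elapsed days / 365.25. The child stratum is the half-open interval
[0, 18) years at a reference date (default 2013-01-01). Dates are strict
ISO 8601.

## Dating

Onset is proxied by the age at the first core-diagnosis code and,
separately, the first treatment-category prescription of any class
(restricting to steroid/TCI only is not done — the inclusive treatment set
is the published convention); last activity by the last such codes. Absence
of a qualifying event yields an absent field, not an error. Any
cohort-selection conditioning (e.g. "no symptoms in the year before the
last visit") is the caller's filter, not part of the operation.

## Validation statistics

* **PPV**: confirmed / labelled positives, with a two-sided 95% CI.
  Default is the exact Clopper–Pearson interval (beta quantiles, with the
  conventional 0/1 endpoints at k = 0 / k = n); Wilson and Wald are
  available. Percent rendering rounds half-up to integers. Patients with a
  missing reference label (unreturned or blank survey) are excluded from
  numerator and denominator.
* **Detection fraction**: variant true positives / reference-confirmed
  cases; equals 1 iff the variant keeps every confirmed baseline case.
* **Proportion comparison**: Pearson χ² without continuity correction;
  the automatic rule switches to Fisher's exact test when any expected cell
  is below 5 (both tests can be forced). Zero-margin tables raise a
  degenerate-table error.
* **Bland–Altman**: differences are survey − database; mean, SD (ddof 1),
  95% CI of the mean as mean ± 1.96·SD/√n (the z approximation — at the
  n ≥ 53 of interest the t correction is < 2%), limits of agreement as
  mean ± 1.96·SD, optional mean-vs-difference plot.
* **Rank sum**: two-sided Wilcoxon rank-sum / Mann–Whitney U; exact null
  when both groups have ≤ 20 tie-free observations, otherwise the
  tie-corrected normal approximation without continuity correction (a
  fully tied pooled sample returns p = 1 by convention).

`validate_cohort` assembles these into a per-variant report (overall,
child and adult PPV, detection fraction against the confirmed reference
positives, child-vs-adult comparison), with notices instead of estimates
where a variant has no (labelled) positives.

Printed CIs from the original study are not reproduced as targets because
the interval method used there is not stated; only point estimates are
reconstructed.

## Synthetic-data generator

The generator emulates the recording features that matter to the pipeline,
with one `numpy` PCG64 stream per config seed (identical configs give
byte-identical CSVs):

| knob | default | basis |
|---|---|---|
| `child_fraction` | 0.5 | validation sampling design (100 children / 100 adults) |
| `case_prevalence` | 0.15 | UK lifetime AE prevalence; yields ~13–15% recorded core-code prevalence |
| `confirm_prob_given_positive` | 0.86 | the measured conditional a PPV study estimates |
| `dx_count_mean/sd` | 1.2 / 0.5 | database-wide per-patient core-code moments |
| `rx_count_mean/sd` | 16.3 / 24.5 | per-patient prescription moments (overdispersed) |
| `treat_noncase_rate` | 0.45 | calibrated to ~45% any-therapy population prevalence |
| `stray_dx_prob` | 0.002 | rare miscoded diagnosis on non-cases |
| `exclusion/atopy/derm_consult_prob` | 0.15 / 0.39 / 0.10 | "at least one such code" survey rates |
| `label_missing_prob` | 0.055 | 11 of 200 surveys unreturned/blank |
| `onset_lag_mean/sd` | 0.8 / 5.0 y | onset agreement structure |
| `last_activity_lead_mean/sd` | −1.3 / 4.5 y | last-activity agreement structure |

Design choices:

* **Core-code counts** are a 1-shifted negative binomial moment-matched to
  the configured mean/SD. A rounded truncated normal was rejected because
  truncation at 1 inflates the realised mean (~1.28 for 1.2/0.5); the
  shifted negative binomial reproduces both configured moments exactly on
  support {1, 2, ...}.
* **Prescription counts** are a negative binomial matched to mean 16.3,
  SD 24.5 (SD ≫ mean, so overdispersion is structural). Underdispersed
  moment pairs raise a config error suggesting the Poisson boundary case.
* **Confirmation labels** are independent Bernoulli draws on true cases.
  Because the draw is independent of the recorded codes, the conditional
  probability of confirmation given algorithm positivity equals the knob,
  without the generator needing to run the phenotyping engine. Since the
  label draw happens for every case regardless of the knob's value, a
  common seed couples the grid: raising the knob can only flip labels
  upward, which the monotone-calibration test exploits.
* **Survey-style truth ages**: the survey-reported onset age is the first
  recorded diagnosis age plus N(onset_lag_mean, onset_lag_sd), untruncated;
  last activity is the last recorded code age plus the lead offset. The
  positive default offset encodes that physician-recalled onset tends to be
  later than the first code, the negative lead that the last code tends to
  postdate recalled last activity. No truncation is applied so the planted
  mean is recovered without bias by the Bland–Altman closed loop; in the
  far tails this can produce physically impossible (pre-birth) survey ages,
  a deliberate simplification.
* Event dates are uniform over the patient's window after onset
  (prescriptions may start up to a year before the first code); calendar
  realism — seasonality, practice effects, consultation clustering — is out
  of scope.

What passing tests on this generator do **not** show: real Read-coded data
have correlated repeat coding (about a third of true patients accrue a
second code, more than the configured count moments imply under a
negative binomial), informative gaps, registration churn and richer code
vocabularies. The generator validates the machinery (counting rules,
subset structure, estimator calibration, closed-loop dating), not the
external validity of any variant's PPV.

## Problem sizes and numerics

The synthetic closure uses 10,000 patients (≈1,000 algorithm positives, so
the empirical PPV estimate has a standard error of ≈1.1 percentage
points); dating recovery uses 160 all-case patients, matching the onset
analysis size. Clopper–Pearson endpoints are beta quantiles (checked
against direct binomial-tail inversion to 1e-9); Fisher's two-sided p uses
the point-mass rule (checked against exact hypergeometric enumeration on
all small tables). Tie-breaks in dating are min/max over dates, so input
order never matters anywhere in the pipeline.

## Known limitations

* Sensitivity, specificity and NPV are structurally unavailable: the
  validation design samples algorithm positives only.
* Severity scoring and in-person diagnostic criteria are out of scope.
* The supplementary likely/possible/treatment/exclusion code lists are
  interfaces, not contents; users must supply their own files.
* The stricter variants' detection fractions on synthetic data differ from
  the published ones (e.g. the two-code variant keeps fewer synthetic
  cases) because repeat-coding correlation is not modelled.
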