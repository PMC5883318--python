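# aecase

Rule-based identification of atopic eczema (AE) cases in coded primary-care
electronic health records, with the validation statistics used to assess such
case definitions and a seeded synthetic coded-record generator for end-to-end
testing.

## The problem

Atopic eczema is chronic, episodic and heterogeneously coded, so finding AE
patients in routinely collected UK primary-care data (THIN, CPRD and similar
Read-coded databases) is error-prone: single diagnosis codes are rarely
repeated, and treatment codes alone are nonspecific. A validated pragmatic
case definition combines the two:

> **Baseline definition** — at least one of the five core eczema diagnosis
> Read codes (M111.00 atopic dermatitis/eczema, M112.00 infantile eczema,
> M113.00 flexural eczema, M114.00 allergic/intrinsic eczema, M12z100 eczema
> NOS) **and** codes for eczema-directed therapy (emollients, topical
> steroids, topical calcineurin inhibitors, topical anti-infectives,
> systemics, phototherapy) on at least **two separate calendar dates**, at
> any time relative to the diagnosis.

Nine stricter published variants (steroid/TCI-specific treatment counts, a
91-day-before/365-day-after window linking prescription to diagnosis, a
second diagnosis code, no exclusionary condition, an atopy code, a
dermatology consult) trade detection for positive predictive value.

The package is for pharmaco-epidemiologists and health-data researchers who
need to (a) apply and audit these case definitions on event-level data,
(b) date disease onset and last activity from first/last codes, and
(c) validate a definition against a reference standard: PPV with exact
Clopper–Pearson 95% CI, detection fraction
(variant true positives / reference-confirmed cases), χ²/Fisher group
comparisons, Bland–Altman agreement (mean difference ±1.96·SD/√n CI, limits
of agreement mean ±1.96·SD), and Wilcoxon rank-sum comparisons.

## Worked example

All stages are available as a library (`import aecase`) and as a CLI. With
synthetic data (no real records are needed anywhere):

```bash
aecase simulate --n 2000 --seed 7 --out demo
aecase phenotype --patients demo/patients.csv --events demo/events.csv \
    --codelists demo/codelists --algorithm baseline --out baseline.csv
aecase phenotype --patients demo/patients.csv --events demo/events.csv \
    --codelists demo/codelists --algorithm twocodes --out twocodes.csv
aecase date-events --patients demo/patients.csv --events demo/events.csv \
    --codelists demo/codelists --out dating.csv
aecase validate --results baseline.csv --labels demo/labels.csv \
    --variant-results twocodes=twocodes.csv \
    --dating dating.csv --truth demo/truth.csv
```

which prints (abridged):

```
baseline: 216/2000 positive (children 114, adults 102)
twocodes: 30/2000 positive (children 15, adults 15)
variant                 TP/pos  PPV%    95% CI child% adult% detect%
--------------------------------------------------------------------
baseline             181/204     89     84-93     87     90     100
twocodes             23/ 27      85     66-96     80     92      13
onset_first_dx: n=284 mean diff +0.38 y (95% CI -0.19 to +0.95), LoA -9.23 to +9.99
```

Reading this: of 2000 synthetic patients the baseline definition flags 216;
204 of those carry a (synthetic) physician label, 181 confirmed, so the
empirical PPV is 89% with exact 95% CI 84–93%. The stricter two-code variant
raises nothing here (85%) while keeping only 13% of confirmed cases — the
PPV/detection trade-off the validation design measures. The Bland–Altman
line shows the survey-reported onset age exceeds the first-diagnosis-code
age by 0.38 y on average (the generator planted a 0.8 y offset with SD 5 y;
the CI reflects n = 284 cases).

The same from Python:

```python
from aecase import ppv, preset, phenotype_cohort, generate, SynthConfig, synthetic_code_registry

est = ppv(163, 189)             # 163 of 189 algorithm positives confirmed
est.percent, est.ci_low, est.ci_high
# (86, 0.805, 0.908)

cohort, truth = generate(SynthConfig(n_patients=2000, seed=7))
results, summary = phenotype_cohort(cohort, preset("baseline"), synthetic_code_registry())
```

Code lists are plain CSV/TSV files (`code,description[,category]`) loaded
per category from a directory (`topical_steroid.csv`, `emollient.csv`, ...);
only the five core diagnosis codes ship built in, everything else is
user-supplied (see `docs/methods.md`).

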