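"""Seeded synthetic cohorts with coded-EHR structure and planted truth.

The generator emulates the recording patterns of UK primary-care data that
matter for eczema phenotyping, so the whole pipeline (case definition,
dating, validation statistics) can be exercised end to end without access to
any real database:

* true cases receive a small number of core diagnosis codes (shifted
  negative binomial moment-matched to a configurable mean/SD, default
  1.2/0.5) and an overdispersed number of treatment prescriptions (negative
  binomial matched to mean 16.3, SD 24.5), mixed over emollient, steroid,
  TCI, anti-infective, systemic and phototherapy codes;
* non-cases receive sporadic emollient scripts (Poisson) and, rarely, a
  stray diagnosis code;
* exclusionary-condition, atopy and dermatology-consult codes occur at flat
  configurable rates so the stricter algorithm variants have something to
  bite on;
* each true case carries a physician-confirmation label drawn independently
  with a configurable probability (the quantity a PPV validation study
  measures), and survey-style onset / last-activity ages offset from the
  first/last recorded codes by configurable Gaussian noise.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
config, so identical configs produce byte-identical event tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from aecase.codelists import Category, CodeList, CodeEntry, CodeRegistry, builtin_core_codes, write_codelist
from aecase.ehr_model import (
    Cohort,
    DAYS_PER_YEAR,
    DEFAULT_REFERENCE_DATE,
    Event,
    Patient,
    age_at,
    stratum,
    write_cohort,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "SynthConfigError",
    "SynthTruth",
    "generate",
    "summary_statistics",
    "synthetic_code_registry",
    "synthetic_code_lists",
    "truth_to_frame",
    "write_synthetic_dataset",
]


class SynthConfigError(ValueError):
    """Infeasible generator configuration."""


#: Synthetic stand-in codes for the user-supplied categories (clearly marked
#: as synthetic; they belong to no real terminology).
SYNTHETIC_CODES: dict[Category, list[str]] = {
    Category.EMOLLIENT: ["SYNRX-EM01", "SYNRX-EM02", "SYNRX-EM03"],
    Category.TOPICAL_STEROID: ["SYNRX-TS01", "SYNRX-TS02", "SYNRX-TS03"],
    Category.TCI: ["SYNRX-TC01"],
    Category.TOPICAL_ANTIINFECTIVE: ["SYNRX-AI01"],
    Category.SYSTEMIC: ["SYNRX-SY01"],
    Category.PHOTOTHERAPY: ["SYNRX-PH01"],
    Category.EXCLUSION: ["SYNDX-EX01", "SYNDX-EX02"],
    Category.DERM_CONSULT: ["SYNRF-DC01"],
    Category.ATOPY: ["SYNDX-AT01", "SYNDX-AT02"],
}

_EVENT_CLASS_BY_CATEGORY = {
    Category.EXCLUSION: "diagnosis",
    Category.ATOPY: "diagnosis",
    Category.DERM_CONSULT: "referral",
}

#: Mixing weights over treatment categories for case prescriptions
#: (emollients and topical steroids dominate; systemic therapy is rare).
CASE_TREATMENT_MIX: dict[Category, float] = {
    Category.EMOLLIENT: 0.45,
    Category.TOPICAL_STEROID: 0.42,
    Category.TCI: 0.03,
    Category.TOPICAL_ANTIINFECTIVE: 0.07,
    Category.SYSTEMIC: 0.02,
    Category.PHOTOTHERAPY: 0.01,
}

#: Relative frequency of the five core diagnosis codes, echoing their
#: relative use in the survey sample (atopic dermatitis/eczema and
#: "not otherwise specified" dominate).
CORE_CODE_WEIGHTS: dict[str, float] = {
    "M111.00": 0.46,
    "M112.00": 0.12,
    "M113.00": 0.06,
    "M114.00": 0.02,
    "M12z100": 0.34,
}


def synthetic_code_lists() -> list[CodeList]:
    """Code lists for the synthetic categories (plus the built-in core)."""
    lists = [builtin_core_codes()]
    for category, codes in SYNTHETIC_CODES.items():
        entries = [
            CodeEntry(code, f"synthetic {category.value.lower()} code", category)
            for code in codes
        ]
        lists.append(CodeList(entries=entries, provenance=f"synthetic:{category.value}"))
    return lists


def synthetic_code_registry() -> CodeRegistry:
    """Registry covering every category the generator emits."""
    return CodeRegistry(synthetic_code_lists())


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration (all rates and moments are per-config knobs).

    Counts: per-case core-code counts are a 1-shifted negative binomial
    moment-matched to ``(dx_count_mean, dx_count_sd)``; prescriptions are a
    negative binomial matched to ``(rx_count_mean, rx_count_sd)``
    (overdispersed).  Moments that cannot be matched on the required support
    raise :class:`SynthConfigError` (a Poisson is used in the boundary case
    where the variance equals the mean).

    Dating: the survey-reported onset age is the first recorded diagnosis
    age plus N(onset_lag_mean, onset_lag_sd) years; the survey-reported last
    activity age is the last recorded code age plus
    N(last_activity_lead_mean, last_activity_lead_sd) years.
    """

    n_patients: int = 1000
    seed: int = 0
    child_fraction: float = 0.5
    case_prevalence: float = 0.15
    confirm_prob_given_positive: float = 0.86
    dx_count_mean: float = 1.2
    dx_count_sd: float = 0.5
    rx_count_mean: float = 16.3
    rx_count_sd: float = 24.5
    treat_noncase_rate: float = 0.45
    stray_dx_prob: float = 0.002
    exclusion_prob: float = 0.15
    atopy_prob: float = 0.39
    derm_consult_prob: float = 0.10
    label_missing_prob: float = 0.055
    onset_lag_mean: float = 0.8
    onset_lag_sd: float = 5.0
    last_activity_lead_mean: float = -1.3
    last_activity_lead_sd: float = 4.5
    reference_date: date = DEFAULT_REFERENCE_DATE

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise SynthConfigError("n_patients must be >= 0")
        for name in (
            "child_fraction",
            "case_prevalence",
            "confirm_prob_given_positive",
            "stray_dx_prob",
            "exclusion_prob",
            "atopy_prob",
            "derm_consult_prob",
            "label_missing_prob",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SynthConfigError(f"{name} must be in [0, 1], got {value}")
        for name in ("dx_count_sd", "rx_count_sd", "onset_lag_sd", "last_activity_lead_sd"):
            if getattr(self, name) < 0:
                raise SynthConfigError(f"{name} must be >= 0")
        if self.treat_noncase_rate < 0:
            raise SynthConfigError("treat_noncase_rate must be >= 0")
        # fail fast on infeasible count moments
        _count_sampler_params(self.rx_count_mean, self.rx_count_sd, shift=0)
        _count_sampler_params(self.dx_count_mean, self.dx_count_sd, shift=1)


def _count_sampler_params(
    mean: float, sd: float, shift: int
) -> tuple[str, tuple[float, ...]]:
    """Parameters for an integer count sampler with support >= *shift*.

    Matches the first two moments with a (shifted) negative binomial;
    degenerates to Poisson when variance equals the shifted mean and to a
    constant when the SD is zero.
    """
    m = mean - shift
    var = sd**2
    if sd == 0.0:
        if m < 0 or abs(m - round(m)) > 1e-9:
            raise SynthConfigError(
                f"sd=0 requires an integer mean >= {shift}, got mean={mean}"
            )
        return "constant", (m,)
    if m <= 0:
        raise SynthConfigError(f"count mean must exceed {shift} when sd > 0")
    if abs(var - m) <= 1e-12:
        return "poisson", (m,)
    if var < m:
        raise SynthConfigError(
            f"count moments mean={mean}, sd={sd} are underdispersed for a "
            f"negative-binomial match (need sd^2 > mean - {shift}); "
            "use sd^2 = mean for a Poisson"
        )
    r = m**2 / (var - m)
    p = r / (r + m)
    return "negbin", (r, p)


def _sample_count(rng: np.random.Generator, mean: float, sd: float, shift: int) -> int:
    kind, params = _count_sampler_params(mean, sd, shift)
    if kind == "constant":
        return shift + int(round(params[0]))
    if kind == "poisson":
        return shift + int(rng.poisson(params[0]))
    r, p = params
    return shift + int(rng.negative_binomial(r, p))


@dataclass(frozen=True)
class SynthTruth:
    """Planted ground truth for one synthetic patient."""

    patient_id: str
    true_case: bool
    physician_confirmed: Optional[bool]  # None = survey missing
    true_onset_age: Optional[float] = None
    true_last_activity_age: Optional[float] = None


def _age_to_date(birth: date, age_years: float) -> date:
    return birth + timedelta(days=int(round(age_years * DAYS_PER_YEAR)))


def generate(config: SynthConfig) -> tuple[Cohort, list[SynthTruth]]:
    """Generate a cohort and its planted truth, deterministically by seed."""
    rng = np.random.default_rng(config.seed)
    reference = config.reference_date
    core_codes = list(CORE_CODE_WEIGHTS)
    core_weights = np.array(list(CORE_CODE_WEIGHTS.values()))
    core_weights = core_weights / core_weights.sum()
    mix_categories = list(CASE_TREATMENT_MIX)
    mix_weights = np.array(list(CASE_TREATMENT_MIX.values()))
    mix_weights = mix_weights / mix_weights.sum()

    patients: dict[str, Patient] = {}
    events: dict[str, list[Event]] = {}
    truths: list[SynthTruth] = []

    for i in range(config.n_patients):
        pid = f"S{i:06d}"
        is_child = rng.random() < config.child_fraction
        age_ref = rng.uniform(1.0, 17.9) if is_child else rng.uniform(18.0, 80.0)
        birth = reference - timedelta(days=int(round(age_ref * DAYS_PER_YEAR)))
        sex = "male" if rng.random() < 0.5 else "female"
        patient = Patient(
            patient_id=pid,
            birth_date=birth,
            sex=sex,
            reg_start=birth,
            reg_end=reference,
        )
        patients[pid] = patient
        patient_events: list[Event] = []

        is_case = rng.random() < config.case_prevalence
        if is_case:
            onset_age = rng.uniform(0.25, max(0.75, age_ref - 0.5))
            n_dx = _sample_count(rng, config.dx_count_mean, config.dx_count_sd, shift=1)
            dx_ages = rng.uniform(onset_age, age_ref, size=n_dx)
            dx_codes = rng.choice(core_codes, size=n_dx, p=core_weights)
            for a, code in zip(dx_ages, dx_codes):
                patient_events.append(
                    Event(pid, _age_to_date(birth, float(a)), str(code), "diagnosis")
                )
            n_rx = _sample_count(rng, config.rx_count_mean, config.rx_count_sd, shift=0)
            if n_rx:
                # symptoms (and scripts) may precede the first coded diagnosis
                rx_low = max(0.1, onset_age - 1.0)
                rx_ages = rng.uniform(rx_low, age_ref, size=n_rx)
                cats = rng.choice(len(mix_categories), size=n_rx, p=mix_weights)
                for a, ci in zip(rx_ages, cats):
                    category = mix_categories[int(ci)]
                    pool = SYNTHETIC_CODES[category]
                    code = pool[int(rng.integers(len(pool)))]
                    patient_events.append(
                        Event(pid, _age_to_date(birth, float(a)), code, "prescription")
                    )
        else:
            n_rx = int(rng.poisson(config.treat_noncase_rate))
            for _ in range(n_rx):
                a = rng.uniform(0.1, age_ref)
                pool = SYNTHETIC_CODES[Category.EMOLLIENT]
                code = pool[int(rng.integers(len(pool)))]
                patient_events.append(
                    Event(pid, _age_to_date(birth, float(a)), code, "prescription")
                )
            if rng.random() < config.stray_dx_prob:
                a = rng.uniform(0.25, age_ref)
                code = str(rng.choice(core_codes, p=core_weights))
                patient_events.append(
                    Event(pid, _age_to_date(birth, float(a)), code, "diagnosis")
                )

        for category, prob in (
            (Category.EXCLUSION, config.exclusion_prob),
            (Category.ATOPY, config.atopy_prob),
            (Category.DERM_CONSULT, config.derm_consult_prob),
        ):
            if rng.random() < prob:
                a = rng.uniform(0.1, age_ref)
                pool = SYNTHETIC_CODES[category]
                code = pool[int(rng.integers(len(pool)))]
                patient_events.append(
                    Event(
                        pid,
                        _age_to_date(birth, float(a)),
                        code,
                        _EVENT_CLASS_BY_CATEGORY[category],
                    )
                )

        patient_events.sort(key=lambda e: (e.date, e.code, e.event_class))
        events[pid] = patient_events

        # labels: confirmation is an independent Bernoulli on true cases,
        # survey non-response strikes any patient
        confirmed: Optional[bool] = bool(
            is_case and rng.random() < config.confirm_prob_given_positive
        )
        if rng.random() < config.label_missing_prob:
            confirmed = None

        onset_truth = last_truth = None
        if is_case:
            dx_dates = [e.date for e in patient_events if e.event_class == "diagnosis" and e.code in CORE_CODE_WEIGHTS]
            all_dates = [e.date for e in patient_events if e.event_class in ("diagnosis", "prescription")]
            first_dx_age = age_at(patient, min(dx_dates))
            last_code_age = age_at(patient, max(all_dates))
            onset_truth = first_dx_age + rng.normal(
                config.onset_lag_mean, config.onset_lag_sd
            )
            last_truth = last_code_age + rng.normal(
                config.last_activity_lead_mean, config.last_activity_lead_sd
            )
        truths.append(
            SynthTruth(
                patient_id=pid,
                true_case=is_case,
                physician_confirmed=confirmed,
                true_onset_age=onset_truth,
                true_last_activity_age=last_truth,
            )
        )

    cohort = Cohort(patients=patients, events=events, reference_date=reference)
    return cohort, truths


def truth_to_frame(cohort: Cohort, truths: Sequence[SynthTruth]) -> pd.DataFrame:
    """Tabulate planted truth with stratum and survey-style labels."""
    rows = []
    for t in truths:
        patient = cohort.patients[t.patient_id]
        confirmed = (
            "missing"
            if t.physician_confirmed is None
            else ("yes" if t.physician_confirmed else "no")
        )
        rows.append(
            {
                "patient_id": t.patient_id,
                "true_case": t.true_case,
                "physician_confirmed": confirmed,
                "stratum": stratum(patient, cohort.reference_date),
                "true_onset_age": (
                    None if t.true_onset_age is None else round(t.true_onset_age, 3)
                ),
                "true_last_activity_age": (
                    None
                    if t.true_last_activity_age is None
                    else round(t.true_last_activity_age, 3)
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "true_case",
            "physician_confirmed",
            "stratum",
            "true_onset_age",
            "true_last_activity_age",
        ],
    )


def summary_statistics(
    cohort: Cohort, lists: Optional[CodeRegistry] = None
) -> pd.DataFrame:
    """Realised code prevalences and per-patient count moments, by stratum.

    Percent rows are over all patients; the mean/SD code-count rows are over
    patients with at least one code of that kind (how per-patient counts are
    conventionally reported for episodic conditions).
    """
    if lists is None:
        lists = synthetic_code_registry()
    records = []
    for patient in cohort:
        n_core = n_treat = n_specific = 0
        for event in cohort.events_for(patient.patient_id):
            category = lists.classify(event.code)
            if category is Category.CORE_DX:
                n_core += 1
            elif category in (
                Category.EMOLLIENT,
                Category.TOPICAL_STEROID,
                Category.TCI,
                Category.TOPICAL_ANTIINFECTIVE,
                Category.SYSTEMIC,
                Category.PHOTOTHERAPY,
            ):
                n_treat += 1
                if category in (Category.TOPICAL_STEROID, Category.TCI):
                    n_specific += 1
        records.append(
            {
                "stratum": stratum(patient, cohort.reference_date),
                "n_core": n_core,
                "n_treat": n_treat,
                "n_specific": n_specific,
            }
        )
    frame = pd.DataFrame(records, columns=["stratum", "n_core", "n_treat", "n_specific"])

    def _column(sub: pd.DataFrame) -> dict:
        n = len(sub)
        if n == 0:
            return {}
        with_core = sub[sub.n_core > 0]
        with_treat = sub[sub.n_treat > 0]
        return {
            "n_patients": n,
            "pct_one_or_more_core": 100.0 * len(with_core) / n,
            "pct_two_or_more_core": 100.0 * (sub.n_core >= 2).sum() / n,
            "pct_one_or_more_treatment": 100.0 * len(with_treat) / n,
            "pct_one_or_more_specific_treatment": 100.0 * (sub.n_specific > 0).sum() / n,
            "mean_core_codes": float(with_core.n_core.mean()) if len(with_core) else float("nan"),
            "sd_core_codes": float(with_core.n_core.std(ddof=1)) if len(with_core) > 1 else float("nan"),
            "mean_treatment_codes": float(with_treat.n_treat.mean()) if len(with_treat) else float("nan"),
            "sd_treatment_codes": float(with_treat.n_treat.std(ddof=1)) if len(with_treat) > 1 else float("nan"),
        }

    columns = {
        "total": _column(frame),
        "children": _column(frame[frame.stratum == "child"]),
        "adults": _column(frame[frame.stratum == "adult"]),
    }
    return pd.DataFrame(columns)


def write_synthetic_dataset(
    cohort: Cohort,
    truths: Sequence[SynthTruth],
    out_dir: Union[str, Path],
) -> dict[str, Path]:
    """Write patients/events/truth/labels CSVs plus the code-list directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out_dir / "patients.csv",
        "events": out_dir / "events.csv",
        "truth": out_dir / "truth.csv",
        "labels": out_dir / "labels.csv",
    }
    write_cohort(cohort, paths["patients"], paths["events"])
    truth_frame = truth_to_frame(cohort, truths)
    truth_frame.to_csv(paths["truth"], index=False)
    truth_frame[["patient_id", "physician_confirmed", "stratum"]].to_csv(
        paths["labels"], index=False
    )
    codelist_dir = out_dir / "codelists"
    codelist_dir.mkdir(exist_ok=True)
    for codelist in synthetic_code_lists():
        category = codelist.entries[0].category
        write_codelist(codelist, codelist_dir / f"{category.value.lower()}.csv")
    paths["codelists"] = codelist_dir
    return paths
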