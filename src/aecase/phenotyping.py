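"""Declarative case-definition algorithms for atopic eczema.

The baseline case definition requires at least one of the five core eczema
diagnosis Read codes plus eczema-directed treatment codes on at least two
separate calendar dates, with treatment counted at any time relative to the
diagnosis.  Nine stricter published variants layer additional constraints on
top: steroid/TCI-specific treatment counts, a temporal window linking a
steroid/TCI prescription to a diagnosis code, a second diagnosis code, no
exclusionary condition, an atopy code, or a dermatology consult.

Each rule set is an :class:`AlgorithmSpec`; :func:`preset` returns the named
published variants.  :func:`evaluate_patient` applies a spec to one patient's
event stream and returns a :class:`PhenotypeResult` carrying the per-criterion
evidence, so a decision can always be audited back to the events that made it.

Counting conventions (all switchable where noted):

* "Separate dates" means distinct calendar dates bearing at least one
  treatment-category code; two drugs on one date count once.
* Core diagnosis codes are likewise counted on distinct dates by default
  (two core codes on one day are one coded occasion); set
  ``core_dx_distinct_dates=False`` to count events instead.
* "3 months" is 91 days and "1 year" is 365 days; window endpoints are
  inclusive.
* The exclusion criterion scans the patient's entire record.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import timedelta
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from aecase.codelists import (
    Category,
    CodeRegistry,
    SPECIFIC_TREATMENT_CATEGORIES,
    TREATMENT_CATEGORIES,
)
from aecase.ehr_model import Cohort, Event, stratum

__all__ = [
    "AlgorithmSpec",
    "CriterionResult",
    "PhenotypeResult",
    "PhenotypeSummary",
    "PRESET_NAMES",
    "preset",
    "evaluate_patient",
    "phenotype_cohort",
    "results_to_frame",
    "load_spec",
    "save_spec",
]


@dataclass(frozen=True)
class AlgorithmSpec:
    """One declarative case-definition rule set.

    Parameters
    ----------
    min_core_dx:
        Minimum number of distinct dates bearing a core diagnosis code.
    min_treatment_dates:
        Minimum number of distinct dates bearing any eczema-directed
        treatment code.
    min_specific_treatments:
        Of the treatment dates, minimum bearing a topical steroid or TCI
        code.
    temporal_window:
        Optional ``(days_before, days_after)``: require a steroid/TCI event
        within [dx - days_before, dx + days_after] of some core diagnosis
        event (endpoints inclusive).
    require_no_exclusion / require_atopy / require_derm_consult:
        Record-level flags for the corresponding category.
    core_dx_distinct_dates:
        Count core codes on distinct dates (default) or as raw events.
    """

    name: str = "custom"
    min_core_dx: int = 1
    min_treatment_dates: int = 2
    min_specific_treatments: int = 0
    temporal_window: Optional[tuple[int, int]] = None
    require_no_exclusion: bool = False
    require_atopy: bool = False
    require_derm_consult: bool = False
    core_dx_distinct_dates: bool = True

    def __post_init__(self) -> None:
        if self.min_core_dx < 1:
            raise ValueError("min_core_dx must be >= 1")
        if self.min_treatment_dates < 0 or self.min_specific_treatments < 0:
            raise ValueError("treatment thresholds must be >= 0")
        if self.min_specific_treatments > self.min_treatment_dates:
            raise ValueError(
                "min_specific_treatments cannot exceed min_treatment_dates"
            )
        if self.temporal_window is not None:
            before, after = self.temporal_window
            if before < 0 or after < 0:
                raise ValueError("temporal_window days must be >= 0")
            object.__setattr__(self, "temporal_window", (int(before), int(after)))

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        if self.temporal_window is not None:
            before, after = self.temporal_window
            data["temporal_window"] = {"days_before": before, "days_after": after}
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "AlgorithmSpec":
        data = dict(data)
        window = data.get("temporal_window")
        if isinstance(window, dict):
            data["temporal_window"] = (window["days_before"], window["days_after"])
        elif isinstance(window, (list, tuple)):
            data["temporal_window"] = tuple(window)
        return cls(**data)


_PRESETS: dict[str, dict] = {
    # one of five core codes + treatment on >= 2 separate dates
    "baseline": dict(min_core_dx=1, min_treatment_dates=2),
    # ... of which >= 1 steroid/TCI date
    "steroid1": dict(min_core_dx=1, min_treatment_dates=2, min_specific_treatments=1),
    # ... of which >= 2 steroid/TCI dates
    "steroid2": dict(min_core_dx=1, min_treatment_dates=2, min_specific_treatments=2),
    # steroid/TCI within 3 months before to 1 year after a core code
    "window": dict(
        min_core_dx=1,
        min_treatment_dates=2,
        min_specific_treatments=1,
        temporal_window=(91, 365),
    ),
    # a second core code (two coded occasions)
    "twocodes": dict(min_core_dx=2, min_treatment_dates=2),
    "twocodes_steroid1": dict(
        min_core_dx=2, min_treatment_dates=2, min_specific_treatments=1
    ),
    "twocodes_steroid2": dict(
        min_core_dx=2, min_treatment_dates=2, min_specific_treatments=2
    ),
    "no_exclusion": dict(min_core_dx=1, min_treatment_dates=2, require_no_exclusion=True),
    "atopy": dict(min_core_dx=1, min_treatment_dates=2, require_atopy=True),
    "derm_consult": dict(min_core_dx=1, min_treatment_dates=2, require_derm_consult=True),
}

PRESET_NAMES: tuple[str, ...] = tuple(_PRESETS)

#: Preset names excluding the baseline, i.e. the stricter variants.
VARIANT_NAMES: tuple[str, ...] = tuple(n for n in PRESET_NAMES if n != "baseline")


def preset(name: str) -> AlgorithmSpec:
    """Return the named published rule set as an :class:`AlgorithmSpec`."""
    try:
        params = _PRESETS[name]
    except KeyError:
        raise LookupError(
            f"unknown algorithm preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        ) from None
    return AlgorithmSpec(name=name, **params)


@dataclass(frozen=True)
class CriterionResult:
    """Whether one criterion held, with the events behind the decision.

    For positive criteria ``events`` lists supporting evidence (one event per
    qualifying date); for the no-exclusion criterion it lists the violating
    exclusion events when the criterion fails.
    """

    satisfied: bool
    events: tuple[Event, ...] = ()


@dataclass(frozen=True)
class PhenotypeResult:
    """Decision for one patient under one algorithm spec."""

    patient_id: str
    spec_name: str
    positive: bool
    criteria: dict[str, CriterionResult]
    n_core_dx_dates: int
    n_treatment_dates: int
    n_specific_treatment_dates: int


def _one_per_date(events: Iterable[Event]) -> tuple[Event, ...]:
    seen: dict = {}
    for event in sorted(events, key=lambda e: e.date):
        seen.setdefault(event.date, event)
    return tuple(seen.values())


def evaluate_patient(
    events: Sequence[Event],
    spec: AlgorithmSpec,
    lists: CodeRegistry,
    patient_id: Optional[str] = None,
) -> PhenotypeResult:
    """Apply one rule set to one patient's events.

    The decision is positive iff every criterion in the spec is satisfied.
    An empty event sequence yields a negative result, not an error.  Input
    order never matters: all counting is over dates and sets.
    """
    if patient_id is None:
        patient_id = events[0].patient_id if events else "<unknown>"

    classified = [(event, lists.classify(event.code)) for event in events]
    core = [e for e, c in classified if c is Category.CORE_DX]
    treatments = [(e, c) for e, c in classified if c in TREATMENT_CATEGORIES]
    specific = [e for e, c in treatments if c in SPECIFIC_TREATMENT_CATEGORIES]

    core_dates = {e.date for e in core}
    treatment_dates = {e.date for e, _ in treatments}
    specific_dates = {e.date for e in specific}

    n_core = len(core_dates) if spec.core_dx_distinct_dates else len(core)
    criteria: dict[str, CriterionResult] = {}

    criteria["core_diagnosis"] = CriterionResult(
        n_core >= spec.min_core_dx, _one_per_date(core) if spec.core_dx_distinct_dates else tuple(core)
    )
    if spec.min_treatment_dates > 0:
        criteria["treatment_dates"] = CriterionResult(
            len(treatment_dates) >= spec.min_treatment_dates,
            _one_per_date(e for e, _ in treatments),
        )
    if spec.min_specific_treatments > 0:
        criteria["specific_treatments"] = CriterionResult(
            len(specific_dates) >= spec.min_specific_treatments,
            _one_per_date(specific),
        )
    if spec.temporal_window is not None:
        before, after = spec.temporal_window
        evidence: tuple[Event, ...] = ()
        for dx in sorted(core, key=lambda e: e.date):
            low = dx.date - timedelta(days=before)
            high = dx.date + timedelta(days=after)
            match = next(
                (t for t in sorted(specific, key=lambda e: e.date) if low <= t.date <= high),
                None,
            )
            if match is not None:
                evidence = (dx, match)
                break
        criteria["temporal_window"] = CriterionResult(bool(evidence), evidence)
    if spec.require_no_exclusion:
        exclusions = tuple(e for e, c in classified if c is Category.EXCLUSION)
        criteria["no_exclusion"] = CriterionResult(not exclusions, exclusions)
    if spec.require_atopy:
        atopy = tuple(e for e, c in classified if c is Category.ATOPY)
        criteria["atopy"] = CriterionResult(bool(atopy), atopy)
    if spec.require_derm_consult:
        consults = tuple(e for e, c in classified if c is Category.DERM_CONSULT)
        criteria["derm_consult"] = CriterionResult(bool(consults), consults)

    return PhenotypeResult(
        patient_id=patient_id,
        spec_name=spec.name,
        positive=all(c.satisfied for c in criteria.values()),
        criteria=criteria,
        n_core_dx_dates=len(core_dates),
        n_treatment_dates=len(treatment_dates),
        n_specific_treatment_dates=len(specific_dates),
    )


@dataclass(frozen=True)
class PhenotypeSummary:
    """Positive counts overall and per age stratum for one cohort run."""

    spec_name: str
    n_patients: int
    n_positive: int
    n_positive_child: int
    n_positive_adult: int


def phenotype_cohort(
    cohort: Cohort,
    spec: AlgorithmSpec,
    lists: CodeRegistry,
) -> tuple[list[PhenotypeResult], PhenotypeSummary]:
    """Evaluate *spec* for every patient; return results plus summary counts."""
    results: list[PhenotypeResult] = []
    n_child = n_adult = 0
    for patient in cohort:
        result = evaluate_patient(
            cohort.events_for(patient.patient_id),
            spec,
            lists,
            patient_id=patient.patient_id,
        )
        results.append(result)
        if result.positive:
            if stratum(patient, cohort.reference_date) == "child":
                n_child += 1
            else:
                n_adult += 1
    summary = PhenotypeSummary(
        spec_name=spec.name,
        n_patients=len(cohort),
        n_positive=n_child + n_adult,
        n_positive_child=n_child,
        n_positive_adult=n_adult,
    )
    return results, summary


def results_to_frame(results: Iterable[PhenotypeResult]) -> pd.DataFrame:
    """Tabulate results: one row per patient with counts and criterion flags."""
    rows = []
    for r in results:
        row = {
            "patient_id": r.patient_id,
            "positive": r.positive,
            "n_core_dx_dates": r.n_core_dx_dates,
            "n_treatment_dates": r.n_treatment_dates,
            "n_specific_treatment_dates": r.n_specific_treatment_dates,
        }
        for name, crit in r.criteria.items():
            row[f"met_{name}"] = crit.satisfied
        rows.append(row)
    return pd.DataFrame(rows)


def load_spec(path: Union[str, Path]) -> AlgorithmSpec:
    """Load an :class:`AlgorithmSpec` from a YAML or JSON file."""
    with Path(path).open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return AlgorithmSpec.from_dict(data)


def save_spec(spec: AlgorithmSpec, path: Union[str, Path]) -> None:
    """Write an :class:`AlgorithmSpec` as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = spec.to_dict()
    with path.open("w", encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)
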