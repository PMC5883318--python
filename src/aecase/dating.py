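"""Onset and last-activity dating from first/last recorded codes.

The age at eczema onset is proxied by the age at the first core diagnosis
code (and, separately, the first prescription for any eczema-directed
treatment); the age at last disease activity by the last such codes.  Fields
are absent (``None``) when the patient has no qualifying event of that class.

Last-activity ages are computed for every patient; any cohort-selection
filter (e.g. restricting to patients with no symptoms in the year before the
last visit) is applied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from aecase.codelists import Category, CodeRegistry, TREATMENT_CATEGORIES
from aecase.ehr_model import Cohort, Event, Patient, age_at

__all__ = ["DatingEstimate", "estimate_dates", "estimate_cohort", "estimates_to_frame"]


@dataclass(frozen=True)
class DatingEstimate:
    """First/last diagnosis and prescription ages (years) for one patient."""

    patient_id: str
    first_dx_age: Optional[float] = None
    first_rx_age: Optional[float] = None
    last_dx_age: Optional[float] = None
    last_rx_age: Optional[float] = None


def estimate_dates(
    patient: Patient,
    events: Sequence[Event],
    lists: CodeRegistry,
) -> DatingEstimate:
    """Ages at first/last core diagnosis code and first/last treatment code.

    Diagnosis dating uses core-tier codes only; prescription dating uses any
    treatment-category code.  Ties on the first or last day resolve through
    min/max over dates, so input order never matters.
    """
    dx_dates = [
        e.date for e in events if lists.classify(e.code) is Category.CORE_DX
    ]
    rx_dates = [
        e.date for e in events if lists.classify(e.code) in TREATMENT_CATEGORIES
    ]
    return DatingEstimate(
        patient_id=patient.patient_id,
        first_dx_age=age_at(patient, min(dx_dates)) if dx_dates else None,
        last_dx_age=age_at(patient, max(dx_dates)) if dx_dates else None,
        first_rx_age=age_at(patient, min(rx_dates)) if rx_dates else None,
        last_rx_age=age_at(patient, max(rx_dates)) if rx_dates else None,
    )


def estimate_cohort(cohort: Cohort, lists: CodeRegistry) -> list[DatingEstimate]:
    """One :class:`DatingEstimate` per patient in the cohort."""
    return [
        estimate_dates(patient, cohort.events_for(patient.patient_id), lists)
        for patient in cohort
    ]


def estimates_to_frame(estimates: Iterable[DatingEstimate], decimals: int = 3) -> pd.DataFrame:
    """Tabulate estimates with ages rounded to *decimals* (default 3) years."""
    frame = pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "first_dx_age": e.first_dx_age,
                "first_rx_age": e.first_rx_age,
                "last_dx_age": e.last_dx_age,
                "last_rx_age": e.last_rx_age,
            }
            for e in estimates
        ]
    )
    age_cols = ["first_dx_age", "first_rx_age", "last_dx_age", "last_rx_age"]
    if not frame.empty:
        frame[age_cols] = frame[age_cols].round(decimals)
    return frame
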