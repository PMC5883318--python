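"""Patients and their date-stamped coded events.

A :class:`Cohort` holds demographics (birth date, sex, registration window)
and per-patient, date-ordered event streams, mirroring the shape of UK
primary-care research extracts: one ``patients.csv`` and one long
``events.csv`` with a code and an event class (diagnosis, prescription,
referral, other) per row.  Dates are strict ISO 8601 (``YYYY-MM-DD``).

Age arithmetic uses the days/365.25 convention; the child/adult split is the
half-open interval [0, 18) years at a configurable reference date (default
2013-01-01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterator, Optional, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "Patient",
    "Event",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "age_at",
    "stratum",
    "DEFAULT_REFERENCE_DATE",
    "DAYS_PER_YEAR",
    "CHILD_AGE_LIMIT",
]

DEFAULT_REFERENCE_DATE = date(2013, 1, 1)
DAYS_PER_YEAR = 365.25
CHILD_AGE_LIMIT = 18.0
_MIN_EVENT_DATE = date(1900, 1, 1)

SEXES = ("male", "female", "unknown")
EVENT_CLASSES = ("diagnosis", "prescription", "referral", "other")

_SEX_ALIASES = {
    "m": "male",
    "f": "female",
    "male": "male",
    "female": "female",
    "unknown": "unknown",
    "": "unknown",
}

PATIENT_COLUMNS = ["patient_id", "birth_date", "sex", "reg_start", "reg_end"]
EVENT_COLUMNS = ["patient_id", "date", "code", "event_class"]


class FormatError(ValueError):
    """Malformed input file; the message names the file and line."""


@dataclass(frozen=True)
class Patient:
    """Demographics and observation window for one patient."""

    patient_id: str
    birth_date: date
    sex: str = "unknown"
    reg_start: Optional[date] = None
    reg_end: Optional[date] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if (
            self.reg_start is not None
            and self.reg_end is not None
            and self.reg_start > self.reg_end
        ):
            raise ValueError(
                f"patient {self.patient_id}: reg_start after reg_end"
            )


@dataclass(frozen=True)
class Event:
    """One date-stamped coded record for one patient."""

    patient_id: str
    date: date
    code: str
    event_class: str = "diagnosis"

    def __post_init__(self) -> None:
        if not self.code.strip():
            raise ValueError("event code must be non-empty")
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(
                f"event_class must be one of {EVENT_CLASSES}, "
                f"got {self.event_class!r}"
            )
        if not (_MIN_EVENT_DATE <= self.date <= date.today()):
            raise ValueError(f"event date {self.date} out of plausible range")


@dataclass
class Cohort:
    """Patients keyed by id plus per-patient date-ordered event lists."""

    patients: dict[str, Patient] = field(default_factory=dict)
    events: dict[str, list[Event]] = field(default_factory=dict)
    reference_date: date = DEFAULT_REFERENCE_DATE
    n_orphan_events: int = 0

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[Patient]:
        return iter(self.patients.values())

    def events_for(self, patient_id: str) -> list[Event]:
        return self.events.get(patient_id, [])

    def all_events(self) -> Iterator[Event]:
        for patient_id in self.patients:
            yield from self.events.get(patient_id, [])

    @property
    def n_events(self) -> int:
        return sum(len(evts) for evts in self.events.values())


def age_at(patient: Patient, on: date) -> float:
    """Age in years on *on*, as elapsed days divided by 365.25."""
    if on < patient.birth_date:
        raise ValueError(
            f"date {on} precedes birth date {patient.birth_date} "
            f"for patient {patient.patient_id}"
        )
    return (on - patient.birth_date).days / DAYS_PER_YEAR


def stratum(patient: Patient, reference_date: date = DEFAULT_REFERENCE_DATE) -> str:
    """``"child"`` if age at *reference_date* is below 18 years else ``"adult"``."""
    return "child" if age_at(patient, reference_date) < CHILD_AGE_LIMIT else "adult"


def _parse_date(value: str, path: Union[str, Path], lineno: int, column: str) -> date:
    try:
        return date.fromisoformat(value.strip())
    except ValueError as exc:
        raise FormatError(
            f"{path} line {lineno}: bad {column} {value!r} (expected YYYY-MM-DD)"
        ) from exc


def _require_columns(frame: pd.DataFrame, required: list[str], path: Union[str, Path]) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_cohort(
    patients_path: Union[str, Path],
    events_path: Union[str, Path],
    reference_date: date = DEFAULT_REFERENCE_DATE,
    within_registration: bool = False,
) -> Cohort:
    """Read ``patients.csv`` and ``events.csv`` into a :class:`Cohort`.

    Events are sorted ascending by date within patient (stable, so same-day
    events keep file order).  Events referencing an unknown patient are
    dropped and counted in :attr:`Cohort.n_orphan_events` with a logged
    warning.  With ``within_registration=True`` events outside the patient's
    registration window are dropped too (off by default: treatment may be
    recorded at any time relative to diagnosis).
    """
    patients_path, events_path = Path(patients_path), Path(events_path)
    pframe = pd.read_csv(patients_path, dtype=str, keep_default_na=False)
    _require_columns(pframe, PATIENT_COLUMNS, patients_path)
    patients: dict[str, Patient] = {}
    for i, row in enumerate(pframe.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        pid = str(row.patient_id).strip()
        if not pid:
            raise FormatError(f"{patients_path} line {lineno}: empty patient_id")
        if pid in patients:
            raise FormatError(
                f"{patients_path} line {lineno}: duplicate patient_id {pid!r}"
            )
        sex = _SEX_ALIASES.get(str(row.sex).strip().lower())
        if sex is None:
            raise FormatError(
                f"{patients_path} line {lineno}: unrecognised sex {row.sex!r}"
            )
        def _opt(value: str, column: str) -> Optional[date]:
            value = str(value).strip()
            return _parse_date(value, patients_path, lineno, column) if value else None

        try:
            patients[pid] = Patient(
                patient_id=pid,
                birth_date=_parse_date(row.birth_date, patients_path, lineno, "birth_date"),
                sex=sex,
                reg_start=_opt(row.reg_start, "reg_start"),
                reg_end=_opt(row.reg_end, "reg_end"),
            )
        except ValueError as exc:
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{patients_path} line {lineno}: {exc}") from exc

    eframe = pd.read_csv(events_path, dtype=str, keep_default_na=False)
    _require_columns(eframe, EVENT_COLUMNS, events_path)
    events: dict[str, list[Event]] = {pid: [] for pid in patients}
    n_orphans = 0
    for i, row in enumerate(eframe.itertuples(index=False)):
        lineno = i + 2
        pid = str(row.patient_id).strip()
        if pid not in patients:
            n_orphans += 1
            continue
        event_class = str(row.event_class).strip().lower()
        try:
            event = Event(
                patient_id=pid,
                date=_parse_date(row.date, events_path, lineno, "date"),
                code=str(row.code).strip(),
                event_class=event_class,
            )
        except ValueError as exc:
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{events_path} line {lineno}: {exc}") from exc
        patient = patients[pid]
        if within_registration and not (
            (patient.reg_start is None or event.date >= patient.reg_start)
            and (patient.reg_end is None or event.date <= patient.reg_end)
        ):
            continue
        events[pid].append(event)
    if n_orphans:
        logger.warning(
            "%s: dropped %d event(s) with unknown patient_id", events_path, n_orphans
        )
    for pid in events:
        events[pid].sort(key=lambda e: e.date)  # stable: same-day order kept
    return Cohort(
        patients=patients,
        events=events,
        reference_date=reference_date,
        n_orphan_events=n_orphans,
    )


def write_cohort(
    cohort: Cohort,
    patients_path: Union[str, Path],
    events_path: Union[str, Path],
) -> None:
    """Write a cohort back to the two-file CSV layout read by :func:`read_cohort`."""
    pframe = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "birth_date": p.birth_date.isoformat(),
                "sex": p.sex,
                "reg_start": "" if p.reg_start is None else p.reg_start.isoformat(),
                "reg_end": "" if p.reg_end is None else p.reg_end.isoformat(),
            }
            for p in cohort
        ],
        columns=PATIENT_COLUMNS,
    )
    pframe.to_csv(patients_path, index=False)
    eframe = pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "date": e.date.isoformat(),
                "code": e.code,
                "event_class": e.event_class,
            }
            for e in cohort.all_events()
        ],
        columns=EVENT_COLUMNS,
    )
    eframe.to_csv(events_path, index=False)
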