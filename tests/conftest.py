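from datetime import date

import pytest

from aecase.codelists import CodeRegistry
from aecase.ehr_model import Event, Patient
from aecase.synth import synthetic_code_registry


@pytest.fixture(scope="session")
def registry() -> CodeRegistry:
    """Registry with the built-in core codes plus synthetic stand-ins for
    every user-supplied category (treatments, exclusion, atopy, consult)."""
    return synthetic_code_registry()


@pytest.fixture
def make_event():
    def _make(iso_date: str, code: str, event_class: str = "diagnosis", pid: str = "P1") -> Event:
        return Event(pid, date.fromisoformat(iso_date), code, event_class)

    return _make


@pytest.fixture
def patient():
    return Patient(
        patient_id="P1",
        birth_date=date(2000, 1, 1),
        sex="female",
        reg_start=date(2000, 1, 1),
        reg_end=date(2013, 1, 1),
    )
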