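from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ontorx.engine import LabResult, PatientRecord, Prescription, RuleEngine
from ontorx.mapping import MappingSet
from ontorx.synth import GFR_UNIT, build_fixture_kb

T0 = datetime(2026, 1, 1, tzinfo=timezone.utc)


@pytest.fixture(scope="session")
def fixture_kb():
    return build_fixture_kb()


@pytest.fixture(scope="session")
def fixture_mappings(fixture_kb):
    return MappingSet(fixture_kb.mappings)


@pytest.fixture(scope="session")
def engine(fixture_kb):
    return RuleEngine(fixture_kb)


def rx(
    rx_id: str,
    code: str,
    dose: float,
    unit: str = "MG",
    freq: str = "Q24H",
    route: str = "PO",
    day: int = 0,
    days: int = 7,
    prn: bool = False,
) -> Prescription:
    start = T0 + timedelta(days=day)
    return Prescription(
        id=rx_id,
        drug_code=code,
        dose=dose,
        dose_unit=unit,
        frequency=freq,
        route=route,
        start=start,
        end=start + timedelta(days=days),
        prn=prn,
    )


def gfr(value: float, day: int = 0) -> LabResult:
    return LabResult(
        test_code="GFR-LOCAL",
        value=value,
        unit=GFR_UNIT,
        taken_at=T0 + timedelta(days=day),
    )


def patient(pid="P1", age=70, prescriptions=(), labs=(), allergies=()):
    return PatientRecord(
        patient_id=pid,
        age_years=age,
        prescriptions=list(prescriptions),
        labs=list(labs),
        allergies=list(allergies),
    )
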