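from datetime import date, timedelta

import pytest

from advckd import CodedEvent, LabResult, PatientRecord, Registry, invert_mdrd

REF = date(2021, 4, 1)


def lab(pid: str, days_before_ref: int, egfr: float, *, age: float = 70.0) -> LabResult:
    """A creatinine lab whose computed MDRD eGFR equals ``egfr`` exactly
    (male, non-Black patient aged ``age`` at the collection date)."""
    d = REF - timedelta(days=days_before_ref)
    age_at_lab = age - days_before_ref / 365.25  # age is the age at REF
    return LabResult(
        patient_id=pid,
        collection_date=d,
        creatinine_mg_dl=invert_mdrd(egfr, age_at_lab),
    )


def patient(pid: str, *, age: float = 70.0) -> PatientRecord:
    return PatientRecord(patient_id=pid, sex="male", race="white", age_years=age)


@pytest.fixture
def toy_registry() -> Registry:
    """Seven hand-built patients covering each cohort/classification path.

    A: index 25 at day -10, prior 40 at day -200        -> intermediate (sub 1)
    B: index 25 at day -5,  prior 28 at day -150        -> high
    C: index 45 at day -20, prior 50 at day -180, N18.4 -> low (code arm)
    D: index 45, prior 50, no codes                     -> not in cohort
    E: index 20, prior 22, CPT 90935 (dialysis)         -> excluded
    F: single lab 25 at day -30 (no prior)              -> unclassified
    G: only lab at day -366 (outside lookback)          -> not tested
    """
    patients = [patient(p) for p in "ABCDEFG"]
    labs = [
        lab("A", 10, 25.0), lab("A", 200, 40.0),
        lab("B", 5, 25.0), lab("B", 150, 28.0),
        lab("C", 20, 45.0), lab("C", 180, 50.0),
        lab("D", 15, 45.0), lab("D", 170, 50.0),
        lab("E", 8, 20.0), lab("E", 120, 22.0),
        lab("F", 30, 25.0),
        lab("G", 366, 25.0),
    ]
    events = [
        CodedEvent("C", REF - timedelta(days=40), "ICD10", "N18.4"),
        CodedEvent("E", REF - timedelta(days=60), "CPT", "90935"),
    ]
    return Registry.from_records(patients, labs, events, REF)
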