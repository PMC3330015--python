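"""Shared fixtures: hand-written patients and the outcome-table fixture cohort."""

from __future__ import annotations

from datetime import date

import pytest

from ceafollow.evaluation import OutcomeFlags
from ceafollow.registry import (
    Arm,
    CEAMeasurement,
    Cohort,
    Comorbidity,
    PatientRecord,
    PatientStatus,
    Site,
    TumorN,
    TumorT,
)


def make_patient(
    patient_id: str = "P001",
    resection_date: date = date(2020, 1, 1),
    arm: Arm = Arm.SOFTWARE,
    postcode: str = "9700AB",
    status: PatientStatus = PatientStatus.ACTIVE,
) -> PatientRecord:
    return PatientRecord(
        patient_id=patient_id,
        resection_date=resection_date,
        arm=arm,
        site=Site.COLON,
        pT=TumorT.T3_4,
        pN=TumorN.N0,
        comorbidity=Comorbidity.MINOR_NONE,
        postcode=postcode,
        status=status,
    )


@pytest.fixture
def patient() -> PatientRecord:
    return make_patient()


@pytest.fixture
def two_patient_cohort() -> Cohort:
    """Two patients with three measurements each, as a hand-checkable ledger."""
    p1 = make_patient("P001", date(2020, 1, 1))
    p2 = make_patient("P002", date(2020, 6, 15), arm=Arm.CONVENTIONAL, postcode="5600ZA")
    measurements = [
        CEAMeasurement("P001", date(2020, 4, 1), 2.0, "lab_a"),
        CEAMeasurement("P001", date(2020, 7, 1), 2.1, "lab_a"),
        CEAMeasurement("P001", date(2020, 10, 1), 1.9, "lab_b"),
        CEAMeasurement("P002", date(2020, 9, 15), 3.0, "lab_a"),
        CEAMeasurement("P002", date(2020, 12, 15), 3.2, "lab_a"),
        CEAMeasurement("P002", date(2021, 3, 15), 3.1, "lab_a"),
    ]
    return Cohort.build([p1, p2], measurements)


def outcome_fixture_cohort() -> tuple[Cohort, dict[str, OutcomeFlags]]:
    """A 245-patient cohort mirroring the published follow-up outcomes.

    Synthetic stand-in for the real study ledger (which is not available):
    184 software-arm patients with 16 recurrences of which 7 curatively
    treated, and 61 conventional-arm patients with 8 recurrences of which 1
    curatively treated.
    """
    patients: list[PatientRecord] = []
    outcomes: dict[str, OutcomeFlags] = {}
    spec = [
        (Arm.SOFTWARE, 184, 16, 7),
        (Arm.CONVENTIONAL, 61, 8, 1),
    ]
    serial = 0
    for arm, n, n_recurrence, n_curative in spec:
        for i in range(n):
            serial += 1
            pid = f"F{serial:03d}"
            patients.append(make_patient(pid, date(2018, 1, 1), arm=arm))
            recurrence = i < n_recurrence
            curative = i < n_curative
            outcomes[pid] = OutcomeFlags(recurrence=recurrence, curative=curative)
    return Cohort.build(patients), outcomes


@pytest.fixture
def fixture_cohort() -> tuple[Cohort, dict[str, OutcomeFlags]]:
    return outcome_fixture_cohort()
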