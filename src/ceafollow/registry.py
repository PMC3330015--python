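"""Cohort ledger data model and delimited-text readers/writers.

The ledger is the audit record of a surveillance cohort: one patients table
(one row per patient, anchored by the resection date) and one measurements
table (one row per dated serum CEA value). Both are plain comma-delimited
text with a header row and ISO-8601 dates; enum fields use lower-case
snake-case labels. Validation is strict — a malformed row is rejected with
its row number and field, never silently repaired — because downstream
scheduling decisions are replayed from this record.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import pandas as pd

if TYPE_CHECKING:  # avoids a registry <-> engine import cycle
    from .engine import SurveillanceState

__all__ = [
    "Arm",
    "Site",
    "TumorT",
    "TumorN",
    "Comorbidity",
    "PatientStatus",
    "PatientRecord",
    "CEAMeasurement",
    "Cohort",
    "LedgerValidationError",
    "read_ledger",
    "write_ledger",
    "latest_measurement",
    "PATIENT_COLUMNS",
    "MEASUREMENT_COLUMNS",
]

PATIENT_COLUMNS = [
    "patient_id",
    "resection_date",
    "arm",
    "site",
    "pT",
    "pN",
    "comorbidity",
    "postcode",
    "status",
]
MEASUREMENT_COLUMNS = ["patient_id", "date", "value", "lab_id"]


class Arm(str, enum.Enum):
    """Follow-up arm: software-supported surveillance or conventional visits."""

    SOFTWARE = "software"
    CONVENTIONAL = "conventional"


class Site(str, enum.Enum):
    COLON = "colon"
    RECTUM = "rectum"


class TumorT(str, enum.Enum):
    """Pathological T stage, grouped as in the cohort characteristics table."""

    T0_1_2 = "t0_1_2"
    T3_4 = "t3_4"
    UNKNOWN = "unknown"


class TumorN(str, enum.Enum):
    N0 = "n0"
    N1_2 = "n1_2"


class Comorbidity(str, enum.Enum):
    MAJOR = "major"
    MINOR_NONE = "minor_none"


class PatientStatus(str, enum.Enum):
    """Protocol lifecycle of a patient.

    ``active`` patients are under algorithmic surveillance; ``ct_alert``
    patients have been escalated to imaging and leave the scheduling loop;
    ``discharged`` marks completion of the five-year protocol; ``lost``
    marks loss to follow-up.
    """

    ACTIVE = "active"
    CT_ALERT = "ct_alert"
    DISCHARGED = "discharged"
    LOST = "lost"


class LedgerValidationError(ValueError):
    """A ledger row violates the schema; names the row number and field."""

    def __init__(self, message: str, *, row: int | None = None, field: str | None = None):
        self.row = row
        self.field = field
        loc = ""
        if row is not None:
            loc = f"row {row}"
            if field is not None:
                loc += f", field '{field}'"
            loc = f" ({loc})"
        super().__init__(message + loc)


@dataclass(frozen=True)
class PatientRecord:
    """One surveilled patient; ``resection_date`` anchors the protocol clock."""

    patient_id: str
    resection_date: date
    arm: Arm
    site: Site
    pT: TumorT
    pN: TumorN
    comorbidity: Comorbidity
    postcode: str
    status: PatientStatus = PatientStatus.ACTIVE


@dataclass(frozen=True)
class CEAMeasurement:
    """One dated serum CEA value for one patient.

    The value is stored in whatever unit the ledger carries (the decision
    rules are purely relative, so the engine is unit-agnostic); it must be
    finite and strictly positive.
    """

    patient_id: str
    date: date
    value: float
    lab_id: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value) and self.value > 0):
            raise LedgerValidationError(
                f"CEA value must be finite and > 0, got {self.value!r}", field="value"
            )


@dataclass
class Cohort:
    """A validated cohort: patients, their measurements, and engine state.

    ``measurements`` are kept sorted per patient by date; ``states`` is the
    decision engine's per-patient memory and is populated by the engine
    (empty until the first sweep).
    """

    patients: dict[str, PatientRecord] = field(default_factory=dict)
    measurements: dict[str, list[CEAMeasurement]] = field(default_factory=dict)
    states: dict[str, "SurveillanceState"] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        patients: Iterable[PatientRecord],
        measurements: Iterable[CEAMeasurement] = (),
    ) -> "Cohort":
        cohort = cls()
        for p in patients:
            if p.patient_id in cohort.patients:
                raise LedgerValidationError(
                    f"duplicate patient_id {p.patient_id!r}", field="patient_id"
                )
            cohort.patients[p.patient_id] = p
            cohort.measurements[p.patient_id] = []
        for m in measurements:
            cohort.add_measurement(m)
        return cohort

    def add_measurement(self, m: CEAMeasurement) -> None:
        patient = self.patients.get(m.patient_id)
        if patient is None:
            raise LedgerValidationError(
                f"measurement references absent patient_id {m.patient_id!r}",
                field="patient_id",
            )
        if m.date <= patient.resection_date:
            raise LedgerValidationError(
                f"measurement on {m.date} does not postdate resection "
                f"({patient.resection_date}) for patient {m.patient_id!r}",
                field="date",
            )
        series = self.measurements.setdefault(m.patient_id, [])
        if any(existing.date == m.date for existing in series):
            raise LedgerValidationError(
                f"duplicate measurement date {m.date} for patient {m.patient_id!r}",
                field="date",
            )
        series.append(m)
        series.sort(key=lambda x: x.date)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_measurements(self) -> int:
        return sum(len(v) for v in self.measurements.values())

    def patient(self, patient_id: str) -> PatientRecord:
        try:
            return self.patients[patient_id]
        except KeyError:
            raise KeyError(f"unknown patient_id {patient_id!r}") from None

    def set_status(self, patient_id: str, status: PatientStatus) -> None:
        self.patients[patient_id] = replace(self.patient(patient_id), status=status)


def latest_measurement(cohort: Cohort, patient_id: str) -> CEAMeasurement | None:
    """Return the maximum-date measurement for a patient, or None if none exist."""
    cohort.patient(patient_id)  # raises KeyError for unknown ids
    series = cohort.measurements.get(patient_id, [])
    return series[-1] if series else None


def _parse_date(raw: object, *, row: int, field_name: str) -> date:
    try:
        return date.fromisoformat(str(raw).strip())
    except ValueError:
        raise LedgerValidationError(
            f"malformed ISO-8601 date {raw!r}", row=row, field=field_name
        ) from None


def _parse_enum(cls: type[enum.Enum], raw: object, *, row: int, field_name: str):
    try:
        return cls(str(raw).strip())
    except ValueError:
        allowed = ", ".join(e.value for e in cls)
        raise LedgerValidationError(
            f"unknown {field_name} label {raw!r} (allowed: {allowed})",
            row=row,
            field=field_name,
        ) from None


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(frame.columns) != columns:
        raise LedgerValidationError(
            f"{Path(path).name}: expected columns {columns}, found {list(frame.columns)}"
        )
    return frame


def read_ledger(patient_path: str | Path, measurement_path: str | Path) -> Cohort:
    """Read and validate the two ledger files into a :class:`Cohort`.

    Row numbers in error messages are 1-based data rows (the header is row 0).
    """
    patients_frame = _read_table(patient_path, PATIENT_COLUMNS)
    measurements_frame = _read_table(measurement_path, MEASUREMENT_COLUMNS)

    patients: list[PatientRecord] = []
    for idx, row in enumerate(patients_frame.itertuples(index=False), start=1):
        patients.append(
            PatientRecord(
                patient_id=row.patient_id,
                resection_date=_parse_date(row.resection_date, row=idx, field_name="resection_date"),
                arm=_parse_enum(Arm, row.arm, row=idx, field_name="arm"),
                site=_parse_enum(Site, row.site, row=idx, field_name="site"),
                pT=_parse_enum(TumorT, row.pT, row=idx, field_name="pT"),
                pN=_parse_enum(TumorN, row.pN, row=idx, field_name="pN"),
                comorbidity=_parse_enum(Comorbidity, row.comorbidity, row=idx, field_name="comorbidity"),
                postcode=row.postcode,
                status=_parse_enum(PatientStatus, row.status, row=idx, field_name="status"),
            )
        )
    cohort = Cohort.build(patients)

    for idx, row in enumerate(measurements_frame.itertuples(index=False), start=1):
        try:
            value = float(row.value)
        except ValueError:
            raise LedgerValidationError(
                f"non-numeric CEA value {row.value!r}", row=idx, field="value"
            ) from None
        if not (math.isfinite(value) and value > 0):
            raise LedgerValidationError(
                f"CEA value must be finite and > 0, got {value!r}", row=idx, field="value"
            )
        try:
            cohort.add_measurement(
                CEAMeasurement(
                    patient_id=row.patient_id,
                    date=_parse_date(row.date, row=idx, field_name="date"),
                    value=value,
                    lab_id=row.lab_id,
                )
            )
        except LedgerValidationError as err:
            if err.row is None:
                raise LedgerValidationError(str(err), row=idx, field=err.field) from None
            raise
    return cohort


def write_ledger(
    cohort: Cohort, patient_path: str | Path, measurement_path: str | Path
) -> None:
    """Write the cohort back to the two delimited files (round-trip exact)."""
    patient_rows = [
        {
            "patient_id": p.patient_id,
            "resection_date": p.resection_date.isoformat(),
            "arm": p.arm.value,
            "site": p.site.value,
            "pT": p.pT.value,
            "pN": p.pN.value,
            "comorbidity": p.comorbidity.value,
            "postcode": p.postcode,
            "status": p.status.value,
        }
        for p in cohort.patients.values()
    ]
    measurement_rows = [
        {
            "patient_id": m.patient_id,
            "date": m.date.isoformat(),
            "value": repr(m.value),
            "lab_id": m.lab_id,
        }
        for pid in cohort.patients
        for m in cohort.measurements.get(pid, [])
    ]
    pd.DataFrame(patient_rows, columns=PATIENT_COLUMNS).to_csv(patient_path, index=False)
    pd.DataFrame(measurement_rows, columns=MEASUREMENT_COLUMNS).to_csv(
        measurement_path, index=False
    )
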