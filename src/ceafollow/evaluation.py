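"""Workload arithmetic, cohort outcome summaries, and detection metrics.

The workload model prices the two follow-up policies in clinician hours: a
conventional outpatient visit of 15 minutes plus a 5-minute telephone call a
week later, on the quarterly/semiannual schedule (16 contacts over five
years), against one annual 15-minute visit plus 30 minutes of software work
per week for a reference cohort of 200 patients. The outcome summary turns
per-arm recurrence and curative-treatment counts into the reported
percentages. Detection metrics score a simulation's event log against its
hidden ground truth: sensitivity, false alerts, and the lead time from
recurrence onset to CT alert.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from statistics import median
from typing import Mapping

import pandas as pd

from .registry import Arm, Cohort
from .simulator import EventLog, SimulatedTruth

__all__ = [
    "WorkloadModel",
    "ConventionalWorkload",
    "SoftwareWorkload",
    "OutcomeSummary",
    "OutcomeFlags",
    "DetectionMetrics",
    "round_half_up",
    "outcome_percentage",
    "participation_pct",
    "workload_conventional",
    "workload_software",
    "annual_saving",
    "cohort_summary",
    "detection_metrics",
    "metrics_table",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-up (5.35 → 5.4 at one decimal), as tables print."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def outcome_percentage(count: int, total: int) -> float:
    """A count as a percentage, rounded the way outcome tables print it.

    Half-up to the whole percent, except an exact half percent (e.g. 1/8 →
    12.5) is kept at one decimal rather than rounded away by half a point.
    """
    if total <= 0:
        raise ZeroDivisionError("percentage of an empty denominator is undefined")
    pct = 100.0 * count / total
    one_decimal = round_half_up(pct, 1)
    if one_decimal % 1 == 0.5:
        return one_decimal
    return round_half_up(pct, 0)


def participation_pct(consented: int, eligible: int) -> float:
    """Consent/participation rate, reported to one decimal (184/245 → 75.1)."""
    if eligible <= 0:
        raise ZeroDivisionError("participation rate of an empty cohort is undefined")
    return round_half_up(100.0 * consented / eligible, 1)


@dataclass(frozen=True)
class WorkloadModel:
    """Unit costs and visit schedules of the two follow-up policies."""

    visit_minutes: float = 15.0
    call_minutes: float = 5.0
    weekly_software_minutes: float = 30.0
    reference_cohort: int = 200
    conventional_visits: int = 16  # 4/year × 3 y + 2/year × 2 y
    software_visits_per_year: int = 1
    weeks_per_year: int = 52

    def __post_init__(self) -> None:
        if min(self.visit_minutes, self.call_minutes, self.weekly_software_minutes) <= 0:
            raise ValueError("all durations must be positive")


@dataclass(frozen=True)
class ConventionalWorkload:
    per_patient_hours: float  # one decimal
    cohort_hours: float  # nearest hour


@dataclass(frozen=True)
class SoftwareWorkload:
    visit_hours: float
    software_hours: float
    total_hours: float


def workload_conventional(
    n_patients: int, model: WorkloadModel | None = None
) -> ConventionalWorkload:
    """Clinician hours for conventional follow-up of ``n_patients``.

    Per patient: 16 contacts × (visit + call) minutes. Reported per-patient
    hours round to one decimal, cohort totals to the nearest hour, so the
    pair (5.3 h, 1067 h) comes from a single computation.
    """
    model = model or WorkloadModel()
    if n_patients < 0:
        raise ValueError("n_patients must be non-negative")
    per_patient = model.conventional_visits * (model.visit_minutes + model.call_minutes) / 60.0
    return ConventionalWorkload(
        per_patient_hours=round_half_up(per_patient, 1),
        cohort_hours=round_half_up(n_patients * per_patient, 0),
    )


def workload_software(
    n_patients: int, years: int = 5, model: WorkloadModel | None = None
) -> SoftwareWorkload:
    """Clinician hours under software-supported follow-up.

    One annual visit per patient plus weekly software time, the latter
    scaled linearly with cohort size from the 200-patient reference (an
    extrapolation: the weekly cost is only known at the reference size).
    """
    model = model or WorkloadModel()
    if n_patients < 0 or years < 0:
        raise ValueError("n_patients and years must be non-negative")
    visit_hours = n_patients * years * model.software_visits_per_year * model.visit_minutes / 60.0
    software_hours = (
        model.weekly_software_minutes * model.weeks_per_year * years / 60.0
    ) * (n_patients / model.reference_cohort)
    return SoftwareWorkload(
        visit_hours=round_half_up(visit_hours, 0),
        software_hours=round_half_up(software_hours, 0),
        total_hours=round_half_up(visit_hours + software_hours, 0),
    )


def annual_saving(conventional_hours: float, software_hours: float, years: int) -> float:
    """Hours saved per year by the software policy; negative if it costs more."""
    if years <= 0:
        raise ValueError("years must be positive")
    return (conventional_hours - software_hours) / years


@dataclass(frozen=True)
class OutcomeFlags:
    """Per-patient outcome: recurrence and, if so, curative treatment."""

    recurrence: bool
    curative: bool = False

    def __post_init__(self) -> None:
        if self.curative and not self.recurrence:
            raise ValueError("curative treatment implies a recurrence")


@dataclass(frozen=True)
class OutcomeSummary:
    """Counts and printed-precision percentages for one arm.

    Percentages are None (undefined) when the denominator is zero, never 0.
    """

    arm: Arm
    n: int
    recurrences: int
    curative_count: int
    recurrence_pct: float | None
    curative_pct: float | None
    visits: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.curative_count <= self.recurrences <= self.n):
            raise ValueError("need curative_count <= recurrences <= n")


def cohort_summary(
    cohort: Cohort,
    outcomes: Mapping[str, OutcomeFlags],
    visits: Mapping[str, int] | None = None,
) -> dict[Arm, OutcomeSummary]:
    """Per-arm outcome summary from a cohort and its outcome flags.

    ``outcomes`` maps patient_id → flags; patients without an entry count as
    recurrence-free. ``visits`` optionally supplies per-patient visit counts
    for the distribution column.
    """
    for pid, flags in outcomes.items():
        cohort.patient(pid)  # unknown ids raise
        if flags.curative and not flags.recurrence:
            raise ValueError(f"patient {pid}: curative treatment without recurrence")
    out: dict[Arm, OutcomeSummary] = {}
    for arm in Arm:
        ids = [pid for pid, p in cohort.patients.items() if p.arm is arm]
        n = len(ids)
        rec = sum(1 for pid in ids if outcomes.get(pid, OutcomeFlags(False)).recurrence)
        cur = sum(1 for pid in ids if outcomes.get(pid, OutcomeFlags(False)).curative)
        out[arm] = OutcomeSummary(
            arm=arm,
            n=n,
            recurrences=rec,
            curative_count=cur,
            recurrence_pct=outcome_percentage(rec, n) if n else None,
            curative_pct=outcome_percentage(cur, rec) if rec else None,
            visits=tuple(sorted(visits.get(pid, 0) for pid in ids)) if visits else (),
        )
    return out


@dataclass(frozen=True)
class DetectionMetrics:
    """How well the trigger rules found the simulated recurrences.

    ``sensitivity`` is alerted recurrences over recurrences; ``lead_days``
    are alert date minus onset date for true detections (non-negative by
    construction when the trajectory is noise-free); ``false_alerts`` counts
    alerted recurrence-free patients, which requires within-patient noise.
    """

    sensitivity: float | None
    n_recurrences: int
    n_detected: int
    false_alerts: int
    lead_days: tuple[int, ...]
    visits_per_patient: float

    @property
    def median_lead_days(self) -> float | None:
        return float(median(self.lead_days)) if self.lead_days else None


def detection_metrics(log: EventLog, truth: SimulatedTruth) -> DetectionMetrics:
    """Score an event log against the simulation's ground truth."""
    unknown = log.patient_ids - set(truth)
    if unknown:
        raise ValueError(f"event log contains patients absent from truth: {sorted(unknown)[:5]}")
    alerts = log.alerts()
    recurrent = [t for t in truth.values() if t.has_recurrence]
    detected = [t for t in recurrent if t.patient_id in alerts]
    false_alerts = sum(1 for pid in alerts if not truth[pid].has_recurrence)
    lead = tuple(
        sorted((alerts[t.patient_id] - t.onset_date).days for t in detected)
    )
    counts = log.draw_counts()
    visits = sum(counts.values()) / len(truth) if truth else 0.0
    return DetectionMetrics(
        sensitivity=len(detected) / len(recurrent) if recurrent else None,
        n_recurrences=len(recurrent),
        n_detected=len(detected),
        false_alerts=false_alerts,
        lead_days=lead,
        visits_per_patient=visits,
    )


def metrics_table(
    n_patients: int,
    years: int,
    summaries: dict[Arm, OutcomeSummary] | None = None,
    detection: DetectionMetrics | None = None,
    model: WorkloadModel | None = None,
) -> pd.DataFrame:
    """The evaluation report as a two-column (metric, value) table.

    Metric names are fixed: per_patient_hours, cohort_hours_conventional,
    cohort_hours_software, annual_saving_hours, recurrence_pct_<arm>,
    curative_pct_<arm>, sensitivity, false_alerts, median_lead_days,
    visits_per_patient.
    """
    model = model or WorkloadModel()
    conv = workload_conventional(n_patients, model)
    soft = workload_software(n_patients, years, model)
    rows: list[tuple[str, object]] = [
        ("per_patient_hours", conv.per_patient_hours),
        ("cohort_hours_conventional", conv.cohort_hours),
        ("cohort_hours_software", soft.total_hours),
        ("annual_saving_hours", round_half_up(annual_saving(conv.cohort_hours, soft.total_hours, years), 1)),
    ]
    if summaries:
        for arm, s in summaries.items():
            rows.append((f"recurrence_pct_{arm.value}", s.recurrence_pct))
            rows.append((f"curative_pct_{arm.value}", s.curative_pct))
    if detection is not None:
        rows += [
            ("sensitivity", detection.sensitivity),
            ("false_alerts", detection.false_alerts),
            ("median_lead_days", detection.median_lead_days),
            ("visits_per_patient", round_half_up(detection.visits_per_patient, 2)),
        ]
    return pd.DataFrame(rows, columns=["metric", "value"])
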