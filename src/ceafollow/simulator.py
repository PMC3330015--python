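"""Closed-loop synthetic cohort generator for CEA surveillance.

Emulates the serum-CEA kinetics the decision engine was built for: baselines
near the normal range (median 2.2, in the ledger's unit) with roughly 55%
inter-individual variation, small multiplicative assay/biological noise
within a patient, and — in a configurable fraction of patients — a
recurrence whose marker excess grows exponentially with a fixed doubling
time from a hidden onset date.

The loop is *closed*: after the first scheduled draw, every subsequent draw
date is whatever the engine asked for (routine interval, or the six-week
recheck after a significant rise), so the sampling process itself depends on
the trajectory — exactly as in deployment. Missed draws (adherence < 1)
reschedule at the next routine calendar date.

Everything is deterministic given the seed: each patient owns a pseudo-random
stream spawned from (seed, patient index), so a patient's trajectory does not
depend on cohort size or on other patients.
"""

from __future__ import annotations

import enum
import math
import string
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from dateutil.relativedelta import relativedelta

from .engine import (
    Action,
    EventKind,
    Recommendation,
    Thresholds,
    initial_state,
    protocol_calendar,
    update_state,
)
from .registry import (
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

__all__ = [
    "SimulationConfig",
    "TruthEntry",
    "SimulatedTruth",
    "DrawEvent",
    "EventLog",
    "simulate_cohort",
    "trajectory_value",
    "run_closed_loop",
    "write_truth",
    "read_truth",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = ["patient_id", "has_recurrence", "onset_date", "baseline"]

# Marginal frequencies for the descriptive patient fields, matching a mixed
# colon/rectum surveillance cohort; they do not influence the kinetics.
_P_COLON = 0.58
_P_T34 = 0.69
_P_N0 = 0.62
_P_MAJOR_COMORBIDITY = 0.14


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters.

    ``baseline_median`` and ``inter_cv`` fix the across-patient log-normal
    baseline distribution (median 2.2 with 55% coefficient of variation —
    the normal-range behaviour the rules assume). ``intra_cv`` is the
    within-patient multiplicative noise CV per draw. A recurrence occurs
    with probability ``recurrence_fraction``, its onset uniform between
    ``onset_window_months`` after resection, and adds
    ``signal_amplitude · 2^((t − onset)/doubling_time_days)`` to the mean.
    ``adherence`` is the probability a scheduled draw actually happens;
    ``arm_split`` the fraction assigned to the software arm.
    """

    n_patients: int = 200
    baseline_median: float = 2.2
    inter_cv: float = 0.55
    intra_cv: float = 0.08
    recurrence_fraction: float = 0.10
    onset_window_months: tuple[int, int] = (3, 54)
    doubling_time_days: float = 60.0
    signal_amplitude: float = 1.0
    adherence: float = 1.0
    arm_split: float = 0.75
    start_date: date = date(2015, 1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.doubling_time_days <= 0:
            raise ValueError("doubling_time_days must be positive")
        for name in ("inter_cv", "intra_cv", "recurrence_fraction", "adherence", "arm_split"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.baseline_median <= 0 or self.signal_amplitude < 0:
            raise ValueError("baseline_median must be > 0 and signal_amplitude >= 0")
        lo, hi = self.onset_window_months
        if not 0 <= lo < hi:
            raise ValueError("onset_window_months must be an increasing non-negative pair")


@dataclass(frozen=True)
class TruthEntry:
    """Hidden ground truth for one patient."""

    patient_id: str
    has_recurrence: bool
    onset_date: date | None
    baseline: float

    def __post_init__(self) -> None:
        if self.has_recurrence != (self.onset_date is not None):
            raise ValueError("onset_date must be set iff has_recurrence")


SimulatedTruth = dict[str, TruthEntry]


def _lognormal_sigma(cv: float) -> float:
    """σ of ln X for a log-normal with coefficient of variation ``cv``."""
    return math.sqrt(math.log(1.0 + cv * cv))


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _random_postcode(rng: np.random.Generator) -> str:
    digits = "".join(str(rng.integers(0, 10)) for _ in range(4))
    letters = "".join(string.ascii_uppercase[rng.integers(0, 26)] for _ in range(2))
    return digits + letters


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, SimulatedTruth]:
    """Draw a cohort of patients with hidden recurrence ground truth.

    The returned cohort has no measurements yet — values are sampled when
    :func:`run_closed_loop` (or the engine, on real data) asks for them.
    Deterministic given ``config.seed``.
    """
    sigma = _lognormal_sigma(config.inter_cv)
    mu = math.log(config.baseline_median)
    lo_m, hi_m = config.onset_window_months
    window_start = config.start_date + relativedelta(months=lo_m)
    window_days = (config.start_date + relativedelta(months=hi_m) - window_start).days

    patients: list[PatientRecord] = []
    truth: SimulatedTruth = {}
    width = max(4, len(str(config.n_patients)))
    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        pid = f"P{i + 1:0{width}d}"
        baseline = float(np.exp(mu + sigma * rng.standard_normal()))
        has_recurrence = bool(rng.random() < config.recurrence_fraction)
        onset = (
            window_start + timedelta(days=int(rng.integers(0, window_days + 1)))
            if has_recurrence
            else None
        )
        arm = Arm.SOFTWARE if rng.random() < config.arm_split else Arm.CONVENTIONAL
        patients.append(
            PatientRecord(
                patient_id=pid,
                resection_date=config.start_date,
                arm=arm,
                site=Site.COLON if rng.random() < _P_COLON else Site.RECTUM,
                pT=TumorT.T3_4 if rng.random() < _P_T34 else TumorT.T0_1_2,
                pN=TumorN.N0 if rng.random() < _P_N0 else TumorN.N1_2,
                comorbidity=(
                    Comorbidity.MAJOR
                    if rng.random() < _P_MAJOR_COMORBIDITY
                    else Comorbidity.MINOR_NONE
                ),
                postcode=_random_postcode(rng),
                status=PatientStatus.ACTIVE,
            )
        )
        truth[pid] = TruthEntry(pid, has_recurrence, onset, baseline)
    return Cohort.build(patients), truth


def trajectory_value(
    entry: TruthEntry,
    at: date,
    *,
    signal_amplitude: float = 1.0,
    doubling_time_days: float = 60.0,
    intra_cv: float = 0.08,
    rng: np.random.Generator | None = None,
) -> float:
    """Sample the marker at a date: baseline, plus exponential excess after onset.

    The mean is ``baseline`` up to and including the onset date, and
    ``baseline + signal_amplitude · 2^((at − onset)/doubling_time)`` strictly
    after it. Noise is a multiplicative log-normal factor with unit mean and
    coefficient of variation ``intra_cv``; the result is strictly positive.
    """
    mean = entry.baseline
    if entry.has_recurrence and entry.onset_date is not None and at > entry.onset_date:
        days = (at - entry.onset_date).days
        mean = entry.baseline + signal_amplitude * 2.0 ** (days / doubling_time_days)
    if intra_cv <= 0:
        return mean
    if rng is None:
        raise ValueError("an rng is required when intra_cv > 0")
    sigma = _lognormal_sigma(intra_cv)
    factor = float(np.exp(sigma * rng.standard_normal() - 0.5 * sigma * sigma))
    return mean * factor


@dataclass(frozen=True)
class DrawEvent:
    """One blood draw and the engine's response to it."""

    patient_id: str
    date: date
    value: float
    rise: float
    action: Action
    due_date: date | None


@dataclass
class EventLog:
    """Per-patient record of every draw and recommendation in a simulation."""

    draws: list[DrawEvent] = field(default_factory=list)

    def for_patient(self, patient_id: str) -> list[DrawEvent]:
        return [d for d in self.draws if d.patient_id == patient_id]

    def alerts(self) -> dict[str, date]:
        """patient_id → date of the CT alert, for alerted patients."""
        return {d.patient_id: d.date for d in self.draws if d.action is Action.CT_ALERT}

    def draw_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for d in self.draws:
            counts[d.patient_id] = counts.get(d.patient_id, 0) + 1
        return counts

    @property
    def patient_ids(self) -> set[str]:
        return {d.patient_id for d in self.draws}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": d.patient_id,
                    "date": d.date.isoformat(),
                    "value": d.value,
                    "rise": d.rise,
                    "action": d.action.value,
                    "due_date": d.due_date.isoformat() if d.due_date else "",
                }
                for d in self.draws
            ],
            columns=["patient_id", "date", "value", "rise", "action", "due_date"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventLog":
        draws = [
            DrawEvent(
                patient_id=str(row.patient_id),
                date=date.fromisoformat(str(row.date)),
                value=float(row.value),
                rise=float(row.rise),
                action=Action(str(row.action)),
                due_date=date.fromisoformat(str(row.due_date)) if str(row.due_date) else None,
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(draws)


def run_closed_loop(
    cohort: Cohort,
    truth: SimulatedTruth,
    config: SimulationConfig,
    thresholds: Thresholds | None = None,
) -> EventLog:
    """Run the engine-in-the-loop simulation for every patient.

    Each patient starts at the first calendar draw (month 3). Every draw is
    attended with probability ``config.adherence`` — a missed draw
    reschedules at the next routine calendar date — and its value is sampled
    from the patient's trajectory. The engine's recommendation then fixes
    the next draw date; the loop ends at ct_alert, discharge, or when the
    calendar is exhausted. Sampled measurements are appended to the cohort
    ledger; ``cohort.states`` reflects each patient's final state.
    """
    thresholds = thresholds or Thresholds()
    log = EventLog()
    index_of = {pid: i for i, pid in enumerate(cohort.patients)}
    for pid in cohort.patients:
        patient = cohort.patients[pid]
        entry = truth[pid]
        rng = _patient_rng(config.seed, index_of[pid]).spawn(1)[0]
        calendar = [
            e.date for e in protocol_calendar(patient, thresholds) if e.kind is EventKind.LAB_DRAW
        ]
        state = initial_state(patient, thresholds)
        cohort.states[pid] = state
        next_date: date | None = calendar[0]
        previous: CEAMeasurement | None = None
        while next_date is not None:
            if config.adherence < 1.0 and rng.random() >= config.adherence:
                later = [d for d in calendar if d > next_date]
                next_date = later[0] if later else None
                continue
            value = trajectory_value(
                entry,
                next_date,
                signal_amplitude=config.signal_amplitude,
                doubling_time_days=config.doubling_time_days,
                intra_cv=config.intra_cv,
                rng=rng if config.intra_cv > 0 else None,
            )
            measurement = CEAMeasurement(pid, next_date, value, lab_id="sim")
            cohort.add_measurement(measurement)
            state, rec = update_state(state, measurement, previous, patient, thresholds)
            cohort.states[pid] = state
            cohort.set_status(pid, state.status)
            log.draws.append(
                DrawEvent(pid, next_date, value, rec.rise, rec.action, rec.due_date)
            )
            previous = measurement
            next_date = rec.due_date
    return log


def write_truth(truth: SimulatedTruth, path: str | Path) -> None:
    rows = [
        {
            "patient_id": t.patient_id,
            "has_recurrence": str(t.has_recurrence).lower(),
            "onset_date": t.onset_date.isoformat() if t.onset_date else "",
            "baseline": repr(t.baseline),
        }
        for t in truth.values()
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, index=False)


def read_truth(path: str | Path) -> SimulatedTruth:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    truth: SimulatedTruth = {}
    for row in frame.itertuples(index=False):
        has_rec = str(row.has_recurrence).lower() == "true"
        truth[str(row.patient_id)] = TruthEntry(
            patient_id=str(row.patient_id),
            has_recurrence=has_rec,
            onset_date=date.fromisoformat(str(row.onset_date)) if has_rec else None,
            baseline=float(row.baseline),
        )
    return truth
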