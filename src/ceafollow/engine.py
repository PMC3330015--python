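"""The CEA surveillance decision engine.

Implements the trigger rules for marker-guided follow-up after curative
colorectal cancer resection: every new serum CEA value is referenced to the
patient's previous value; a relative rise above 20% sends the patient back
to the laboratory in six weeks, and a rise above 40% — or a second
significant rise in a row — escalates to a CT alert. Steady values return
the patient to the routine schedule: quarterly draws for the first three
years (intensive phase), semiannual draws for years four and five (extended
phase), discharge after five years.

Threshold inequalities are strict: a rise of exactly 20% is steady, exactly
40% is significant but not large. The consecutive-rise counter resets on any
steady result, decreases included; consecutiveness is interrupted the moment
a value stops rising. The large-rise rule applies between any two consecutive
measurements regardless of the interval separating them. The first
measurement ever is steady by definition (there is no reference value).

Calendar arithmetic: "3 months"/"6 months" are calendar-month additions with
end-of-month clamping; "6 weeks" is exactly 42 days.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from pathlib import Path

import pandas as pd
from dateutil.relativedelta import relativedelta

from .registry import (
    CEAMeasurement,
    Cohort,
    PatientRecord,
    PatientStatus,
    latest_measurement,
)

__all__ = [
    "Thresholds",
    "SurveillanceState",
    "RiseClass",
    "Action",
    "Phase",
    "Recommendation",
    "ProtocolEvent",
    "EventKind",
    "Letter",
    "relative_rise",
    "classify_rise",
    "phase_of",
    "update_state",
    "protocol_calendar",
    "daily_sweep",
    "suggest_lab",
    "generate_letter",
    "initial_state",
    "recommendations_frame",
    "DEFAULT_LETTER_TEMPLATE",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds and protocol calendar parameters.

    ``significant_rise`` and ``large_rise`` are relative-rise fractions
    (0.20 → "+20%"); ``recheck_interval`` is the early re-lab delay after a
    significant rise; the two phase intervals are calendar months between
    routine draws; ``intensive_years``/``total_years`` bound the quarterly
    phase and the whole protocol.
    """

    significant_rise: float = 0.20
    large_rise: float = 0.40
    recheck_interval: timedelta = timedelta(weeks=6)
    intensive_interval_months: int = 3
    extended_interval_months: int = 6
    intensive_years: int = 3
    total_years: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.significant_rise < self.large_rise):
            raise ValueError("need 0 < significant_rise < large_rise")
        # 30-day months suffice for the ordering check
        if self.recheck_interval >= timedelta(days=30 * self.intensive_interval_months):
            raise ValueError("recheck_interval must be shorter than the intensive interval")

    @property
    def intensive_end_months(self) -> int:
        return 12 * self.intensive_years

    @property
    def total_months(self) -> int:
        return 12 * self.total_years


class RiseClass(enum.IntEnum):
    """Ordered severity of a relative rise between consecutive values."""

    STEADY = 0
    SIGNIFICANT_RISE = 1
    LARGE_RISE = 2


class Action(str, enum.Enum):
    """What the engine asks for after a new measurement.

    ``routine_relab`` — next draw on the phase schedule; ``early_relab`` —
    six-week recheck after one significant rise; ``ct_alert`` — escalate to
    CT imaging (clinician phone task, no letter); ``discharge`` — the
    five-year protocol is complete.
    """

    ROUTINE_RELAB = "routine_relab"
    EARLY_RELAB = "early_relab"
    CT_ALERT = "ct_alert"
    DISCHARGE = "discharge"


_SEVERITY = {
    Action.DISCHARGE: 0,
    Action.ROUTINE_RELAB: 0,
    Action.EARLY_RELAB: 1,
    Action.CT_ALERT: 2,
}


class Phase(str, enum.Enum):
    INTENSIVE = "intensive"
    EXTENDED = "extended"
    POST_SURVEILLANCE = "post_surveillance"


@dataclass(frozen=True)
class SurveillanceState:
    """Per-patient memory of the state machine.

    ``consecutive_rises`` holds the "two times in a row" counter; it is 0 or
    1 while the patient is active (a second rise forces ``ct_alert``).
    """

    patient_id: str
    consecutive_rises: int = 0
    last_date: date | None = None
    next_due: date | None = None
    status: PatientStatus = PatientStatus.ACTIVE


@dataclass(frozen=True)
class Recommendation:
    """The engine's output for one new measurement.

    ``due_date`` is set for re-lab actions and None for ``ct_alert`` and
    ``discharge``, which leave the scheduling loop. ``rise`` is the signed
    relative change against the previous value (0.0 for a first measurement).
    """

    patient_id: str
    action: Action
    due_date: date | None
    rise: float
    reason: str
    date: date | None = None

    def __post_init__(self) -> None:
        terminal = self.action in (Action.CT_ALERT, Action.DISCHARGE)
        if terminal != (self.due_date is None):
            raise ValueError("due_date must be None exactly for ct_alert/discharge")


class EventKind(str, enum.Enum):
    LAB_DRAW = "lab_draw"
    ANNUAL_VISIT = "annual_visit"
    CT_SCAN = "ct_scan"
    COLONOSCOPY = "colonoscopy"


@dataclass(frozen=True)
class ProtocolEvent:
    date: date
    kind: EventKind


def initial_state(patient: PatientRecord, thresholds: Thresholds | None = None) -> SurveillanceState:
    """Fresh state for a patient entering surveillance after resection."""
    thresholds = thresholds or Thresholds()
    return SurveillanceState(
        patient_id=patient.patient_id,
        consecutive_rises=0,
        last_date=None,
        next_due=patient.resection_date + relativedelta(months=thresholds.intensive_interval_months),
        status=PatientStatus.ACTIVE,
    )


def relative_rise(previous: float, current: float) -> float:
    """Signed relative change of ``current`` against ``previous``: c/p − 1."""
    if previous <= 0 or current <= 0:
        raise ValueError("CEA concentrations must be strictly positive")
    return current / previous - 1.0


def classify_rise(rise: float, thresholds: Thresholds | None = None) -> RiseClass:
    """Classify a signed rise; strict inequalities, all decreases are steady."""
    thresholds = thresholds or Thresholds()
    if rise > thresholds.large_rise:
        return RiseClass.LARGE_RISE
    if rise > thresholds.significant_rise:
        return RiseClass.SIGNIFICANT_RISE
    return RiseClass.STEADY


def phase_of(resection_date: date, at: date, thresholds: Thresholds | None = None) -> Phase:
    """Protocol phase at a calendar date: quarterly, semiannual, or finished."""
    thresholds = thresholds or Thresholds()
    if at < resection_date:
        raise ValueError(f"date {at} precedes resection {resection_date}")
    if at < resection_date + relativedelta(months=thresholds.intensive_end_months):
        return Phase.INTENSIVE
    if at < resection_date + relativedelta(months=thresholds.total_months):
        return Phase.EXTENDED
    return Phase.POST_SURVEILLANCE


def update_state(
    state: SurveillanceState,
    measurement: CEAMeasurement,
    previous: CEAMeasurement | None,
    patient: PatientRecord,
    thresholds: Thresholds | None = None,
) -> tuple[SurveillanceState, Recommendation]:
    """Apply one new measurement to the state machine.

    Returns a new state and the recommendation; the input state is unchanged.
    The second significant rise is judged against the immediately preceding
    (already elevated) value, consistent with referencing every measurement
    to the previous one.
    """
    thresholds = thresholds or Thresholds()
    if state.status is not PatientStatus.ACTIVE:
        raise ValueError(f"patient {state.patient_id} is not active ({state.status.value})")
    if state.last_date is not None and measurement.date <= state.last_date:
        raise ValueError(
            f"measurement on {measurement.date} is not after the last processed "
            f"date {state.last_date} for patient {state.patient_id}"
        )

    if previous is None:
        rise = 0.0
        rise_class = RiseClass.STEADY
    else:
        rise = relative_rise(previous.value, measurement.value)
        rise_class = classify_rise(rise, thresholds)

    if rise_class is RiseClass.LARGE_RISE or (
        rise_class is RiseClass.SIGNIFICANT_RISE and state.consecutive_rises >= 1
    ):
        reason = (
            f"large rise of {rise:+.0%} (>{thresholds.large_rise:.0%})"
            if rise_class is RiseClass.LARGE_RISE
            else f"significant rise of {rise:+.0%} twice in a row"
        )
        new_state = replace(
            state,
            consecutive_rises=state.consecutive_rises + 1,
            last_date=measurement.date,
            next_due=None,
            status=PatientStatus.CT_ALERT,
        )
        rec = Recommendation(
            patient_id=state.patient_id,
            action=Action.CT_ALERT,
            due_date=None,
            rise=rise,
            reason=f"{reason}; call patient to plan CT of thorax and abdomen",
            date=measurement.date,
        )
        return new_state, rec

    if rise_class is RiseClass.SIGNIFICANT_RISE:
        due = measurement.date + thresholds.recheck_interval
        new_state = replace(
            state,
            consecutive_rises=1,
            last_date=measurement.date,
            next_due=due,
            status=PatientStatus.ACTIVE,
        )
        rec = Recommendation(
            patient_id=state.patient_id,
            action=Action.EARLY_RELAB,
            due_date=due,
            rise=rise,
            reason=f"significant rise of {rise:+.0%} (>{thresholds.significant_rise:.0%}); recheck in 6 weeks",
            date=measurement.date,
        )
        return new_state, rec

    # Steady: counter resets; interval follows the phase at the measurement date.
    phase = phase_of(patient.resection_date, measurement.date, thresholds)
    end_of_protocol = patient.resection_date + relativedelta(months=thresholds.total_months)
    if phase is Phase.POST_SURVEILLANCE:
        due = None
    else:
        months = (
            thresholds.intensive_interval_months
            if phase is Phase.INTENSIVE
            else thresholds.extended_interval_months
        )
        due = measurement.date + relativedelta(months=months)
        if due > end_of_protocol:
            due = None

    if due is None:
        new_state = replace(
            state,
            consecutive_rises=0,
            last_date=measurement.date,
            next_due=None,
            status=PatientStatus.DISCHARGED,
        )
        rec = Recommendation(
            patient_id=state.patient_id,
            action=Action.DISCHARGE,
            due_date=None,
            rise=rise,
            reason="five-year surveillance complete; discharge from follow-up",
            date=measurement.date,
        )
        return new_state, rec

    new_state = replace(
        state,
        consecutive_rises=0,
        last_date=measurement.date,
        next_due=due,
        status=PatientStatus.ACTIVE,
    )
    rec = Recommendation(
        patient_id=state.patient_id,
        action=Action.ROUTINE_RELAB,
        due_date=due,
        rise=rise,
        reason=f"CEA steady ({rise:+.0%}); routine re-lab in {phase.value} phase",
        date=measurement.date,
    )
    return new_state, rec


_EVENT_ORDER = {
    EventKind.LAB_DRAW: 0,
    EventKind.ANNUAL_VISIT: 1,
    EventKind.CT_SCAN: 2,
    EventKind.COLONOSCOPY: 3,
}


def protocol_calendar(
    patient: PatientRecord, thresholds: Thresholds | None = None
) -> list[ProtocolEvent]:
    """The fixed five-year protocol calendar for one patient.

    Routine lab draws at months 3, 6, …, 36 then 42, 48, 54, 60 (16 total);
    an annual outpatient visit and CT scan at months 12, 24, 36, 48, 60;
    one colonoscopy at month 36. Sorted by date.
    """
    thresholds = thresholds or Thresholds()
    anchor = patient.resection_date
    events: list[ProtocolEvent] = []

    months = list(
        range(thresholds.intensive_interval_months, thresholds.intensive_end_months + 1,
              thresholds.intensive_interval_months)
    ) + list(
        range(thresholds.intensive_end_months + thresholds.extended_interval_months,
              thresholds.total_months + 1, thresholds.extended_interval_months)
    )
    events += [ProtocolEvent(anchor + relativedelta(months=m), EventKind.LAB_DRAW) for m in months]
    for year in range(1, thresholds.total_years + 1):
        visit_date = anchor + relativedelta(months=12 * year)
        events.append(ProtocolEvent(visit_date, EventKind.ANNUAL_VISIT))
        events.append(ProtocolEvent(visit_date, EventKind.CT_SCAN))
    events.append(
        ProtocolEvent(anchor + relativedelta(months=thresholds.intensive_end_months),
                      EventKind.COLONOSCOPY)
    )
    events.sort(key=lambda e: (e.date, _EVENT_ORDER[e.kind]))
    return events


def daily_sweep(
    cohort: Cohort, today: date, thresholds: Thresholds | None = None
) -> list[Recommendation]:
    """One daily pass over the cohort, as the deployed system ran it.

    For every active patient whose latest measurement postdates the state's
    last processed date, fold the unprocessed measurements (up to ``today``)
    through :func:`update_state` in date order and emit the final
    recommendation. Updates ``cohort.states`` and patient status in place.
    Idempotent: a second sweep on the same day returns an empty list.
    Recommendations are returned in ascending patient_id order.
    """
    thresholds = thresholds or Thresholds()
    out: list[Recommendation] = []
    for patient_id in sorted(cohort.patients):
        patient = cohort.patients[patient_id]
        state = cohort.states.get(patient_id)
        if state is None:
            state = initial_state(patient, thresholds)
            cohort.states[patient_id] = state
        if state.status is not PatientStatus.ACTIVE:
            continue
        series = cohort.measurements.get(patient_id, [])
        pending = [
            m for m in series
            if m.date <= today and (state.last_date is None or m.date > state.last_date)
        ]
        if not pending:
            continue
        rec: Recommendation | None = None
        try:
            for m in pending:
                previous = _measurement_before(series, m.date)
                state, rec = update_state(state, m, previous, patient, thresholds)
                if state.status is not PatientStatus.ACTIVE:
                    break
        except ValueError as err:  # invalid patients are skipped, never fatal
            logger.warning("skipping patient %s during sweep: %s", patient_id, err)
            continue
        cohort.states[patient_id] = state
        cohort.set_status(patient_id, state.status)
        if rec is not None:
            out.append(rec)
    return out


def _measurement_before(series: list[CEAMeasurement], at: date) -> CEAMeasurement | None:
    previous = None
    for m in series:
        if m.date < at:
            previous = m
        else:
            break
    return previous


def suggest_lab(
    postcode: str,
    lab_directory: dict[str, str],
    default: str | None = None,
) -> str:
    """Suggest the local laboratory whose postcode prefix matches longest.

    An empty-string prefix in the directory acts as the catch-all; an
    explicit ``default`` is used when nothing (not even "") matches.
    """
    if not lab_directory and default is None:
        raise ValueError("lab directory is empty and no default lab configured")
    best: str | None = None
    best_len = -1
    for prefix, name in lab_directory.items():
        if postcode.startswith(prefix) and len(prefix) > best_len:
            best, best_len = name, len(prefix)
    if best is not None:
        return best
    if default is not None:
        return default
    raise ValueError(f"no laboratory matches postcode {postcode!r} and no default configured")


DEFAULT_LETTER_TEMPLATE = """\
Dear patient {patient_id},

Your latest CEA measurement of {date} gave a value of {value}.
This value gives no cause to change your follow-up schedule.

Please have blood drawn again on or around {due_date}.
You can do so at your local laboratory: {lab}.

With kind regards,
the surgical outpatient clinic
"""


@dataclass
class Letter:
    """A rendered patient letter; held until a clinician approves it."""

    patient_id: str
    text: str
    approved: bool = False
    approved_at: datetime | None = None

    def approve(self, when: datetime | None = None) -> None:
        self.approved = True
        self.approved_at = when or datetime.now()


def generate_letter(
    patient: PatientRecord,
    measurement: CEAMeasurement,
    recommendation: Recommendation,
    lab: str,
    template: str = DEFAULT_LETTER_TEMPLATE,
) -> Letter:
    """Render the patient letter for a re-lab recommendation.

    CT alerts are a clinician phone task, not a letter; passing one is a
    contract violation. The rendered text carries the latest value, its
    date, the next due date and the suggested laboratory verbatim.
    """
    if recommendation.action is Action.CT_ALERT:
        raise ValueError("ct_alert recommendations produce a phone task, not a letter")
    due = recommendation.due_date.isoformat() if recommendation.due_date else "n/a"
    text = template.format(
        patient_id=patient.patient_id,
        value=f"{measurement.value:g}",
        date=measurement.date.isoformat(),
        due_date=due,
        lab=lab,
    )
    return Letter(patient_id=patient.patient_id, text=text)


def recommendations_frame(recommendations: list[Recommendation]) -> pd.DataFrame:
    """Recommendations as the exportable delimited table."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "date": r.date.isoformat() if r.date else "",
                "rise": r.rise,
                "action": r.action.value,
                "due_date": r.due_date.isoformat() if r.due_date else "",
                "reason": r.reason,
            }
            for r in recommendations
        ],
        columns=["patient_id", "date", "rise", "action", "due_date", "reason"],
    )
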