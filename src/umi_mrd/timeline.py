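"""Longitudinal monitoring: per-patient timelines and cohort summary.

Plasma sample calls are assembled against the clinical course (day 0 =
definitive treatment).  Derived quantities: baseline status (latest sample
drawn on or before day 0), clearance (first evaluable post-treatment sample
negative), molecular recurrence (first post-treatment positive sample) and
lead time = clinical recurrence day − molecular recurrence day, positive
when the blood test anticipated the clinic.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .calling import PlasmaSampleCall

EVENT_TYPES = (
    "treatment",
    "adjuvant_therapy",
    "clinical_recurrence_local",
    "clinical_recurrence_distant",
    "last_followup",
)
RECURRENCE_EVENTS = ("clinical_recurrence_local", "clinical_recurrence_distant")


@dataclass(frozen=True)
class ClinicalEvent:
    patient_id: str
    event_type: str
    day: int

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")


@dataclass(frozen=True)
class PatientTimeline:
    patient_id: str
    samples: tuple[PlasmaSampleCall, ...]  # sorted by day
    events: tuple[ClinicalEvent, ...]
    baseline_positive: Optional[bool]
    clearance: Optional[bool]
    molecular_recurrence_day: Optional[int]
    clinical_recurrence_day: Optional[int]
    lead_time_days: Optional[int]


def build_timeline(
    calls: Iterable[PlasmaSampleCall], events: Iterable[ClinicalEvent]
) -> PatientTimeline:
    """Derive the monitoring timeline for one patient.

    Requires exactly one treatment event at day 0 and unique sample days;
    non-evaluable samples are kept in the record but skipped when deriving
    baseline, clearance and molecular recurrence.
    """
    calls = sorted(calls, key=lambda s: s.collection_day)
    events = tuple(events)
    if not calls:
        raise ValueError("timeline needs at least one plasma sample")
    patients = {s.patient_id for s in calls} | {e.patient_id for e in events}
    if len(patients) != 1:
        raise ValueError(f"records span multiple patients: {sorted(patients)}")
    treatments = [e for e in events if e.event_type == "treatment"]
    if len(treatments) != 1 or treatments[0].day != 0:
        raise ValueError("exactly one treatment event at day 0 is required")
    days = [s.collection_day for s in calls]
    if len(set(days)) != len(days):
        raise ValueError("duplicate sample collection days")

    evaluable = [s for s in calls if s.sample_positive is not None]
    baseline = [s for s in evaluable if s.collection_day <= 0]
    baseline_positive = baseline[-1].sample_positive if baseline else None

    post = [s for s in evaluable if s.collection_day > 0]
    clearance = (not post[0].sample_positive) if post else None
    positives = [s for s in post if s.sample_positive]
    molecular_day = positives[0].collection_day if positives else None

    recurrences = [e.day for e in events if e.event_type in RECURRENCE_EVENTS]
    clinical_day = min(recurrences) if recurrences else None
    lead = (
        clinical_day - molecular_day
        if clinical_day is not None and molecular_day is not None
        else None
    )
    return PatientTimeline(
        patient_id=patients.pop(),
        samples=tuple(calls),
        events=events,
        baseline_positive=baseline_positive,
        clearance=clearance,
        molecular_recurrence_day=molecular_day,
        clinical_recurrence_day=clinical_day,
        lead_time_days=lead,
    )


def lead_time(timeline: PatientTimeline) -> Optional[int]:
    """Days from molecular to clinical recurrence; positive when the blood
    draw came first, None unless both recurrences exist."""
    return timeline.lead_time_days


def _pct(numerator: int, denominator: int) -> Optional[int]:
    """Integer percentage, rounded half-up (matching 6/7 -> 86)."""
    if denominator == 0:
        return None
    return int(
        (decimal.Decimal(numerator) * 100 / decimal.Decimal(denominator)).quantize(
            decimal.Decimal(1), rounding=decimal.ROUND_HALF_UP
        )
    )


def cohort_summary(timelines: Sequence[PatientTimeline]) -> dict:
    """Cohort-level counts and rates in the study's reporting vocabulary."""
    if not timelines:
        raise ValueError("cohort summary needs at least one timeline")
    n = len(timelines)
    with_baseline = [t for t in timelines if t.baseline_positive is not None]
    baseline_pos = [t for t in with_baseline if t.baseline_positive]

    baseline_mut_total = 0
    baseline_mut_detected = 0
    for t in timelines:
        baseline = [
            s
            for s in t.samples
            if s.collection_day <= 0 and s.sample_positive is not None
        ]
        if not baseline:
            continue
        for call in baseline[-1].mutation_calls:
            if call.evaluable:
                baseline_mut_total += 1
                baseline_mut_detected += bool(call.detected)

    with_clinical = [t for t in timelines if t.clinical_recurrence_day is not None]
    with_molecular = [t for t in timelines if t.molecular_recurrence_day is not None]
    led = [
        t
        for t in with_clinical
        if t.lead_time_days is not None and t.lead_time_days > 0
    ]
    lead_rows = [
        {
            "patient_id": t.patient_id,
            "molecular_recurrence_day": t.molecular_recurrence_day,
            "clinical_recurrence_day": t.clinical_recurrence_day,
            "lead_time_days": t.lead_time_days,
        }
        for t in timelines
        if t.lead_time_days is not None
    ]
    return {
        "n_patients": n,
        "baseline_evaluable_patients": len(with_baseline),
        "baseline_positive_patients": len(baseline_pos),
        "baseline_positive_pct": _pct(len(baseline_pos), len(with_baseline)),
        "baseline_mutations_evaluable": baseline_mut_total,
        "baseline_mutations_detected": baseline_mut_detected,
        "baseline_mutations_detected_pct": _pct(
            baseline_mut_detected, baseline_mut_total
        ),
        "clinical_recurrence_patients": len(with_clinical),
        "molecular_recurrence_patients": len(with_molecular),
        "molecular_preceded_clinical": len(led),
        "lead_times": lead_rows,
    }


def timelines_frame(timelines: Sequence[PatientTimeline]) -> pd.DataFrame:
    rows = []
    for t in timelines:
        rows.append(
            {
                "patient_id": t.patient_id,
                "n_samples": len(t.samples),
                "baseline_positive": t.baseline_positive,
                "clearance": t.clearance,
                "molecular_recurrence_day": t.molecular_recurrence_day,
                "clinical_recurrence_day": t.clinical_recurrence_day,
                "lead_time_days": t.lead_time_days,
            }
        )
    return pd.DataFrame(rows)
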