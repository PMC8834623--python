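"""Longitudinal clinical interpretation of ctDNA timelines.

Three clinical applications are covered:

* **Molecular residual disease (MRD)** — ctDNA present in plasma within a
  post-surgery window (default 4-50 days, the study's sampling span).
* **Recurrence detection** — the first ctDNA-positive sample after a period
  of negativity following curative treatment, with the lead time to the
  subsequent clinical recurrence when one exists.
* **Treatment response** — consecutive-sample VAF changes during
  chemotherapy classified as RESPONSE / RESISTANCE / STABLE / CLEARED; a
  change is significant when the measurement uncertainty intervals do not
  overlap or the fold-change exceeds a configurable minimum.

Marker concordance compares which of ctDNA, cfDNA concentration and CEA
level anticipated each clinical event.  The non-specific markers (cfDNA,
CEA) only count as predictive if, besides being elevated in the event
window, they show a qualitative change somewhere on the timeline: a marker
that is elevated at every single visit carries no event-specific signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .classify import CtdnaStatus, MarkerPanel, StatusCall

__all__ = [
    "EventKind",
    "ClinicalEvent",
    "TimepointSample",
    "PatientTimeline",
    "Direction",
    "TrajectoryCall",
    "MrdResult",
    "RecurrenceCall",
    "call_mrd",
    "detect_recurrence",
    "classify_trajectory",
    "marker_concordance",
]

MRD_WINDOW_DAYS = (4, 50)
RECURRENCE_LOOKBACK_DAYS = 90


class EventKind(str, Enum):
    SURGERY = "surgery"
    CHEMO_START = "chemo_start"
    CHEMO_END = "chemo_end"
    METASTASIS_CONFIRMED = "metastasis_confirmed"
    RECURRENCE_CLINICAL = "recurrence_clinical"
    REMISSION = "remission"
    PROGRESSION = "progression"


@dataclass(frozen=True)
class ClinicalEvent:
    day: int
    kind: EventKind


@dataclass(frozen=True)
class TimepointSample:
    day: int
    call: StatusCall
    panel: Optional[MarkerPanel] = None


@dataclass
class PatientTimeline:
    patient_id: str
    uicc_stage: str
    assay_id: str
    samples: list[TimepointSample] = field(default_factory=list)
    events: list[ClinicalEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = sorted(self.samples, key=lambda s: s.day)
        self.events = sorted(self.events, key=lambda e: e.day)
        days = [s.day for s in self.samples]
        if len(days) != len(set(days)):
            raise ValueError(f"{self.patient_id}: duplicate sample days")
        surgeries = [e for e in self.events if e.kind is EventKind.SURGERY]
        if len(surgeries) > 1:
            raise ValueError(f"{self.patient_id}: more than one surgery event")

    def event_days(self, kind: EventKind) -> list[int]:
        return [e.day for e in self.events if e.kind is kind]

    def surgery_day(self) -> Optional[int]:
        days = self.event_days(EventKind.SURGERY)
        return days[0] if days else None

    def samples_in(self, start: float, end: float) -> list[TimepointSample]:
        return [s for s in self.samples if start <= s.day <= end]


class Direction(str, Enum):
    RESPONSE = "RESPONSE"
    RESISTANCE = "RESISTANCE"
    STABLE = "STABLE"
    CLEARED = "CLEARED"
    NOT_EVALUABLE = "NOT_EVALUABLE"


@dataclass(frozen=True)
class TrajectoryCall:
    interval: tuple[int, int]
    direction: Direction
    vaf_from: float
    vaf_to: float


@dataclass(frozen=True)
class MrdResult:
    evaluable: bool
    mrd: Optional[bool]
    supporting_sample: Optional[TimepointSample] = None


@dataclass(frozen=True)
class RecurrenceCall:
    molecular_day: int
    vaf: float
    clinical_day: Optional[int]
    lead_time_days: Optional[int]
    confirmed: bool


def call_mrd(
    timeline: PatientTimeline,
    window_days: tuple[int, int] = MRD_WINDOW_DAYS,
) -> MrdResult:
    """Residual disease after surgery: any ctDNA-positive sample in window.

    Returns a NOT-EVALUABLE result (``evaluable=False, mrd=None``) when no
    surgery event or no post-operative plasma sample falls in the window.
    """
    surgery = timeline.surgery_day()
    if surgery is None:
        return MrdResult(evaluable=False, mrd=None)
    lo, hi = window_days
    window = timeline.samples_in(surgery + lo, surgery + hi)
    if not window:
        return MrdResult(evaluable=False, mrd=None)
    for s in window:
        if s.call.status.detected:
            return MrdResult(evaluable=True, mrd=True, supporting_sample=s)
    return MrdResult(evaluable=True, mrd=False)


def _curative_day(timeline: PatientTimeline) -> Optional[int]:
    surgery = timeline.surgery_day()
    if surgery is not None:
        return surgery
    ends = timeline.event_days(EventKind.CHEMO_END)
    return ends[0] if ends else None


def detect_recurrence(timeline: PatientTimeline) -> list[RecurrenceCall]:
    """Molecular recurrence calls after curative treatment.

    A call is the first ctDNA-positive sample after at least one negative
    sample following curative treatment; a further call requires a return to
    negativity first.  The lead time is the day difference to the next
    clinical recurrence event at or after the molecular call; calls without
    such an event are flagged unconfirmed.
    """
    start = _curative_day(timeline)
    if start is None:
        return []
    clinical = timeline.event_days(EventKind.RECURRENCE_CLINICAL)
    calls: list[RecurrenceCall] = []
    seen_negative = False
    used_events: set[int] = set()
    for s in timeline.samples:
        if s.day <= start:
            continue
        if s.call.status.detected:
            if seen_negative:
                following = [d for d in clinical if d >= s.day and d not in used_events]
                clin = following[0] if following else None
                if clin is not None:
                    used_events.add(clin)
                calls.append(
                    RecurrenceCall(
                        molecular_day=s.day,
                        vaf=s.call.vaf,
                        clinical_day=clin,
                        lead_time_days=None if clin is None else clin - s.day,
                        confirmed=clin is not None,
                    )
                )
                seen_negative = False
        else:
            seen_negative = True
    return calls


def _intervals_overlap(a: StatusCall, b: StatusCall) -> Optional[bool]:
    if a.ci_low is None or a.ci_high is None or b.ci_low is None or b.ci_high is None:
        return None
    return a.ci_low <= b.ci_high and b.ci_low <= a.ci_high


def _pair_direction(
    frm: TimepointSample, to: TimepointSample, min_fold: float
) -> Direction:
    a, b = frm.call, to.call
    lob, loq = a.cutoffs.lob, a.cutoffs.loq
    from_neg, to_neg = a.vaf <= lob, b.vaf <= lob
    if from_neg and to_neg:
        return Direction.STABLE
    if not from_neg and to_neg:
        return Direction.CLEARED
    # both in the sub-quantifiable band: direction cannot be judged
    if (lob < a.vaf <= loq) and (lob < b.vaf <= loq):
        return Direction.NOT_EVALUABLE
    overlap = _intervals_overlap(a, b)
    if overlap is not None:
        significant = not overlap
    else:
        hi, lo_ = max(a.vaf, b.vaf), min(a.vaf, b.vaf)
        significant = lo_ == 0.0 or hi / lo_ >= min_fold
    if not significant:
        return Direction.STABLE
    return Direction.RESPONSE if b.vaf < a.vaf else Direction.RESISTANCE


def classify_trajectory(
    timeline: PatientTimeline,
    interval: tuple[int, int] | None = None,
    min_fold: float = 2.0,
) -> list[TrajectoryCall]:
    """Directional calls for consecutive sample pairs during treatment.

    ``interval`` defaults to the first chemotherapy course (chemo_start to
    chemo_end, or the last sample).  The latest sample at or before the
    interval start is included as the starting point so the pre-treatment
    level anchors the first comparison.  Fewer than two usable samples give
    an empty list.
    """
    if interval is None:
        starts = timeline.event_days(EventKind.CHEMO_START)
        if not starts:
            return []
        ends = [d for d in timeline.event_days(EventKind.CHEMO_END) if d > starts[0]]
        interval = (
            starts[0],
            ends[0] if ends else (timeline.samples[-1].day if timeline.samples else starts[0]),
        )
    lo, hi = interval
    inside = timeline.samples_in(lo, hi)
    before = [s for s in timeline.samples if s.day < lo]
    series = ([before[-1]] if before else []) + inside
    if len(series) < 2:
        return []
    calls = []
    for frm, to in zip(series, series[1:]):
        calls.append(
            TrajectoryCall(
                interval=(frm.day, to.day),
                direction=_pair_direction(frm, to, min_fold),
                vaf_from=frm.call.vaf,
                vaf_to=to.call.vaf,
            )
        )
    return calls


def _marker_window_flag(
    timeline: PatientTimeline,
    attr: str,
    start: float,
    end: float,
) -> Optional[bool]:
    """Elevation verdict for cfDNA/CEA over [start, end].

    None when no assessable measurement exists in the window.  Elevation in
    the window only counts as predictive if the marker is not elevated at
    every assessable visit of the whole timeline (a flat-elevated marker
    shows no event-related change).
    """
    window_flags = [
        getattr(s.panel, attr)
        for s in timeline.samples_in(start, end)
        if s.panel is not None and getattr(s.panel, attr) is not None
    ]
    if not window_flags:
        return None
    if not any(window_flags):
        return False
    all_flags = [
        getattr(s.panel, attr)
        for s in timeline.samples
        if s.panel is not None and getattr(s.panel, attr) is not None
    ]
    if all(all_flags):
        return False  # uniformly elevated: no qualitative change to read
    return True


def marker_concordance(
    timeline: PatientTimeline,
    window_days: tuple[int, int] = MRD_WINDOW_DAYS,
    lookback_days: int = RECURRENCE_LOOKBACK_DAYS,
) -> pd.DataFrame:
    """Which markers anticipated each clinical event.

    One row per event (MRD assessment after surgery; each clinical
    recurrence) with columns ``ctdna``, ``cfdna``, ``cea`` holding True /
    False / None (not assessable).  Patients without events yield an empty
    frame.
    """
    rows = []
    surgery = timeline.surgery_day()
    if surgery is not None:
        mrd = call_mrd(timeline, window_days)
        if mrd.evaluable:
            lo, hi = window_days
            rows.append(
                {
                    "patient_id": timeline.patient_id,
                    "event": "mrd",
                    "event_day": surgery,
                    "ctdna": mrd.mrd,
                    "cfdna": _marker_window_flag(
                        timeline, "cfdna_elevated", surgery + lo, surgery + hi
                    ),
                    "cea": _marker_window_flag(
                        timeline, "cea_elevated", surgery + lo, surgery + hi
                    ),
                }
            )
    molecular = detect_recurrence(timeline)
    for day in timeline.event_days(EventKind.RECURRENCE_CLINICAL):
        start = day - lookback_days
        ct = any(
            c.molecular_day <= day and c.molecular_day >= start for c in molecular
        )
        rows.append(
            {
                "patient_id": timeline.patient_id,
                "event": "recurrence",
                "event_day": day,
                "ctdna": ct,
                "cfdna": _marker_window_flag(timeline, "cfdna_elevated", start, day),
                "cea": _marker_window_flag(timeline, "cea_elevated", start, day),
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "event", "event_day", "ctdna", "cfdna", "cea"])
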