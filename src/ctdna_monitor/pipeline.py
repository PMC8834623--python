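"""Stage drivers tying measurements to cohort-level clinical summaries.

These functions are the programmatic surface behind the command line:
assay validation (blanks -> LOB, positive replicates -> LOQ, healthy
controls -> verification), per-sample classification, and per-patient
monitoring reports with the cohort summary counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .classify import CtdnaStatus, baseline_marker_table
from .io import build_timelines, ensure_vaf
from .monitoring import (
    EventKind,
    PatientTimeline,
    call_mrd,
    classify_trajectory,
    detect_recurrence,
    marker_concordance,
)
from .validation import (
    AssayCutoffs,
    BlankSet,
    LoqReplicateSet,
    estimate_lob,
    estimate_loq,
    verify_cutoff,
)

logger = logging.getLogger("ctdna_monitor")

__all__ = [
    "validate_assay",
    "classify_samples",
    "baseline_frame",
    "mrd_calls",
    "prechemo_detection",
    "monitor_cohort",
]


def validate_assay(
    assay_id: str,
    blanks: Sequence[float],
    replicate_sets: Sequence[LoqReplicateSet],
    verification_values: Sequence[float],
    alpha: float = 0.05,
    max_exceed_fraction: float = 0.15,
    strict: bool = True,
) -> dict:
    """Run LOB estimation, LOQ search and clinical verification for one assay."""
    blank_set = BlankSet(values=tuple(blanks), alpha=alpha)
    lob = estimate_lob(blank_set, strict=strict)
    loq = estimate_loq(replicate_sets, lob=lob, strict=strict)
    verification = verify_cutoff(verification_values, lob, max_exceed_fraction)
    cutoffs = AssayCutoffs(assay_id, lob=lob, loq=loq, verified=verification.passed)
    logger.info(
        "%s: LOB=%.4f LOQ=%.4f verified=%s (exceedance %.0f%% of %d controls)",
        assay_id, lob, loq, verification.passed,
        100 * verification.exceed_fraction, verification.n_valid,
    )
    return {
        "assay_id": assay_id,
        "lob": lob,
        "loq": loq,
        "alpha": alpha,
        "n_b": blank_set.n_b,
        "verified": verification.passed,
        "exceed_fraction": verification.exceed_fraction,
        "n_exceed": verification.n_exceed,
        "n_controls": verification.n_valid,
        "cutoffs": cutoffs,
    }


def classify_samples(
    samples: pd.DataFrame,
    events: Optional[pd.DataFrame] = None,
    cutoffs: Optional[Mapping[str, AssayCutoffs]] = None,
) -> pd.DataFrame:
    """Per-sample call table: status, VAF and marker elevations."""
    timelines = build_timelines(samples, events, cutoffs)
    rows = []
    for tl in timelines.values():
        for s in tl.samples:
            p = s.panel
            rows.append(
                {
                    "sample_id": s.call.sample_id,
                    "patient_id": tl.patient_id,
                    "collection_day": s.day,
                    "assay_id": tl.assay_id,
                    "uicc_stage": tl.uicc_stage,
                    "vaf_pct": s.call.vaf,
                    "status": s.call.status.value,
                    "gdna_checked": s.call.gdna_checked,
                    "cfdna_elevated": None if p is None else p.cfdna_elevated,
                    "cea_elevated": None if p is None else p.cea_elevated,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "patient_id", "collection_day", "assay_id", "uicc_stage",
            "vaf_pct", "status", "gdna_checked", "cfdna_elevated", "cea_elevated",
        ],
    )
    logger.info("classified %d plasma samples from %d patients", len(out), len(timelines))
    return out


def baseline_frame(timelines: Mapping[str, PatientTimeline]) -> pd.DataFrame:
    """One row per patient with baseline marker flags.

    The baseline sample is the earliest plasma sample collected before the
    first treatment event (or the earliest sample overall when no treatment
    is recorded).
    """
    rows = []
    for pid, tl in timelines.items():
        if not tl.samples:
            continue
        treatment = [
            e.day for e in tl.events if e.kind in (EventKind.SURGERY, EventKind.CHEMO_START)
        ]
        pre = [s for s in tl.samples if not treatment or s.day < min(treatment)]
        base = pre[0] if pre else tl.samples[0]
        p = base.panel
        rows.append(
            {
                "patient_id": pid,
                "uicc_stage": tl.uicc_stage,
                "ctdna_detected": base.call.status.detected,
                "cfdna_elevated": None if p is None else p.cfdna_elevated,
                "cea_elevated": None if p is None else p.cea_elevated,
            }
        )
    return pd.DataFrame(rows)


def mrd_calls(
    timelines: Mapping[str, PatientTimeline],
    window_days: tuple[int, int] = (4, 50),
) -> pd.DataFrame:
    rows = []
    for pid, tl in timelines.items():
        res = call_mrd(tl, window_days)
        rows.append(
            {
                "patient_id": pid,
                "evaluable": res.evaluable,
                "mrd": res.mrd,
                "supporting_day": res.supporting_sample.day if res.supporting_sample else None,
            }
        )
    return pd.DataFrame(rows)


def prechemo_detection(timelines: Mapping[str, PatientTimeline]) -> pd.DataFrame:
    """ctDNA detection in the last sample at or before chemotherapy start."""
    rows = []
    for pid, tl in timelines.items():
        starts = tl.event_days(EventKind.CHEMO_START)
        if not starts:
            continue
        prior = [s for s in tl.samples if s.day <= starts[0]]
        detected = bool(prior) and prior[-1].call.status.detected
        rows.append(
            {
                "patient_id": pid,
                "chemo_start_day": starts[0],
                "detected": detected,
                "vaf_pct": prior[-1].call.vaf if prior else None,
            }
        )
    return pd.DataFrame(rows)


def monitor_cohort(
    samples: pd.DataFrame,
    events: pd.DataFrame,
    cutoffs: Optional[Mapping[str, AssayCutoffs]] = None,
    window_days: tuple[int, int] = (4, 50),
) -> dict:
    """Full monitoring report: per-patient calls plus cohort summary counts."""
    timelines = build_timelines(samples, events, cutoffs)
    per_patient = {}
    for pid, tl in timelines.items():
        mrd = call_mrd(tl, window_days)
        recurrences = detect_recurrence(tl)
        trajectory = classify_trajectory(tl)
        concordance = marker_concordance(tl, window_days)
        per_patient[pid] = {
            "uicc_stage": tl.uicc_stage,
            "assay_id": tl.assay_id,
            "mrd": {
                "evaluable": mrd.evaluable,
                "mrd": mrd.mrd,
                "supporting_day": mrd.supporting_sample.day if mrd.supporting_sample else None,
            },
            "recurrence_calls": [
                {
                    "molecular_day": c.molecular_day,
                    "vaf_pct": c.vaf,
                    "clinical_day": c.clinical_day,
                    "lead_time_days": c.lead_time_days,
                    "confirmed": c.confirmed,
                }
                for c in recurrences
            ],
            "trajectory": [
                {
                    "from_day": t.interval[0],
                    "to_day": t.interval[1],
                    "direction": t.direction.value,
                    "vaf_from": t.vaf_from,
                    "vaf_to": t.vaf_to,
                }
                for t in trajectory
            ],
            "marker_concordance": concordance.to_dict(orient="records"),
        }

    surgical = [tl for tl in timelines.values() if tl.surgery_day() is not None]
    mrd_results = [call_mrd(tl, window_days) for tl in surgical]
    n_mrd = sum(1 for r in mrd_results if r.mrd)
    n_recurrence = sum(
        1 for tl in surgical if tl.event_days(EventKind.RECURRENCE_CLINICAL)
    )
    prechemo = prechemo_detection(timelines)
    summary = {
        "n_patients": len(timelines),
        "n_surgery_patients": len(surgical),
        "mrd_positive": n_mrd,
        "clinical_recurrences": n_recurrence,
        "prechemo_patients": int(len(prechemo)),
        "prechemo_detected": int(prechemo["detected"].sum()) if len(prechemo) else 0,
    }
    logger.info("monitoring summary: %s", summary)
    return {"summary": summary, "patients": per_patient}
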