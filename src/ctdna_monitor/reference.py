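"""Deterministic reference cohort for end-to-end testing and worked examples.

Encodes an 18-patient primary-surgery roster plus the 4 primary-chemotherapy
patients monitored during treatment (9 chemotherapy-monitored patients in
total), with the per-stage marker detection pattern of the validation study:
baseline ctDNA positivity 9/18 (0/4 stage I, 4/8 II, 3/4 III, 2/2 IV),
elevated cfDNA 12/18 (2/4, 4/8, 4/4, 2/2), elevated CEA 2/18 (0, 0, 1, 1),
MRD 3/18 and pre-chemotherapy ctDNA detection 7/9.

VAF magnitudes reuse published values where the study prints them (e.g.
1.48 +/- 0.39, 1.72 +/- 0.45, 2.01 +/- 0.73, 0.82 +/- 0.30, 8.99 +/- 2.36,
47.75 +/- 7.11, 12.19 +/- 1.82, the 0.03% healthy control, the 0.14% gDNA
clonal-hematopoiesis check); everything else is a synthetic placement on the
documented side of the validated cutoffs, since no per-sample data are
deposited.  The fixture is pure code — regenerating it is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ReferenceCohort", "reference_cohort", "SURGERY_PATIENTS", "CHEMO_PATIENTS"]

BRAF = "BRAF_V600E"
KRAS = "KRAS_G12G13"

# pid -> (stage, assay, smoker)
_PATIENT_ATTRS: dict[str, tuple[str, str, bool]] = {
    # stage I
    "LB-CRC-01": ("I", BRAF, False),
    "LB-CRC-03": ("I", BRAF, False),
    "LB-CRC-04": ("I", KRAS, False),
    "LB-CRC-05": ("I", KRAS, False),
    # stage II
    "LB-CRC-07": ("II", BRAF, False),
    "LB-CRC-11": ("II", KRAS, False),
    "LB-CRC-12": ("II", KRAS, False),
    "LB-CRC-13": ("II", KRAS, False),
    "LB-CRC-14": ("II", BRAF, True),
    "LB-CRC-15": ("II", BRAF, False),
    "LB-CRC-16": ("II", BRAF, False),
    "LB-CRC-17": ("II", KRAS, False),
    # stage III
    "LB-CRC-18": ("III", KRAS, False),
    "LB-CRC-22": ("III", BRAF, False),
    "LB-CRC-25": ("III", KRAS, False),
    "LB-CRC-29": ("III", KRAS, False),
    # stage IV
    "LB-CRC-38": ("IV", BRAF, False),
    "LB-CRC-09": ("IV", KRAS, False),
    # primary chemotherapy (not part of the 18-surgery roster)
    "LB-CRC-02": ("IV", BRAF, False),
    "LB-CRC-30": ("IV", KRAS, False),
    "LB-CRC-32": ("IV", BRAF, False),
    "LB-CRC-43": ("IV", KRAS, False),
}

SURGERY_PATIENTS = tuple(
    p for p in _PATIENT_ATTRS if p not in ("LB-CRC-02", "LB-CRC-30", "LB-CRC-32", "LB-CRC-43")
)
CHEMO_PATIENTS = (
    "LB-CRC-02", "LB-CRC-30", "LB-CRC-32", "LB-CRC-43",
    "LB-CRC-38", "LB-CRC-25", "LB-CRC-07", "LB-CRC-18", "LB-CRC-29",
)

NAN = float("nan")

# pid -> list of (day, vaf, half_width, cfdna, cea)
_PLASMA: dict[str, list[tuple[int, float, float, float, float]]] = {
    # ---- stage I: ctDNA-negative throughout ----
    "LB-CRC-01": [(-3, 0.0, 0.01, 8.0, 1.0), (14, 0.0, 0.01, 5.0, 1.1), (100, 0.0, 0.01, 3.5, 0.9)],
    "LB-CRC-03": [(-3, 0.0, 0.01, 2.0, 0.8), (14, 0.0, 0.01, 2.2, 0.9), (100, 0.0, 0.01, 1.8, 0.7)],
    "LB-CRC-04": [(-3, 0.0, 0.01, 7.5, 1.2), (14, 0.0, 0.01, 4.8, 1.0), (100, 0.0, 0.01, 3.0, 1.1)],
    "LB-CRC-05": [(-3, 0.0, 0.01, 3.1, 1.5), (14, 0.0, 0.01, 2.9, 1.4), (100, 0.0, 0.01, 2.5, 1.2)],
    # ---- stage II ----
    # recurrence patient: negative at baseline, molecular call 90 days before
    # clinical recurrence, palliative chemotherapy 0.82% -> undetectable
    "LB-CRC-07": [
        (-3, 0.0, 0.01, 3.0, 1.0),
        (14, 0.0, 0.01, 3.5, 1.2),
        (100, 0.0, 0.01, 4.0, 1.1),
        (180, 0.0, 0.01, 3.2, 1.3),
        (270, 0.30, 0.10, 4.5, 1.5),
        (365, 0.82, 0.30, 5.0, 1.8),
        (400, 0.25, 0.10, 8.0, 1.6),
        (430, 0.0, 0.01, 7.5, 1.4),
        (460, 0.0, 0.01, 6.0, 1.2),
    ],
    # the clonal-hematopoiesis check case: plasma 1.48%, gDNA 0.14%
    "LB-CRC-11": [(-3, 1.48, 0.39, 12.0, 2.0), (14, 0.0, 0.01, 6.0, 1.8), (100, 0.0, 0.01, 4.0, 1.5)],
    "LB-CRC-12": [(-3, 0.95, 0.30, 9.0, 1.8), (14, 0.0, 0.01, 5.5, 1.6), (100, 0.0, 0.01, 3.8, 1.4)],
    "LB-CRC-13": [(-3, 0.62, 0.20, 8.2, 2.2), (14, 0.0, 0.01, 5.0, 2.0), (100, 0.0, 0.01, 3.5, 1.9)],
    "LB-CRC-14": [(-3, 0.0, 0.01, 2.8, 3.0), (14, 0.0, 0.01, 2.6, 2.8), (100, 0.0, 0.01, 2.4, 2.9)],
    "LB-CRC-15": [(-3, 0.0, 0.01, 4.0, 1.1), (14, 0.0, 0.01, 3.6, 1.0), (100, 0.0, 0.01, 3.0, 1.2)],
    "LB-CRC-16": [(-3, 0.30, 0.10, 10.5, 1.4), (14, 0.0, 0.01, 5.2, 1.3), (100, 0.0, 0.01, 4.1, 1.2)],
    "LB-CRC-17": [(-3, 0.0, 0.01, 1.9, 0.9), (14, 0.0, 0.01, 2.1, 0.8), (100, 0.0, 0.01, 1.7, 0.9)],
    # ---- stage III ----
    # adjuvant chemotherapy, no MRD, cfDNA normalizes within a year
    "LB-CRC-18": [
        (-3, 0.80, 0.25, 13.0, 1.6),
        (14, 0.0, 0.01, 8.0, 1.4),
        (60, 0.0, 0.01, 6.5, 1.2),
        (120, 0.0, 0.01, 5.0, 1.0),
        (240, 0.0, 0.01, 4.2, 1.1),
        (365, 0.0, 0.01, 3.0, 1.3),
    ],
    "LB-CRC-22": [(-3, 0.45, 0.15, 9.9, 2.0), (14, 0.0, 0.01, 5.4, 1.8), (100, 0.0, 0.01, 4.4, 1.7)],
    # MRD (2.01% -> undetectable under adjuvant chemo), late recurrence not
    # anticipated molecularly; cfDNA elevated at every single visit
    "LB-CRC-25": [
        (-3, 1.30, 0.35, 11.6, 4.0),
        (14, 2.01, 0.73, 12.0, 3.5),
        (60, 0.70, 0.25, 10.5, 2.9),
        (90, 0.0, 0.01, 11.0, 2.0),
        (180, 0.0, 0.01, 12.5, 1.5),
        (270, 0.0, 0.01, 10.8, 1.8),
        (330, 0.0, 0.01, 11.2, 2.0),
        (430, 0.60, 0.20, 13.0, 2.2),
    ],
    # adjuvant chemotherapy, never ctDNA-positive, oscillating cfDNA
    "LB-CRC-29": [
        (-3, 0.0, 0.01, 6.8, 2.4),
        (14, 0.0, 0.01, 4.0, 2.0),
        (60, 0.0, 0.01, 7.2, 1.8),
        (120, 0.0, 0.01, 3.9, 2.1),
        (240, 0.0, 0.01, 6.0, 1.9),
        (365, 0.0, 0.01, 7.5, 2.2),
    ],
    # ---- stage IV ----
    # MRD with confirmed metastasis; cfDNA predicts MRD, CEA stays normal
    "LB-CRC-38": [
        (-3, 2.50, 0.60, 15.0, 1.9),
        (14, 1.72, 0.45, 12.5, 1.8),
        (60, 0.65, 0.22, 8.0, 1.5),
        (90, 0.0, 0.01, 4.0, 1.2),
        (150, 0.0, 0.01, 4.5, 1.0),
    ],
    # MRD with confirmed metastasis; cfDNA not assessable 4-7 weeks
    # post-surgery, CEA elevated at baseline and two weeks after
    "LB-CRC-09": [
        (-3, 3.10, 0.80, 18.0, 6.5),
        (14, 0.90, 0.30, NAN, 5.8),
        (35, 1.10, 0.35, NAN, 5.0),
        (100, 1.50, 0.45, 9.0, 2.0),
    ],
    # ---- primary chemotherapy (chemo_start at day 0) ----
    "LB-CRC-02": [
        (-3, 47.75, 7.11, NAN, NAN),
        (28, 12.19, 1.82, NAN, NAN),
        (90, 2.00, 0.50, NAN, NAN),
        (150, 9.00, 1.50, NAN, NAN),
        (200, 30.00, 4.00, 20.0, 8.0),
    ],
    "LB-CRC-30": [
        (-3, 15.0, 2.5, 14.0, 6.0),
        (28, 3.0, 0.8, 10.0, 7.0),
        (60, 0.90, 0.30, 5.0, 6.5),
        (120, 6.0, 1.2, 12.0, 8.0),
    ],
    "LB-CRC-32": [
        (-3, 8.99, 2.36, 9.5, 4.2),
        (28, 2.5, 0.6, 11.0, 3.4),
        (60, 0.0, 0.01, 5.0, 2.8),
        (120, 0.0, 0.01, 10.0, 1.9),
    ],
    "LB-CRC-43": [
        (-3, 25.0, 4.0, 16.0, 2.0),
        (28, 6.0, 1.3, 12.0, 1.8),
        (90, 1.5, 0.4, 10.0, 2.2),
        (150, 0.0, 0.01, 9.0, 1.5),
    ],
}

# pid -> measured VAF in matched lymphocyte gDNA (patients checked for
# clonal hematopoiesis: everyone with a ctDNA-positive plasma sample)
_GDNA: dict[str, float] = {
    "LB-CRC-07": 0.0,
    "LB-CRC-11": 0.14,
    "LB-CRC-12": 0.0,
    "LB-CRC-13": 0.0,
    "LB-CRC-16": 0.0,
    "LB-CRC-18": 0.0,
    "LB-CRC-22": 0.0,
    "LB-CRC-25": 0.0,
    "LB-CRC-29": 0.0,
    "LB-CRC-38": 0.0,
    "LB-CRC-09": 0.0,
    "LB-CRC-02": 0.0,
    "LB-CRC-30": 0.0,
    "LB-CRC-32": 0.0,
    "LB-CRC-43": 0.0,
}

# pid -> list of (day, event_kind)
_EVENTS: dict[str, list[tuple[int, str]]] = {
    **{p: [(0, "surgery")] for p in SURGERY_PATIENTS},
    "LB-CRC-07": [
        (0, "surgery"),
        (360, "recurrence_clinical"),
        (370, "chemo_start"),
        (450, "remission"),
        (480, "chemo_end"),
    ],
    "LB-CRC-25": [
        (0, "surgery"),
        (30, "chemo_start"),
        (240, "chemo_end"),
        (420, "recurrence_clinical"),
    ],
    "LB-CRC-18": [(0, "surgery"), (30, "chemo_start"), (180, "chemo_end")],
    "LB-CRC-29": [(0, "surgery"), (30, "chemo_start"), (180, "chemo_end")],
    "LB-CRC-38": [
        (0, "surgery"),
        (7, "metastasis_confirmed"),
        (30, "chemo_start"),
        (150, "chemo_end"),
    ],
    "LB-CRC-09": [(0, "surgery"), (10, "metastasis_confirmed")],
    "LB-CRC-02": [(0, "chemo_start"), (160, "progression")],
    "LB-CRC-30": [(0, "chemo_start"), (125, "progression")],
    "LB-CRC-32": [(0, "chemo_start"), (130, "remission")],
    "LB-CRC-43": [(0, "chemo_start"), (155, "remission")],
}

#: healthy-control verification measurements (VAF %); NaN = failed analysis
VERIFICATION_CONTROLS: dict[str, list[float]] = {
    BRAF: [0.0] * 9 + [0.03],
    KRAS: [0.0] * 8 + [NAN, NAN],
}


@dataclass(frozen=True)
class ReferenceCohort:
    samples: pd.DataFrame
    events: pd.DataFrame
    verification_controls: dict[str, list[float]]


def reference_cohort() -> ReferenceCohort:
    """Build the reference sample sheet and event table (deterministic)."""
    rows = []
    for pid, visits in _PLASMA.items():
        stage, assay, smoker = _PATIENT_ATTRS[pid]
        for day, vaf, hw, cfdna, cea in visits:
            rows.append(
                {
                    "sample_id": f"{pid}-d{day}",
                    "patient_id": pid,
                    "collection_day": day,
                    "specimen": "plasma",
                    "assay_id": assay,
                    "vaf_pct": vaf,
                    "vaf_ci_low": max(vaf - hw, 0.0),
                    "vaf_ci_high": vaf + hw,
                    "cfdna_ng_ml": cfdna,
                    "cea_ng_ml": cea,
                    "smoker": smoker,
                    "uicc_stage": stage,
                }
            )
        if pid in _GDNA:
            gv = _GDNA[pid]
            rows.append(
                {
                    "sample_id": f"{pid}-gdna",
                    "patient_id": pid,
                    "collection_day": -3,
                    "specimen": "gdna",
                    "assay_id": assay,
                    "vaf_pct": gv,
                    "vaf_ci_low": max(gv - 0.05, 0.0),
                    "vaf_ci_high": gv + 0.05,
                    "cfdna_ng_ml": NAN,
                    "cea_ng_ml": NAN,
                    "smoker": smoker,
                    "uicc_stage": stage,
                }
            )
    events = [
        {"patient_id": pid, "day": day, "event_kind": kind}
        for pid, evs in _EVENTS.items()
        for day, kind in evs
    ]
    return ReferenceCohort(
        samples=pd.DataFrame(rows),
        events=pd.DataFrame(events, columns=["patient_id", "day", "event_kind"]),
        verification_controls={k: list(v) for k, v in VERIFICATION_CONTROLS.items()},
    )
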