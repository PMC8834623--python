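"""CSV dialects and construction of patient timelines from sample sheets.

Three tabular inputs are supported (RFC 4180 CSV, UTF-8, header required):

* droplet sheet — one well per row: ``sample_id, assay_id, k_mut, k_wt,
  n_total, v_droplet_nl, input_mass_ng``
* sample sheet — one measurement per row: ``sample_id, patient_id,
  collection_day, specimen (plasma|gdna), assay_id, vaf_pct`` plus optional
  ``vaf_ci_low, vaf_ci_high, cfdna_ng_ml, cea_ng_ml, smoker, uicc_stage``.
  A sheet carrying droplet columns instead of ``vaf_pct`` is quantified on
  the fly and yields identical downstream calls.
* events — ``patient_id, day, event_kind`` with the controlled vocabulary
  of :class:`~ctdna_monitor.monitoring.EventKind`.
"""

from __future__ import annotations

import math
from collections import defaultdict
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .classify import apply_ch_filter, classify_ctdna_status, make_marker_panel
from .ddpcr import DEFAULT_DROPLET_VOLUME_NL, DropletWell, quantify_sample
from .monitoring import ClinicalEvent, EventKind, PatientTimeline, TimepointSample
from .validation import PUBLISHED_CUTOFFS, AssayCutoffs, CFDNA_CUTOFF_NG_ML

__all__ = [
    "read_droplet_csv",
    "quantify_droplet_frame",
    "read_sample_sheet",
    "read_events",
    "write_events",
    "write_sample_sheet",
    "ensure_vaf",
    "build_timelines",
    "MalformedInputError",
]

DROPLET_COLUMNS = ["sample_id", "assay_id", "k_mut", "k_wt", "n_total"]
SAMPLE_COLUMNS = ["sample_id", "patient_id", "collection_day", "specimen", "assay_id"]
EVENT_COLUMNS = ["patient_id", "day", "event_kind"]


class MalformedInputError(ValueError):
    pass


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{what} is missing required column(s): {missing}")


def read_droplet_csv(path: str | Path, default_v_droplet: float = DEFAULT_DROPLET_VOLUME_NL) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, DROPLET_COLUMNS, f"droplet sheet {path}")
    if "v_droplet_nl" not in df.columns:
        df["v_droplet_nl"] = default_v_droplet
    df["v_droplet_nl"] = df["v_droplet_nl"].fillna(default_v_droplet)
    if "input_mass_ng" not in df.columns:
        df["input_mass_ng"] = 25.0
    return df


def quantify_droplet_frame(droplets: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate wells per sample into quantified VAF rows."""
    _require(droplets, DROPLET_COLUMNS, "droplet frame")
    out = []
    for (sample_id, assay_id), grp in droplets.groupby(["sample_id", "assay_id"], sort=False):
        wells = [
            DropletWell(
                assay_id=assay_id,
                k_mut=int(r.k_mut),
                k_wt=int(r.k_wt),
                n_total=int(r.n_total),
                v_droplet=float(r.v_droplet_nl),
                input_mass=float(r.input_mass_ng),
            )
            for r in grp.itertuples()
        ]
        m = quantify_sample(wells)
        out.append(
            {
                "sample_id": sample_id,
                "assay_id": assay_id,
                "vaf_pct": m.vaf,
                "vaf_ci_low": m.ci_low,
                "vaf_ci_high": m.ci_high,
                "input_mass_ng": m.input_mass,
                "in_validated_range": m.in_validated_range,
            }
        )
    return pd.DataFrame(out)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, SAMPLE_COLUMNS, f"sample sheet {path}")
    return ensure_vaf(df)


def ensure_vaf(samples: pd.DataFrame) -> pd.DataFrame:
    """Guarantee a ``vaf_pct`` column, quantifying droplet columns if needed."""
    df = samples.copy()
    if "vaf_pct" not in df.columns or df["vaf_pct"].isna().all():
        _require(df, ["k_mut", "k_wt", "n_total"], "sample sheet without vaf_pct")
        if "v_droplet_nl" not in df.columns:
            df["v_droplet_nl"] = DEFAULT_DROPLET_VOLUME_NL
        if "input_mass_ng" not in df.columns:
            df["input_mass_ng"] = 25.0
        quant = quantify_droplet_frame(df)
        df = df.drop(columns=["vaf_pct", "vaf_ci_low", "vaf_ci_high"], errors="ignore")
        df = df.merge(quant[["sample_id", "assay_id", "vaf_pct", "vaf_ci_low", "vaf_ci_high"]],
                      on=["sample_id", "assay_id"], how="left")
    for col, default in (
        ("vaf_ci_low", None),
        ("vaf_ci_high", None),
        ("cfdna_ng_ml", float("nan")),
        ("cea_ng_ml", float("nan")),
        ("smoker", False),
        ("uicc_stage", ""),
    ):
        if col not in df.columns:
            df[col] = default
    return df


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, EVENT_COLUMNS, f"events file {path}")
    bad = set(df["event_kind"]) - {e.value for e in EventKind}
    if bad:
        raise MalformedInputError(f"unknown event kind(s) in {path}: {sorted(bad)}")
    return df


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def build_timelines(
    samples: pd.DataFrame,
    events: Optional[pd.DataFrame] = None,
    cutoffs: Optional[Mapping[str, AssayCutoffs]] = None,
    cfdna_cutoff: float = CFDNA_CUTOFF_NG_ML,
) -> dict[str, PatientTimeline]:
    """Assemble per-patient timelines with classified sample calls.

    Plasma rows become status calls against the per-assay cutoffs, filtered
    against the patient's matched gDNA measurement (the maximum gDNA VAF on
    the same assay; missing gDNA leaves calls unchecked).
    """
    cutoffs = dict(cutoffs or PUBLISHED_CUTOFFS)
    samples = ensure_vaf(samples)
    events = events if events is not None else pd.DataFrame(columns=EVENT_COLUMNS)

    gdna_by_patient: dict[str, float] = (
        samples[samples["specimen"] == "gdna"].groupby("patient_id")["vaf_pct"].max().to_dict()
    )
    timelines: dict[str, PatientTimeline] = {}
    for pid, grp in samples[samples["specimen"] == "plasma"].groupby("patient_id", sort=False):
        grp = grp.sort_values("collection_day")
        assay = grp["assay_id"].iloc[0]
        if assay not in cutoffs:
            raise MalformedInputError(f"no cutoffs known for assay {assay!r}")
        tps = []
        for r in grp.itertuples():
            ci = None
            if r.vaf_ci_low is not None and not (
                isinstance(r.vaf_ci_low, float) and math.isnan(r.vaf_ci_low)
            ):
                ci = (float(r.vaf_ci_low), float(r.vaf_ci_high))
            call = classify_ctdna_status(
                float(r.vaf_pct), cutoffs[assay], sample_id=str(r.sample_id), ci=ci
            )
            call = apply_ch_filter(call, gdna_by_patient.get(pid), cutoffs[assay])
            panel = make_marker_panel(
                ctdna=call,
                cfdna_conc=float(r.cfdna_ng_ml),
                cea=float(r.cea_ng_ml),
                smoker=bool(r.smoker),
                cfdna_cutoff=cfdna_cutoff,
            )
            tps.append(TimepointSample(day=int(r.collection_day), call=call, panel=panel))
        ev = [
            ClinicalEvent(day=int(e.day), kind=EventKind(e.event_kind))
            for e in events[events["patient_id"] == pid].itertuples()
        ]
        timelines[pid] = PatientTimeline(
            patient_id=pid,
            uicc_stage=str(grp["uicc_stage"].iloc[0]),
            assay_id=assay,
            samples=tps,
            events=ev,
        )
    return timelines
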