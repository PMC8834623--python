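"""Per-sample clinical marker calls.

A plasma sample's ctDNA status follows from its VAF and the validated
assay cutoffs: NEGATIVE at or below the LOB, POSITIVE above the LOB, and
QUANTIFIABLE above the LOQ (all comparisons strict).  A positive plasma
call is tumor-specific only if matched lymphocyte genomic DNA does not
explain the signal; otherwise clonal hematopoiesis is suspected.

cfDNA concentration is "elevated" above the 5.6 ng/mL cutoff; CEA above
2.5 ng/mL in non-smokers and 5 ng/mL in smokers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .validation import AssayCutoffs, CFDNA_CUTOFF_NG_ML

__all__ = [
    "CtdnaStatus",
    "StatusCall",
    "MarkerPanel",
    "classify_ctdna_status",
    "apply_ch_filter",
    "classify_cea",
    "classify_cfdna",
    "make_marker_panel",
    "baseline_marker_table",
    "CEA_CUTOFF_NONSMOKER",
    "CEA_CUTOFF_SMOKER",
]

CEA_CUTOFF_NONSMOKER = 2.5
CEA_CUTOFF_SMOKER = 5.0

UICC_STAGES = ("I", "II", "III", "IV")


class CtdnaStatus(str, Enum):
    NEGATIVE = "NEGATIVE"
    POSITIVE = "POSITIVE"
    QUANTIFIABLE = "QUANTIFIABLE"
    CH_SUSPECTED = "CH_SUSPECTED"

    @property
    def detected(self) -> bool:
        """Tumor-specific ctDNA presence (CH-suspected does not count)."""
        return self in (CtdnaStatus.POSITIVE, CtdnaStatus.QUANTIFIABLE)


@dataclass(frozen=True)
class StatusCall:
    sample_id: str
    status: CtdnaStatus
    vaf: float
    cutoffs: AssayCutoffs
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    gdna_checked: bool = False

    def __post_init__(self) -> None:
        lob, loq = self.cutoffs.lob, self.cutoffs.loq
        if self.status is CtdnaStatus.QUANTIFIABLE and not self.vaf > loq:
            raise ValueError("QUANTIFIABLE requires vaf > loq")
        if self.status is CtdnaStatus.POSITIVE and not (lob < self.vaf <= loq):
            raise ValueError("POSITIVE requires lob < vaf <= loq")
        if self.status is CtdnaStatus.NEGATIVE and self.vaf > lob:
            raise ValueError("NEGATIVE requires vaf <= lob")


def classify_ctdna_status(
    vaf: float,
    cutoffs: AssayCutoffs,
    sample_id: str = "",
    ci: tuple[float, float] | None = None,
) -> StatusCall:
    """Call ctDNA status from a VAF percentage against validated cutoffs."""
    if vaf < 0:
        raise ValueError(f"vaf must be nonnegative, got {vaf}")
    if not cutoffs.verified:
        warnings.warn(
            f"cutoffs for {cutoffs.assay_id} are not clinically verified",
            stacklevel=2,
        )
    if vaf > cutoffs.loq:
        status = CtdnaStatus.QUANTIFIABLE
    elif vaf > cutoffs.lob:
        status = CtdnaStatus.POSITIVE
    else:
        status = CtdnaStatus.NEGATIVE
    lo, hi = ci if ci is not None else (None, None)
    return StatusCall(sample_id, status, vaf, cutoffs, ci_low=lo, ci_high=hi)


def apply_ch_filter(
    plasma: StatusCall,
    gdna_vaf: float | None,
    cutoffs: AssayCutoffs | None = None,
) -> StatusCall:
    """Check a plasma call against matched lymphocyte gDNA.

    * gDNA below/at the LOB (or negative plasma): call unchanged.
    * gDNA above the LOB but plasma VAF higher: the plasma signal exceeds
      what blood cells explain — still tumor-specific, call unchanged.
    * gDNA above the LOB and plasma VAF not higher: clonal hematopoiesis
      suspected; the sample is excluded from tumor-positive counts.

    A missing gDNA measurement returns the call with ``gdna_checked=False``.
    """
    cutoffs = cutoffs or plasma.cutoffs
    if gdna_vaf is None or (isinstance(gdna_vaf, float) and math.isnan(gdna_vaf)):
        return replace(plasma, gdna_checked=False)
    if gdna_vaf < 0:
        raise ValueError("gdna_vaf must be nonnegative")
    if not plasma.status.detected or gdna_vaf <= cutoffs.lob or plasma.vaf > gdna_vaf:
        return replace(plasma, gdna_checked=True)
    return replace(plasma, status=CtdnaStatus.CH_SUSPECTED, gdna_checked=True)


def classify_cea(
    cea: float,
    smoker: bool = False,
    nonsmoker_cutoff: float = CEA_CUTOFF_NONSMOKER,
    smoker_cutoff: float = CEA_CUTOFF_SMOKER,
) -> bool:
    """CEA elevation under the smoker-dependent threshold (strict >)."""
    if cea < 0:
        raise ValueError("CEA must be nonnegative")
    return cea > (smoker_cutoff if smoker else nonsmoker_cutoff)


def classify_cfdna(conc: float, cutoff: float = CFDNA_CUTOFF_NG_ML) -> bool:
    """cfDNA concentration elevation against the healthy-donor cutoff."""
    if conc < 0:
        raise ValueError("concentration must be nonnegative")
    return conc > cutoff


@dataclass(frozen=True)
class MarkerPanel:
    """The three baseline/monitoring markers of one sample."""

    ctdna: Optional[StatusCall]
    cfdna_conc: float
    cfdna_elevated: Optional[bool]
    cea: float
    cea_elevated: Optional[bool]
    smoker: bool = False


def make_marker_panel(
    ctdna: Optional[StatusCall],
    cfdna_conc: float,
    cea: float,
    smoker: bool = False,
    cfdna_cutoff: float = CFDNA_CUTOFF_NG_ML,
) -> MarkerPanel:
    """Assemble a panel; NaN concentrations yield not-assessable flags."""
    cf_missing = cfdna_conc is None or math.isnan(cfdna_conc)
    cea_missing = cea is None or math.isnan(cea)
    return MarkerPanel(
        ctdna=ctdna,
        cfdna_conc=float("nan") if cf_missing else cfdna_conc,
        cfdna_elevated=None if cf_missing else classify_cfdna(cfdna_conc, cfdna_cutoff),
        cea=float("nan") if cea_missing else cea,
        cea_elevated=None if cea_missing else classify_cea(cea, smoker),
        smoker=smoker,
    )


def baseline_marker_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-stage detection counts for each marker at baseline.

    ``cohort`` holds one row per patient with columns ``patient_id``,
    ``uicc_stage`` and boolean (nullable) columns ``ctdna_detected``,
    ``cfdna_elevated``, ``cea_elevated``.  Returns a table indexed by UICC
    stage plus a TOTAL row, with ``<marker>_detected`` / ``<marker>_total``
    counts and the union-marker column.
    """
    required = {"patient_id", "uicc_stage", "ctdna_detected", "cfdna_elevated", "cea_elevated"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing columns: {sorted(missing)}")
    if cohort["patient_id"].duplicated().any():
        dupes = cohort.loc[cohort["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patients in baseline cohort: {dupes}")

    markers = ("ctdna", "cfdna", "cea")
    flag_cols = {"ctdna": "ctdna_detected", "cfdna": "cfdna_elevated", "cea": "cea_elevated"}
    df = cohort.copy()
    any_flag = df[list(flag_cols.values())].fillna(False).astype(bool).any(axis=1)
    df["any_marker"] = any_flag

    rows = []
    stages = [s for s in UICC_STAGES if s in set(df["uicc_stage"])]
    for stage in stages + ["TOTAL"]:
        sub = df if stage == "TOTAL" else df[df["uicc_stage"] == stage]
        row: dict[str, object] = {"stage": stage, "n_patients": len(sub)}
        for m in markers:
            flags = sub[flag_cols[m]]
            row[f"{m}_detected"] = int(flags.fillna(False).astype(bool).sum())
            row[f"{m}_total"] = int(flags.notna().sum())
        row["any_marker_detected"] = int(sub["any_marker"].sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("stage")
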