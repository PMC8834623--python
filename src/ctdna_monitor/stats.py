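"""Cohort-level nonparametric statistics.

Two-group comparisons use the Wilcoxon rank-sum (Mann-Whitney) test, exact
for small tie-free samples and normal-approximated with tie correction
otherwise.  Three or more groups use the Kruskal-Wallis H test with
chi-square reference, followed by pairwise rank-sum tests under Bonferroni
correction.  Phase comparisons contrast each marker (ctDNA VAF, cfDNA
concentration, CEA level) across baseline, course-of-disease and follow-up
samples; undetectable ctDNA enters with its measured VAF (usually 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .monitoring import EventKind, PatientTimeline

__all__ = [
    "TestResult",
    "MultiGroupResult",
    "two_group_test",
    "multi_group_test",
    "bonferroni",
    "assign_phases",
    "phase_comparison",
    "PHASES",
]

PHASES = ("baseline", "course_of_disease", "followup_after_curative")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    n: tuple[int, ...]


@dataclass(frozen=True)
class MultiGroupResult:
    statistic: float  # Kruskal-Wallis H
    p: float
    n: tuple[int, ...]
    pairwise: dict[tuple[int, int], float]  # Bonferroni-adjusted p per group pair


def bonferroni(p_raw: float, m: int) -> float:
    """Adjusted p = min(1, m * p_raw)."""
    if not 0 <= p_raw <= 1 or m < 1:
        raise ValueError("need 0 <= p <= 1 and m >= 1")
    return min(1.0, m * p_raw)


def _all_identical(*groups: Sequence[float]) -> bool:
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    return pooled.size > 0 and np.all(pooled == pooled[0])


def two_group_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    The statistic is reported in rank-sum form (W = sum of ranks of the
    first sample).  Identical pooled values give p = 1 by convention.
    """
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if _all_identical(x, y):
        w = x.size * (x.size + y.size + 1) / 2.0  # mean rank sum
        return TestResult(statistic=w, p=1.0, n=(x.size, y.size))
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank sum
    return TestResult(statistic=w, p=float(res.pvalue), n=(x.size, y.size))


def multi_group_test(groups: Sequence[Sequence[float]]) -> MultiGroupResult:
    """Kruskal-Wallis with Bonferroni-adjusted pairwise rank-sum follow-up.

    Intended for >= 3 groups; two groups are accepted (the H test then
    agrees asymptotically with the rank-sum test).
    """
    gs = [np.asarray(list(g), dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("every group must be nonempty")
    if _all_identical(*gs):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*gs)
    m = len(gs) * (len(gs) - 1) // 2
    pairwise = {
        (i, j): bonferroni(two_group_test(gs[i], gs[j]).p, m)
        for i, j in combinations(range(len(gs)), 2)
    }
    return MultiGroupResult(
        statistic=float(h), p=float(p), n=tuple(g.size for g in gs), pairwise=pairwise
    )


_TUMOR_EVIDENT = {
    EventKind.METASTASIS_CONFIRMED,
    EventKind.RECURRENCE_CLINICAL,
    EventKind.PROGRESSION,
}
_TUMOR_CLEARED = {EventKind.SURGERY, EventKind.REMISSION}
_TREATMENT = {EventKind.SURGERY, EventKind.CHEMO_START}


def assign_phases(timelines: Sequence[PatientTimeline]) -> pd.DataFrame:
    """Label every plasma sample with its disease phase.

    Samples before the first treatment event are ``baseline``.  Afterwards a
    tumor-evident state machine walks the events: surgery (R0 resection) and
    remission clear the tumor, while metastasis, clinical recurrence and
    progression make it evident again.  Samples in an evident state are
    ``course_of_disease``, otherwise ``followup_after_curative``.
    """
    rows = []
    for tl in timelines:
        treatment_days = [e.day for e in tl.events if e.kind in _TREATMENT]
        first_treatment = min(treatment_days) if treatment_days else None
        for s in tl.samples:
            if first_treatment is None or s.day < first_treatment:
                phase = "baseline"
            else:
                evident = True  # disease present at enrollment
                for e in tl.events:
                    if e.day > s.day:
                        break
                    if e.kind in _TUMOR_CLEARED:
                        evident = False
                    elif e.kind in _TUMOR_EVIDENT:
                        evident = True
                phase = "course_of_disease" if evident else "followup_after_curative"
            panel = s.panel
            rows.append(
                {
                    "patient_id": tl.patient_id,
                    "day": s.day,
                    "phase": phase,
                    "vaf": s.call.vaf,
                    "cfdna": panel.cfdna_conc if panel is not None else float("nan"),
                    "cea": panel.cea if panel is not None else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "day", "phase", "vaf", "cfdna", "cea"])


def phase_comparison(
    phase_samples: pd.DataFrame,
    markers: Sequence[str] = ("vaf", "cfdna", "cea"),
    patient_median: bool = False,
) -> dict[str, MultiGroupResult]:
    """Kruskal-Wallis per marker across the three disease phases.

    ``patient_median=True`` collapses repeated measures to one median per
    patient and phase before testing; the default treats samples as
    independent, matching the study's sample counts.
    """
    df = phase_samples
    present = [p for p in PHASES if p in set(df["phase"])]
    if len(present) < 3:
        raise ValueError(f"all three phases must be populated, have {present}")
    results = {}
    for marker in markers:
        sub = df[["patient_id", "phase", marker]].dropna(subset=[marker])
        if patient_median:
            sub = (
                sub.groupby(["patient_id", "phase"], as_index=False)[marker].median()
            )
        groups = [sub.loc[sub["phase"] == p, marker].to_numpy() for p in PHASES]
        results[marker] = multi_group_test(groups)
    return results
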