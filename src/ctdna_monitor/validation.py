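"""Detection and quantification cutoffs for liquid-biopsy assays.

The limit of blank (LOB) is the nonparametric (1-alpha) percentile of blank
measurements, estimated CLSI-style from the rank position

    p = (1 - alpha) * N_B + 0.5

on the ascending sorted blanks, with linear interpolation between adjacent
ranks.  With alpha = 0.05 the cutoff has nominal 95% specificity.  The same
machinery yields the cfDNA concentration cutoff from healthy-donor plasma.

The limit of quantification (LOQ) is the lowest positive-control level whose
replicate measurements achieve the required precision (100 - CV%, default
>= 80) and trueness (100 - |relative bias|%, default >= 90).

A cutoff established on reference material is clinically *verified* on
independent healthy controls: at most 15% of them may exceed it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BlankSet",
    "LoqReplicateSet",
    "AssayCutoffs",
    "VerificationResult",
    "InsufficientBlanksError",
    "InsufficientReplicatesError",
    "NoQualifyingLevelError",
    "estimate_lob",
    "estimate_concentration_cutoff",
    "precision_pct",
    "trueness_pct",
    "estimate_loq",
    "verify_cutoff",
    "PUBLISHED_CUTOFFS",
    "CFDNA_CUTOFF_NG_ML",
]

#: minimum blanks for a valid nonparametric cutoff claim
MIN_BLANKS = 60
#: minimum replicates per candidate level for a valid LOQ claim
MIN_LOQ_REPLICATES = 40


class InsufficientBlanksError(ValueError):
    pass


class InsufficientReplicatesError(ValueError):
    pass


class NoQualifyingLevelError(ValueError):
    pass


@dataclass(frozen=True)
class BlankSet:
    """Blank (analyte-free) measurements used to establish a cutoff.

    ``values`` are VAF percentages for ctDNA assays or ng/mL for the cfDNA
    concentration cutoff.
    """

    values: tuple[float, ...]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if any(v < 0 for v in self.values):
            raise ValueError("blank measurements must be nonnegative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def n_b(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class LoqReplicateSet:
    """Replicate measurements of a positive control at one known VAF level."""

    candidate_level: float
    measurements: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "measurements", tuple(float(v) for v in self.measurements)
        )
        if self.candidate_level <= 0:
            raise ValueError("candidate_level must be positive")


@dataclass
class AssayCutoffs:
    """Validated per-assay cutoffs, in VAF %."""

    assay_id: str
    lob: float
    loq: float
    input_mass_range: tuple[float, float] = (20.0, 30.0)
    verified: bool = False

    def __post_init__(self) -> None:
        if self.lob < 0 or self.loq < self.lob:
            raise ValueError(
                f"require 0 <= lob <= loq, got lob={self.lob}, loq={self.loq}"
            )


@dataclass(frozen=True)
class VerificationResult:
    passed: bool
    exceed_fraction: float
    n_exceed: int
    n_valid: int


#: cutoffs validated for the two colorectal-cancer assays (VAF %)
PUBLISHED_CUTOFFS: dict[str, AssayCutoffs] = {
    "BRAF_V600E": AssayCutoffs("BRAF_V600E", lob=0.02, loq=0.52, verified=True),
    "KRAS_G12G13": AssayCutoffs("KRAS_G12G13", lob=0.11, loq=0.41, verified=True),
}

#: plasma cfDNA concentration cutoff, ng/mL, at 95% specificity
CFDNA_CUTOFF_NG_ML = 5.6


def _as_values(blanks: "BlankSet | Sequence[float]") -> tuple[np.ndarray, float]:
    if isinstance(blanks, BlankSet):
        return np.asarray(blanks.values, dtype=float), blanks.alpha
    return np.asarray(list(blanks), dtype=float), 0.05


def estimate_lob(
    blanks: "BlankSet | Sequence[float]",
    alpha: float | None = None,
    min_n: int = MIN_BLANKS,
    strict: bool = True,
) -> float:
    """Nonparametric cutoff at the (1-alpha) percentile of blank values.

    Sorts ascending, evaluates the 1-based rank position
    ``p = (1-alpha)*n + 0.5`` and linearly interpolates between the bracketing
    ranks.  With fewer than ``min_n`` blanks the estimate is not a valid
    cutoff claim: raises by default, warns with ``strict=False``.
    """
    values, set_alpha = _as_values(blanks)
    a = set_alpha if alpha is None else alpha
    n = values.size
    if n == 0:
        raise InsufficientBlanksError("no blank measurements")
    if n < min_n:
        msg = f"{n} blanks < required {min_n} for a valid cutoff claim"
        if strict:
            raise InsufficientBlanksError(msg)
        warnings.warn(msg, stacklevel=2)
    p = (1.0 - a) * n + 0.5
    if p > n:
        raise ValueError(
            f"rank position {p:.2f} exceeds sample size {n}; need more blanks"
        )
    ordered = np.sort(values)
    if p < 1.0:
        return float(ordered[0])
    lo = math.floor(p)
    frac = p - lo
    if frac == 0.0 or lo == n:
        return float(ordered[lo - 1])
    return float(ordered[lo - 1] + frac * (ordered[lo] - ordered[lo - 1]))


def estimate_concentration_cutoff(
    healthy: "BlankSet | Sequence[float]",
    alpha: float | None = None,
    min_n: int = MIN_BLANKS,
    strict: bool = True,
) -> float:
    """cfDNA concentration cutoff (ng/mL) from healthy donors.

    Identical percentile machinery to :func:`estimate_lob`; healthy-donor
    concentrations play the role of the blanks.
    """
    return estimate_lob(healthy, alpha=alpha, min_n=min_n, strict=strict)


def precision_pct(measurements: Sequence[float]) -> float:
    """100 minus the coefficient of variation, in percent."""
    x = np.asarray(list(measurements), dtype=float)
    if x.size < 2:
        raise ValueError("precision needs at least two replicates")
    mean = x.mean()
    if mean == 0:
        return -math.inf
    cv = x.std(ddof=1) / mean
    return 100.0 * (1.0 - cv)


def trueness_pct(measurements: Sequence[float], level: float) -> float:
    """100 minus the absolute relative bias to the known level, in percent."""
    if level <= 0:
        raise ValueError("level must be positive")
    x = np.asarray(list(measurements), dtype=float)
    if x.size == 0:
        raise ValueError("no measurements")
    return 100.0 * (1.0 - abs(x.mean() - level) / level)


def estimate_loq(
    replicate_sets: Sequence[LoqReplicateSet],
    precision_min: float = 80.0,
    trueness_min: float = 90.0,
    lob: float = 0.0,
    min_replicates: int = MIN_LOQ_REPLICATES,
    strict: bool = True,
) -> float:
    """Lowest candidate level meeting the precision and trueness criteria.

    The returned LOQ is additionally required to be >= ``lob`` so the
    quantification cutoff can never undercut the detection cutoff.
    """
    if not replicate_sets:
        raise ValueError("no replicate sets supplied")
    levels = [rs.candidate_level for rs in replicate_sets]
    if len(set(levels)) != len(levels):
        raise ValueError("candidate levels must be distinct")
    for rs in replicate_sets:
        if len(rs.measurements) < min_replicates:
            msg = (
                f"level {rs.candidate_level}: {len(rs.measurements)} replicates "
                f"< required {min_replicates}"
            )
            if strict:
                raise InsufficientReplicatesError(msg)
            warnings.warn(msg, stacklevel=2)
    for rs in sorted(replicate_sets, key=lambda r: r.candidate_level):
        if rs.candidate_level < lob:
            continue
        if (
            precision_pct(rs.measurements) >= precision_min
            and trueness_pct(rs.measurements, rs.candidate_level) >= trueness_min
        ):
            return rs.candidate_level
    raise NoQualifyingLevelError(
        f"no candidate level met precision >= {precision_min}% "
        f"and trueness >= {trueness_min}%"
    )


def verify_cutoff(
    control_values: Sequence[float],
    cutoff: float,
    max_exceed_fraction: float = 0.15,
) -> VerificationResult:
    """Clinically verify a cutoff on independent healthy controls.

    Failed analyses (NaN values) are excluded from the denominator.  The
    cutoff passes when the fraction of controls strictly above it does not
    exceed ``max_exceed_fraction``.
    """
    x = np.asarray(list(control_values), dtype=float)
    valid = x[~np.isnan(x)]
    if valid.size == 0:
        raise ValueError("no valid control measurements after excluding failures")
    n_exceed = int((valid > cutoff).sum())
    frac = n_exceed / valid.size
    return VerificationResult(
        passed=frac <= max_exceed_fraction,
        exceed_fraction=frac,
        n_exceed=n_exceed,
        n_valid=int(valid.size),
    )
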