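"""Droplet digital PCR quantification.

A ddPCR reaction partitions the template into ~20,000 nanoliter droplets.
Template molecules distribute across droplets approximately as a Poisson
process, so the mean number of copies per droplet is recovered from the
fraction of positive droplets f as

    lambda = -ln(1 - f)

and the concentration in copies/uL follows from the droplet volume.  The
variant allele frequency (VAF) of a mutant assay is the mutant fraction of
all detected alleles,

    VAF (%) = 100 * N_mut / (N_mut + N_WT),

computed here from Poisson-corrected copy numbers rather than raw droplet
counts, because at 20-30 ng of input two templates frequently co-occupy a
droplet.

Uncertainty: each channel's rate estimate carries two noise components —
Poisson sampling of template molecules into the reaction and binomial
droplet partitioning.  Channel intervals combine both on the log scale
(exact Clopper-Pearson for zero counts) and are merged conservatively
(mutant-low with WT-high and vice versa) into a VAF interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.stats import beta, norm

__all__ = [
    "DropletWell",
    "VafMeasurement",
    "SaturationError",
    "MixedAssayError",
    "UndefinedVafError",
    "droplets_to_copies",
    "positive_fraction_interval",
    "poisson_rate_interval",
    "merge_wells",
    "compute_vaf",
    "quantify_sample",
]

#: default droplet volume of the QX200 system, nanoliters
DEFAULT_DROPLET_VOLUME_NL = 0.85

#: validated cfDNA input mass range per reaction, ng
VALIDATED_INPUT_MASS_NG = (20.0, 30.0)


class SaturationError(ValueError):
    """All droplets positive: the Poisson correction is undefined."""


class MixedAssayError(ValueError):
    """Wells from different assays cannot be pooled."""


class UndefinedVafError(ValueError):
    """VAF is undefined when no alleles of either kind were detected."""


@dataclass(frozen=True)
class DropletWell:
    """Raw readout of one ddPCR well.

    Parameters
    ----------
    assay_id : str
        Assay identifier, e.g. ``"BRAF_V600E"`` or ``"KRAS_G12G13"``.
    k_mut, k_wt : int
        Droplets positive on the mutant / wild-type channel.
    n_total : int
        Total accepted droplets.
    v_droplet : float
        Droplet volume in nL.
    input_mass : float
        cfDNA mass loaded into the reaction, ng.
    """

    assay_id: str
    k_mut: int
    k_wt: int
    n_total: int
    v_droplet: float = DEFAULT_DROPLET_VOLUME_NL
    input_mass: float = 25.0

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError(f"n_total must be positive, got {self.n_total}")
        if self.v_droplet <= 0:
            raise ValueError(f"v_droplet must be positive, got {self.v_droplet}")
        for name, k in (("k_mut", self.k_mut), ("k_wt", self.k_wt)):
            if k < 0:
                raise ValueError(f"{name} must be nonnegative, got {k}")
            if k > self.n_total:
                raise ValueError(f"{name}={k} exceeds n_total={self.n_total}")


@dataclass(frozen=True)
class VafMeasurement:
    """Merged-well quantification of one sample.

    ``n_mut``/``n_wt`` are estimated allele concentrations in copies/uL of
    reaction volume; ``vaf`` and the interval bounds are percentages.
    """

    n_mut: float
    n_wt: float
    vaf: float
    ci_low: float
    ci_high: float
    input_mass: float
    in_validated_range: bool = True
    n_wells: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf <= 100.0):
            raise ValueError(f"vaf out of range: {self.vaf}")
        if not (self.ci_low <= self.vaf <= self.ci_high):
            raise ValueError("interval must bracket the point estimate")
        if (self.vaf == 0.0) != (self.n_mut == 0.0):
            raise ValueError("vaf is zero iff no mutant copies were detected")


def droplets_to_copies(k_pos: int, n_total: int, v_droplet: float = DEFAULT_DROPLET_VOLUME_NL) -> float:
    """Poisson-correct a droplet count into a concentration (copies/uL).

    ``lambda = -ln(1 - k_pos/n_total)`` copies per droplet, divided by the
    droplet volume.  Returns 0 for ``k_pos == 0``; raises
    :class:`SaturationError` when every droplet is positive.
    """
    if k_pos < 0 or n_total <= 0 or v_droplet <= 0:
        raise ValueError("counts must be nonnegative and n_total, v_droplet positive")
    if k_pos > n_total:
        raise ValueError(f"k_pos={k_pos} exceeds n_total={n_total}")
    if k_pos == n_total:
        raise SaturationError(
            f"all {n_total} droplets positive; concentration not quantifiable"
        )
    if k_pos == 0:
        return 0.0
    lam = -math.log1p(-k_pos / n_total)  # copies per droplet
    return lam / (v_droplet * 1e-3)  # nL -> uL


def positive_fraction_interval(k_pos: int, n_total: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) interval for the positive-droplet fraction."""
    if not 0 <= k_pos <= n_total:
        raise ValueError("k_pos must lie in [0, n_total]")
    lo = 0.0 if k_pos == 0 else float(beta.ppf(alpha / 2, k_pos, n_total - k_pos + 1))
    hi = 1.0 if k_pos == n_total else float(beta.ppf(1 - alpha / 2, k_pos + 1, n_total - k_pos))
    return lo, hi


def poisson_rate_interval(k_pos: int, n_total: int, alpha: float = 0.05) -> tuple[float, float]:
    """Interval for the mean copies per droplet, from the binomial bounds."""
    p_lo, p_hi = positive_fraction_interval(k_pos, n_total, alpha)
    lam_lo = -math.log1p(-p_lo)
    lam_hi = math.inf if p_hi >= 1.0 else -math.log1p(-p_hi)
    return lam_lo, lam_hi


def _channel_rate_interval(k_pos: int, n_total: int, alpha: float) -> tuple[float, float]:
    """Interval for the per-droplet rate including template-sampling noise.

    Two variance components: Poisson sampling of template molecules into the
    reaction (relative variance 1/copies) and droplet partitioning (delta
    method on the binomial positive fraction).  Log-normal interval keeps
    the bounds positive; for k=0 the exact Clopper-Pearson upper bound is
    used.
    """
    if k_pos == 0:
        return 0.0, poisson_rate_interval(0, n_total, alpha)[1]
    p = k_pos / n_total
    lam = -math.log1p(-p)
    copies = n_total * lam
    rel_var = 1.0 / copies + p / (n_total * (1.0 - p) * lam**2)
    z = float(norm.ppf(1.0 - alpha / 2.0))
    spread = math.exp(z * math.sqrt(rel_var))
    return lam / spread, lam * spread


def merge_wells(wells: Sequence[DropletWell]) -> DropletWell:
    """Pool replicate wells of one sample+assay by summing counts and mass."""
    wells = list(wells)
    if not wells:
        raise ValueError("cannot merge an empty list of wells")
    assay_ids = {w.assay_id for w in wells}
    if len(assay_ids) > 1:
        raise MixedAssayError(f"wells mix assays: {sorted(assay_ids)}")
    volumes = {w.v_droplet for w in wells}
    if len(volumes) > 1:
        raise ValueError("wells disagree on droplet volume")
    return DropletWell(
        assay_id=wells[0].assay_id,
        k_mut=sum(w.k_mut for w in wells),
        k_wt=sum(w.k_wt for w in wells),
        n_total=sum(w.n_total for w in wells),
        v_droplet=wells[0].v_droplet,
        input_mass=sum(w.input_mass for w in wells),
    )


def compute_vaf(n_mut: float, n_wt: float) -> float:
    """Mutant allele percentage of all detected alleles."""
    if n_mut < 0 or n_wt < 0:
        raise ValueError("allele counts must be nonnegative")
    if n_mut + n_wt == 0:
        raise UndefinedVafError("no alleles detected on either channel")
    return 100.0 * n_mut / (n_mut + n_wt)


def quantify_sample(
    wells: Iterable[DropletWell],
    alpha: float = 0.05,
    validated_mass_range: tuple[float, float] = VALIDATED_INPUT_MASS_NG,
) -> VafMeasurement:
    """Merge replicate wells and quantify the sample's VAF with uncertainty.

    Raises :class:`UndefinedVafError` when neither channel detected anything
    and :class:`SaturationError` when a channel is fully positive.  An input
    mass outside the validated range is flagged (and warned about), not an
    error.
    """
    wells = list(wells)
    merged = merge_wells(wells)
    if merged.k_mut == 0 and merged.k_wt == 0:
        raise UndefinedVafError("no positive droplets on either channel")
    if merged.k_mut == merged.n_total or merged.k_wt == merged.n_total:
        raise SaturationError("a channel is saturated; dilute and re-run")

    n = merged.n_total
    lam_mut = 0.0 if merged.k_mut == 0 else -math.log1p(-merged.k_mut / n)
    lam_wt = 0.0 if merged.k_wt == 0 else -math.log1p(-merged.k_wt / n)
    mut_lo, mut_hi = _channel_rate_interval(merged.k_mut, n, alpha)
    wt_lo, wt_hi = _channel_rate_interval(merged.k_wt, n, alpha)

    vaf = compute_vaf(lam_mut, lam_wt)
    # conservative channel combination: mutant-low vs WT-high and vice versa
    ci_low = 0.0 if mut_lo == 0.0 else 100.0 * mut_lo / (mut_lo + wt_hi)
    denom_hi = mut_hi + wt_lo
    ci_high = 100.0 if denom_hi == 0 or math.isinf(mut_hi) else 100.0 * mut_hi / denom_hi
    ci_low = min(ci_low, vaf)
    ci_high = max(ci_high, vaf)

    to_copies = 1.0 / (merged.v_droplet * 1e-3)
    lo_mass, hi_mass = validated_mass_range
    in_range = lo_mass <= merged.input_mass <= hi_mass
    if not in_range:
        warnings.warn(
            f"input mass {merged.input_mass:.1f} ng outside validated "
            f"range [{lo_mass:g}, {hi_mass:g}] ng; cutoffs may not apply",
            stacklevel=2,
        )
    return VafMeasurement(
        n_mut=lam_mut * to_copies,
        n_wt=lam_wt * to_copies,
        vaf=vaf,
        ci_low=ci_low,
        ci_high=ci_high,
        input_mass=merged.input_mass,
        in_validated_range=in_range,
        n_wells=len(wells),
    )
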