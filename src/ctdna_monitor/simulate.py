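"""Seeded synthetic ddPCR data with the statistical structure of the study.

The forward model mirrors the physics the quantification inverts:

* A reaction receives 20-30 ng cfDNA, ~303 haploid genome equivalents per
  ng.  Template copies are split mutant/wild-type by the true VAF and
  partitioned into ~20,000 droplets; a droplet is channel-positive when it
  holds at least one copy (probability ``1 - exp(-c/n)``).
* Blank (analyte-free) wells add a small Poisson number of false-positive
  mutant droplets per well — the assay's intrinsic noise.  The rate is
  per-assay: the pooled 7-probe KRAS screening assay is noisier than the
  single-probe BRAF assay.
* Cohorts combine healthy donors (blank VAFs, log-normal cfDNA around a
  2.5 ng/mL median) with patients (stage-dependent shedding probability and
  baseline VAF, log-normal cfDNA around 11.6 ng/mL while tumor is evident)
  on a fixed visit grid, with surgery/chemotherapy timelines drawn from
  trajectory templates (cleared, MRD-responder, recurrence-with-lead).

All randomness flows through one ``numpy.random.Generator``; a fixed seed
and config reproduce every output bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import CEA_CUTOFF_NONSMOKER, CEA_CUTOFF_SMOKER
from .ddpcr import DropletWell, quantify_sample
from .validation import LoqReplicateSet

__all__ = [
    "SimulationConfig",
    "CohortSim",
    "simulate_blank_well",
    "simulate_blank_vafs",
    "simulate_positive_well",
    "simulate_loq_replicates",
    "simulate_cohort",
]

STAGE_COUNTS_DEFAULT = {"I": 4, "II": 8, "III": 4, "IV": 2}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults encode the measurement setting the analysis assumes: 20-30 ng
    input, ~20,000 accepted 0.85 nL droplets, healthy/patient cfDNA medians
    of 2.5 and 11.6 ng/mL, and stage-dependent ctDNA shedding that rises
    from UICC I to IV.
    """

    seed: int = 0
    n_droplets: int = 20_000
    v_droplet_nl: float = 0.85
    input_mass_range: tuple[float, float] = (20.0, 30.0)
    genome_equiv_per_ng: float = 303.0
    #: expected false-positive mutant droplets per blank well, per assay
    blank_fp_rate: dict[str, float] = field(
        default_factory=lambda: {"BRAF_V600E": 0.35, "KRAS_G12G13": 4.0}
    )
    healthy_cfdna_median: float = 2.5
    healthy_cfdna_sigma: float = 0.6
    patient_cfdna_median: float = 11.6
    patient_cfdna_sigma: float = 0.7
    stage_shed_prob: dict[str, float] = field(
        default_factory=lambda: {"I": 0.1, "II": 0.5, "III": 0.75, "IV": 1.0}
    )
    stage_vaf_median: dict[str, float] = field(
        default_factory=lambda: {"I": 0.05, "II": 0.3, "III": 1.0, "IV": 10.0}
    )
    stage_vaf_sigma: float = 0.8
    visit_interval_days: int = 14
    horizon_days: int = 365
    #: template mix for shedding surgery patients
    template_weights: dict[str, float] = field(
        default_factory=lambda: {"cleared": 0.6, "mrd_responder": 0.25, "recurrence": 0.15}
    )
    mrd_residual_factor: float = 0.3
    recurrence_clinical_day: int = 270
    recurrence_lead_days: int = 90
    recurrence_onset_vaf: float = 0.5
    #: fraction of shedding patients whose gDNA carries a clonal-hematopoiesis
    #: signal exceeding the plasma level
    ch_fraction: float = 0.0
    ch_gdna_factor: float = 5.0
    cea_elevated_prob: dict[str, float] = field(
        default_factory=lambda: {"I": 0.0, "II": 0.05, "III": 0.2, "IV": 0.5}
    )
    smoker_prob: float = 0.3
    #: couple cfDNA concentration / CEA elevation to the tumor-evident state;
    #: decoupled markers are drawn identically in every disease phase
    cfdna_tumor_coupled: bool = True
    cea_tumor_coupled: bool = True

    def validate(self) -> None:
        if self.n_droplets <= 0 or self.v_droplet_nl <= 0:
            raise ValueError("droplet geometry must be positive")
        if any(r < 0 for r in self.blank_fp_rate.values()):
            raise ValueError("blank false-positive rates must be nonnegative")
        lo, hi = self.input_mass_range
        if not 0 < lo <= hi:
            raise ValueError("input mass range must be positive and ordered")
        if abs(sum(self.template_weights.values()) - 1.0) > 1e-9:
            raise ValueError("template weights must sum to 1")


def _draw_mass(config: SimulationConfig, rng: np.random.Generator, size=None):
    lo, hi = config.input_mass_range
    return rng.uniform(lo, hi, size=size)


def _occupancy_positive(rng: np.random.Generator, copies, n_droplets):
    """Positive-droplet counts when `copies` templates fill n droplets."""
    p = -np.expm1(-np.asarray(copies, dtype=float) / n_droplets)
    return rng.binomial(n_droplets, p)


def simulate_blank_well(
    config: SimulationConfig, assay_id: str, rng: np.random.Generator
) -> DropletWell:
    """One analyte-free well: WT occupancy plus Poisson false positives."""
    config.validate()
    mass = float(_draw_mass(config, rng))
    wt_copies = rng.poisson(mass * config.genome_equiv_per_ng)
    k_wt = int(_occupancy_positive(rng, wt_copies, config.n_droplets))
    k_mut = int(min(rng.poisson(config.blank_fp_rate[assay_id]), config.n_droplets))
    return DropletWell(
        assay_id=assay_id,
        k_mut=k_mut,
        k_wt=k_wt,
        n_total=config.n_droplets,
        v_droplet=config.v_droplet_nl,
        input_mass=mass,
    )


def simulate_blank_vafs(
    n: int, config: SimulationConfig, assay_id: str, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized measured VAFs (%) of ``n`` blank wells.

    Equivalent to quantifying ``simulate_blank_well`` outputs one at a time
    but fast enough for large specificity calibrations.
    """
    config.validate()
    nd = config.n_droplets
    mass = _draw_mass(config, rng, size=n)
    wt_copies = rng.poisson(mass * config.genome_equiv_per_ng)
    k_wt = _occupancy_positive(rng, wt_copies, nd)
    k_mut = np.minimum(rng.poisson(config.blank_fp_rate[assay_id], size=n), nd)
    lam_wt = -np.log1p(-k_wt / nd)
    lam_mut = -np.log1p(-k_mut / nd)
    denom = lam_mut + lam_wt
    denom[denom == 0] = np.nan  # no signal on either channel
    vaf = 100.0 * lam_mut / denom
    return np.nan_to_num(vaf, nan=0.0)


def simulate_positive_well(
    config: SimulationConfig,
    true_vaf: float,
    rng: np.random.Generator,
    assay_id: str = "BRAF_V600E",
) -> DropletWell:
    """One well holding template at a known true VAF (%)."""
    config.validate()
    if not 0.0 < true_vaf <= 100.0:
        raise ValueError(f"true_vaf must be in (0, 100], got {true_vaf}")
    mass = float(_draw_mass(config, rng))
    total = rng.poisson(mass * config.genome_equiv_per_ng)
    mut = rng.binomial(total, true_vaf / 100.0)
    wt = total - mut
    k_mut = int(_occupancy_positive(rng, mut, config.n_droplets))
    k_mut = int(min(k_mut + rng.poisson(config.blank_fp_rate[assay_id]), config.n_droplets))
    k_wt = int(_occupancy_positive(rng, wt, config.n_droplets))
    return DropletWell(
        assay_id=assay_id,
        k_mut=k_mut,
        k_wt=k_wt,
        n_total=config.n_droplets,
        v_droplet=config.v_droplet_nl,
        input_mass=mass,
    )


def _measure_vaf(
    config: SimulationConfig,
    true_vaf: float,
    rng: np.random.Generator,
    assay_id: str,
) -> tuple[float, float, float]:
    """Simulate + quantify one sample; returns (vaf, ci_low, ci_high)."""
    if true_vaf > 0:
        well = simulate_positive_well(config, true_vaf, rng, assay_id)
    else:
        well = simulate_blank_well(config, assay_id, rng)
    m = quantify_sample([well])
    return m.vaf, m.ci_low, m.ci_high


def simulate_loq_replicates(
    config: SimulationConfig,
    levels: Sequence[float],
    rng: np.random.Generator,
    n_replicates: int = 40,
    assay_id: str = "BRAF_V600E",
) -> list[LoqReplicateSet]:
    """Replicate positive-control sets at each candidate VAF level."""
    sets = []
    for level in levels:
        vals = [
            quantify_sample([simulate_positive_well(config, level, rng, assay_id)]).vaf
            for _ in range(n_replicates)
        ]
        sets.append(LoqReplicateSet(candidate_level=level, measurements=tuple(vals)))
    return sets


@dataclass(frozen=True)
class CohortSim:
    """Output of :func:`simulate_cohort`."""

    samples: pd.DataFrame  # sample-sheet rows (plasma + gdna)
    events: pd.DataFrame  # patient_id, day, event_kind
    truth: pd.DataFrame  # per-patient ground truth for recovery tests
    healthy: pd.DataFrame  # healthy donors: blank VAFs and cfDNA


def _true_vaf_series(
    config: SimulationConfig,
    template: str,
    baseline_vaf: float,
    days: Sequence[int],
) -> dict[int, float]:
    """Ground-truth plasma VAF at each visit day (surgery at day 0)."""
    out: dict[int, float] = {}
    onset = config.recurrence_clinical_day - config.recurrence_lead_days
    for d in days:
        if d < 0:
            out[d] = baseline_vaf
        elif template == "cleared":
            out[d] = 0.0
        elif template == "mrd_responder":
            # residual disease after surgery, decaying under adjuvant chemo
            residual = baseline_vaf * config.mrd_residual_factor
            out[d] = residual * math.exp(-d / 30.0) if d <= 90 else 0.0
        elif template == "recurrence":
            if d < onset:
                out[d] = 0.0
            else:
                grow = 1.0 + (d - onset) / max(config.recurrence_lead_days, 1)
                out[d] = config.recurrence_onset_vaf * grow
        else:
            raise ValueError(f"unknown template {template!r}")
    return out


def simulate_cohort(
    config: SimulationConfig,
    n_patients: int = 18,
    n_healthy: int = 60,
    stage_counts: Optional[dict[str, int]] = None,
    rng: Optional[np.random.Generator] = None,
) -> CohortSim:
    """Full synthetic study: healthy donors plus surgery-patient timelines.

    Patients get a baseline visit (day -3), surgery at day 0 and follow-up
    visits on the configured grid.  Shedding patients draw a trajectory
    template; non-shedders stay negative throughout.  Matched lymphocyte
    gDNA is sampled for every patient (with an injected clonal-hematopoiesis
    signal for a configured fraction of shedders).
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    # ---- healthy donors -------------------------------------------------
    healthy_rows = []
    mu_h = math.log(config.healthy_cfdna_median)
    for i in range(n_healthy):
        assay = "BRAF_V600E" if i % 2 == 0 else "KRAS_G12G13"
        vaf = float(simulate_blank_vafs(1, config, assay, rng)[0])
        healthy_rows.append(
            {
                "donor_id": f"HC-{i + 1:03d}",
                "assay_id": assay,
                "vaf_pct": vaf,
                "cfdna_ng_ml": float(rng.lognormal(mu_h, config.healthy_cfdna_sigma)),
            }
        )

    # ---- patients -------------------------------------------------------
    if stage_counts is None:
        base = STAGE_COUNTS_DEFAULT
        total = sum(base.values())
        stage_list = [s for s, c in base.items() for _ in range(c)]
        # repeat/truncate the canonical stage mix to n_patients
        stage_list = [stage_list[i % total] for i in range(n_patients)]
    else:
        stage_list = [s for s, c in stage_counts.items() for _ in range(c)]
        if len(stage_list) != n_patients:
            raise ValueError("stage_counts must sum to n_patients")

    visit_days = [-3] + list(
        range(config.visit_interval_days, config.horizon_days + 1, config.visit_interval_days)
    )
    templates = list(config.template_weights)
    weights = np.array([config.template_weights[t] for t in templates])

    sample_rows, event_rows, truth_rows = [], [], []
    mu_p = math.log(config.patient_cfdna_median)
    for i, stage in enumerate(stage_list):
        pid = f"SIM-{i + 1:03d}"
        assay = "BRAF_V600E" if i % 2 == 0 else "KRAS_G12G13"
        smoker = bool(rng.random() < config.smoker_prob)
        sheds = bool(rng.random() < config.stage_shed_prob[stage])
        baseline_vaf = 0.0
        template = "cleared"
        if sheds:
            baseline_vaf = float(
                rng.lognormal(math.log(config.stage_vaf_median[stage]), config.stage_vaf_sigma)
            )
            baseline_vaf = min(baseline_vaf, 80.0)
            template = str(rng.choice(templates, p=weights))
        ch_injected = bool(sheds and rng.random() < config.ch_fraction)

        event_rows.append({"patient_id": pid, "day": 0, "event_kind": "surgery"})
        if template == "mrd_responder":
            event_rows.append({"patient_id": pid, "day": 14, "event_kind": "chemo_start"})
            event_rows.append({"patient_id": pid, "day": 120, "event_kind": "chemo_end"})
        if template == "recurrence":
            event_rows.append(
                {
                    "patient_id": pid,
                    "day": config.recurrence_clinical_day,
                    "event_kind": "recurrence_clinical",
                }
            )

        true_by_day = _true_vaf_series(config, template, baseline_vaf, visit_days)
        for day in visit_days:
            tv = true_by_day[day]
            vaf, lo, hi = _measure_vaf(config, tv, rng, assay)
            tumor_evident = tv > 0 or day < 0
            cf_high = tumor_evident if config.cfdna_tumor_coupled else True
            mu = mu_p if cf_high else mu_h
            sigma = config.patient_cfdna_sigma if cf_high else config.healthy_cfdna_sigma
            cfdna = float(rng.lognormal(mu, sigma))
            if config.cea_tumor_coupled:
                cea_prob = config.cea_elevated_prob[stage] if tumor_evident else 0.01
            else:
                cea_prob = 0.15  # flat across phases and stages
            cea_elev = rng.random() < cea_prob
            threshold = CEA_CUTOFF_SMOKER if smoker else CEA_CUTOFF_NONSMOKER
            cea = float(
                rng.uniform(threshold * 1.2, threshold * 4)
                if cea_elev
                else rng.uniform(0.3, threshold * 0.9)
            )
            sample_rows.append(
                {
                    "sample_id": f"{pid}-d{day}",
                    "patient_id": pid,
                    "collection_day": day,
                    "specimen": "plasma",
                    "assay_id": assay,
                    "vaf_pct": vaf,
                    "vaf_ci_low": lo,
                    "vaf_ci_high": hi,
                    "cfdna_ng_ml": cfdna,
                    "cea_ng_ml": cea,
                    "smoker": smoker,
                    "uicc_stage": stage,
                    "true_vaf_pct": tv,
                }
            )
        # matched lymphocyte gDNA
        gdna_true = baseline_vaf * config.ch_gdna_factor if ch_injected else 0.0
        gdna_vaf, glo, ghi = _measure_vaf(config, min(gdna_true, 80.0), rng, assay)
        sample_rows.append(
            {
                "sample_id": f"{pid}-gdna",
                "patient_id": pid,
                "collection_day": -3,
                "specimen": "gdna",
                "assay_id": assay,
                "vaf_pct": gdna_vaf,
                "vaf_ci_low": glo,
                "vaf_ci_high": ghi,
                "cfdna_ng_ml": float("nan"),
                "cea_ng_ml": float("nan"),
                "smoker": smoker,
                "uicc_stage": stage,
                "true_vaf_pct": gdna_true,
            }
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "uicc_stage": stage,
                "assay_id": assay,
                "sheds": sheds,
                "template": template,
                "baseline_true_vaf": baseline_vaf,
                "ch_injected": ch_injected,
                "recurrence_onset_day": (
                    config.recurrence_clinical_day - config.recurrence_lead_days
                    if template == "recurrence"
                    else None
                ),
            }
        )

    return CohortSim(
        samples=pd.DataFrame(sample_rows),
        events=pd.DataFrame(event_rows, columns=["patient_id", "day", "event_kind"]),
        truth=pd.DataFrame(truth_rows),
        healthy=pd.DataFrame(healthy_rows),
    )

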