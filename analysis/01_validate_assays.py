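#!/usr/bin/env python
"""Establish and clinically verify the assay cutoffs.

Estimates each assay's limit of blank from 60 simulated blank wells and its
limit of quantification from 40-replicate positive-control sets, then
verifies the detection cutoff against the bundled healthy-control outcomes
(1/10 exceedance for BRAF p.V600E, 0/8 for KRAS p.G12/p.G13 after two
failed analyses).  Also derives the cfDNA concentration cutoff from a
simulated healthy cohort.  Writes results/assay_validation.json.
"""

import json
from pathlib import Path

import numpy as np

from ctdna_monitor.pipeline import validate_assay
from ctdna_monitor.reference import reference_cohort
from ctdna_monitor.simulate import SimulationConfig, simulate_blank_vafs, simulate_loq_replicates
from ctdna_monitor.validation import estimate_concentration_cutoff

SEED = 20180301
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    rng = np.random.default_rng(SEED)
    ref = reference_cohort()
    report = {}
    for assay in ("BRAF_V600E", "KRAS_G12G13"):
        blanks = simulate_blank_vafs(60, cfg, assay, rng)
        sets = simulate_loq_replicates(
            cfg, [round(0.1 * k, 1) for k in range(1, 11)], rng, n_replicates=40, assay_id=assay
        )
        res = validate_assay(assay, blanks, sets, ref.verification_controls[assay])
        res.pop("cutoffs")
        report[assay] = res
        print(
            f"{assay}: LOB {res['lob']:.3f}% VAF, LOQ {res['loq']:.2f}% VAF, "
            f"verification exceedance {100 * res['exceed_fraction']:.0f}% "
            f"of {res['n_controls']} controls -> verified={res['verified']}"
        )

    healthy_cfdna = rng.lognormal(np.log(cfg.healthy_cfdna_median), cfg.healthy_cfdna_sigma, 60)
    cutoff = estimate_concentration_cutoff(healthy_cfdna)
    report["cfdna_cutoff_ng_ml"] = cutoff
    print(f"cfDNA concentration cutoff from 60 simulated healthy donors: {cutoff:.2f} ng/mL")

    OUT.mkdir(exist_ok=True)
    (OUT / "assay_validation.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {OUT / 'assay_validation.json'}")


if __name__ == "__main__":
    main()
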