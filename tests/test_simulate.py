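"""Synthetic generator: determinism, forward/inverse consistency, cohorts."""

import numpy as np
import pandas as pd
import pytest

from ctdna_monitor.classify import CtdnaStatus
from ctdna_monitor.ddpcr import quantify_sample
from ctdna_monitor.io import build_timelines
from ctdna_monitor.monitoring import detect_recurrence
from ctdna_monitor.pipeline import baseline_frame
from ctdna_monitor.simulate import (
    SimulationConfig,
    simulate_blank_vafs,
    simulate_blank_well,
    simulate_cohort,
    simulate_positive_well,
)
from ctdna_monitor.validation import estimate_lob


@pytest.fixture
def cfg():
    return SimulationConfig(seed=123)


class TestBlankWells:
    def test_zero_false_positive_rate_never_yields_mutant_droplets(self):
        cfg = SimulationConfig(blank_fp_rate={"BRAF_V600E": 0.0, "KRAS_G12G13": 0.0})
        rng = np.random.default_rng(0)
        assert all(
            simulate_blank_well(cfg, "BRAF_V600E", rng).k_mut == 0 for _ in range(200)
        )

    def test_false_positive_rate_law_of_large_numbers(self, cfg):
        rng = np.random.default_rng(1)
        ks = [simulate_blank_well(cfg, "KRAS_G12G13", rng).k_mut for _ in range(10_000)]
        assert np.mean(ks) == pytest.approx(cfg.blank_fp_rate["KRAS_G12G13"], rel=0.05)

    def test_vectorized_blanks_deterministic_under_seed(self, cfg):
        a = simulate_blank_vafs(500, cfg, "BRAF_V600E", np.random.default_rng(9))
        b = simulate_blank_vafs(500, cfg, "BRAF_V600E", np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_lob_from_blanks_calibrates_specificity(self, cfg):
        # quick calibration loop: fresh-blank specificity near 95%
        rng = np.random.default_rng(5)
        specs = []
        for _ in range(100):
            lob = estimate_lob(simulate_blank_vafs(60, cfg, "BRAF_V600E", rng))
            fresh = simulate_blank_vafs(2000, cfg, "BRAF_V600E", rng)
            specs.append(float((fresh <= lob).mean()))
        assert np.mean(specs) == pytest.approx(0.95, abs=0.015)


class TestPositiveWells:
    def test_pure_mutant_sample_has_negligible_wt(self, cfg):
        rng = np.random.default_rng(3)
        well = simulate_positive_well(cfg, 100.0, rng)
        assert well.k_wt == 0

    def test_rejects_nonpositive_vaf(self, cfg):
        with pytest.raises(ValueError):
            simulate_positive_well(cfg, 0.0, np.random.default_rng(0))

    def test_median_recovery_at_one_percent(self, cfg):
        rng = np.random.default_rng(17)
        vafs = [
            quantify_sample([simulate_positive_well(cfg, 1.0, rng)]).vaf
            for _ in range(200)
        ]
        assert np.median(vafs) == pytest.approx(1.0, rel=0.10)

    @pytest.mark.parametrize("true_vaf", [0.5, 1.0, 5.0, 10.0])
    def test_forward_inverse_consistency(self, true_vaf):
        cfg = SimulationConfig(blank_fp_rate={"BRAF_V600E": 0.0, "KRAS_G12G13": 0.0})
        rng = np.random.default_rng(int(true_vaf * 10))
        vafs = [
            quantify_sample([simulate_positive_well(cfg, true_vaf, rng)]).vaf
            for _ in range(500)
        ]
        se = np.std(vafs, ddof=1) / np.sqrt(len(vafs))
        assert abs(np.mean(vafs) - true_vaf) < max(4 * se, 0.02 * true_vaf)


class TestCohort:
    def test_bit_identical_under_fixed_seed(self):
        sim1 = simulate_cohort(SimulationConfig(seed=42), n_patients=6, n_healthy=10)
        sim2 = simulate_cohort(SimulationConfig(seed=42), n_patients=6, n_healthy=10)
        pd.testing.assert_frame_equal(sim1.samples, sim2.samples)
        pd.testing.assert_frame_equal(sim1.events, sim2.events)
        pd.testing.assert_frame_equal(sim1.healthy, sim2.healthy)

    def test_zero_shedding_cohort_has_no_baseline_detection(self):
        cfg = SimulationConfig(
            seed=7,
            stage_shed_prob={"I": 0.0, "II": 0.0, "III": 0.0, "IV": 0.0},
            blank_fp_rate={"BRAF_V600E": 0.0, "KRAS_G12G13": 0.0},
        )
        sim = simulate_cohort(cfg, n_patients=8, n_healthy=0)
        tls = build_timelines(sim.samples.drop(columns=["true_vaf_pct"]), sim.events)
        assert not baseline_frame(tls)["ctdna_detected"].any()

    def test_recurrence_template_recovers_lead_time(self):
        cfg = SimulationConfig(
            seed=11,
            template_weights={"cleared": 0.0, "mrd_responder": 0.0, "recurrence": 1.0},
            stage_shed_prob={"I": 1.0, "II": 1.0, "III": 1.0, "IV": 1.0},
            blank_fp_rate={"BRAF_V600E": 0.0, "KRAS_G12G13": 0.0},
        )
        sim = simulate_cohort(cfg, n_patients=6, n_healthy=0, stage_counts={"IV": 6})
        tls = build_timelines(sim.samples.drop(columns=["true_vaf_pct"]), sim.events)
        for pid, tl in tls.items():
            calls = [c for c in detect_recurrence(tl) if c.confirmed]
            assert calls, f"{pid} missed its molecular recurrence"
            lead = calls[0].lead_time_days
            assert (
                cfg.recurrence_lead_days - cfg.visit_interval_days
                <= lead
                <= cfg.recurrence_lead_days
            )

    def test_ch_injection_is_flagged_exactly(self):
        common = dict(
            template_weights={"cleared": 1.0, "mrd_responder": 0.0, "recurrence": 0.0},
            stage_shed_prob={"I": 1.0, "II": 1.0, "III": 1.0, "IV": 1.0},
        )
        cfg = SimulationConfig(seed=19, ch_fraction=1.0, **common)
        sim = simulate_cohort(cfg, n_patients=6, n_healthy=0, stage_counts={"IV": 6})
        tls = build_timelines(sim.samples.drop(columns=["true_vaf_pct"]), sim.events)
        for pid, tl in tls.items():
            baseline = [s for s in tl.samples if s.day < 0][0]
            assert baseline.call.status is CtdnaStatus.CH_SUSPECTED

        clean = SimulationConfig(seed=19, ch_fraction=0.0, **common)
        sim2 = simulate_cohort(clean, n_patients=6, n_healthy=0, stage_counts={"IV": 6})
        tls2 = build_timelines(sim2.samples.drop(columns=["true_vaf_pct"]), sim2.events)
        statuses = [s.call.status for tl in tls2.values() for s in tl.samples]
        assert CtdnaStatus.CH_SUSPECTED not in statuses

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_droplets=0).validate()
        with pytest.raises(ValueError):
            SimulationConfig(
                template_weights={"cleared": 0.5, "mrd_responder": 0.0, "recurrence": 0.0}
            ).validate()
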