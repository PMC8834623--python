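"""Rank-based cohort statistics and phase comparisons."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from ctdna_monitor.stats import (
    PHASES,
    assign_phases,
    bonferroni,
    multi_group_test,
    phase_comparison,
    two_group_test,
)


def exact_ranksum_p(a, b):
    """Enumeration oracle: two-sided p over all rank assignments (no ties)."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    n = len(pooled)
    mean_w = len(a) * (n + 1) / 2
    ws = [sum(c) for c in combinations(range(1, n + 1), len(a))]
    extreme = sum(1 for w in ws if abs(w - mean_w) >= abs(w_obs - mean_w))
    return extreme / len(ws)


class TestTwoGroup:
    def test_identical_samples_give_p_one(self):
        assert two_group_test([1.0, 1.0, 1.0], [1.0, 1.0]).p == 1.0

    def test_extreme_ranking_matches_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = two_group_test(a, b)
        assert res.p == pytest.approx(exact_ranksum_p(a, b))  # = 2/20
        assert res.p == pytest.approx(0.1)
        assert res.statistic == 6.0  # rank-sum of the first sample

    def test_matches_enumeration_on_random_small_samples(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            a = list(rng.normal(0, 1, 4))
            b = list(rng.normal(0.5, 1, 5))
            assert two_group_test(a, b).p == pytest.approx(exact_ranksum_p(a, b))

    def test_large_shift_is_overwhelming(self):
        rng = np.random.default_rng(2)
        healthy = rng.lognormal(np.log(2.5), 0.6, 60)
        patients = rng.lognormal(np.log(11.6), 0.7, 128)
        assert two_group_test(healthy, patients).p < 1e-6

    def test_symmetry_and_monotone_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 15), rng.normal(0.8, 1, 12)
        p_ab = two_group_test(a, b).p
        assert two_group_test(b, a).p == pytest.approx(p_ab)
        assert two_group_test(np.exp(a), np.exp(b)).p == pytest.approx(p_ab)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            two_group_test([], [1.0])


class TestMultiGroup:
    def test_identical_groups(self):
        res = multi_group_test([[1.0, 1.0], [1.0], [1.0, 1.0]])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_computed_h(self):
        # three tie-free groups of 3 with fully separated ranks: H = 7.2
        res = multi_group_test([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)

    def test_bonferroni_multiplier_is_pair_count(self):
        res = multi_group_test([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert len(res.pairwise) == 3
        raw = two_group_test([1, 2, 3], [4, 5, 6]).p
        assert res.pairwise[(0, 1)] == pytest.approx(min(1.0, 3 * raw))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            multi_group_test([[1.0], [], [2.0]])

    def test_two_group_h_agrees_with_ranksum_asymptotically(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 200)
        b = rng.normal(0.2, 1, 200)
        p_h = multi_group_test([a, b]).p
        p_w = two_group_test(a, b).p
        assert p_h == pytest.approx(p_w, rel=0.05)


class TestBonferroni:
    @pytest.mark.parametrize("p, m, expected", [(0.02, 3, 0.06), (0.5, 4, 1.0), (0.0, 10, 0.0)])
    def test_adjustment(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_never_below_raw(self):
        rng = np.random.default_rng(1)
        for p in rng.random(50):
            assert bonferroni(float(p), 5) >= p


def _phase_frame(vaf_effect=True, rng=None):
    rng = rng or np.random.default_rng(13)
    rows = []
    means = {"baseline": 5.0, "course_of_disease": 3.0, "followup_after_curative": 0.0}
    for phase in PHASES:
        for i in range(25):
            rows.append(
                {
                    "patient_id": f"p{i}",
                    "phase": phase,
                    "vaf": max(0.0, (means[phase] if vaf_effect else 1.0) + rng.normal(0, 0.5)),
                    "cfdna": float(rng.lognormal(np.log(6), 0.5)),
                    "cea": float(rng.lognormal(np.log(2), 0.4)),
                }
            )
    return pd.DataFrame(rows)


class TestPhaseComparison:
    def test_effect_only_on_vaf_detected(self):
        res = phase_comparison(_phase_frame(vaf_effect=True))
        assert res["vaf"].p < 0.05
        assert res["cfdna"].p > 0.05 and res["cea"].p > 0.05

    def test_shared_constant_gives_p_one(self):
        df = _phase_frame()
        for col in ("vaf", "cfdna", "cea"):
            df[col] = 1.0
        res = phase_comparison(df)
        assert all(r.p == 1.0 for r in res.values())

    def test_requires_all_three_phases(self):
        df = _phase_frame()
        with pytest.raises(ValueError):
            phase_comparison(df[df["phase"] != "baseline"])

    def test_permuted_labels_calibrate_type_one_error(self):
        rng = np.random.default_rng(77)
        df = _phase_frame(vaf_effect=True, rng=np.random.default_rng(3))
        labels = df["phase"].to_numpy().copy()
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            perm = df.copy()
            perm["phase"] = rng.permutation(labels)
            rejections += phase_comparison(perm, markers=("vaf",))["vaf"].p < 0.05
        rate = rejections / n_rep
        assert 0.03 <= rate <= 0.07


class TestSimulatedPhaseEffect:
    def test_vaf_only_effect_when_markers_decoupled(self):
        from ctdna_monitor.io import build_timelines
        from ctdna_monitor.simulate import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(
            seed=20180303, cfdna_tumor_coupled=False, cea_tumor_coupled=False
        )
        sim = simulate_cohort(cfg, n_patients=29, n_healthy=0)
        tls = build_timelines(sim.samples.drop(columns=["true_vaf_pct"]), sim.events)
        res = phase_comparison(assign_phases(list(tls.values())))
        assert res["vaf"].p < 0.05
        assert res["cfdna"].p > 0.05 and res["cea"].p > 0.05


class TestAssignPhases:
    def test_reference_timeline_phases(self, timelines):
        df = assign_phases([timelines["LB-CRC-25"]])
        by_day = df.set_index("day")["phase"]
        assert by_day[-3] == "baseline"
        assert by_day[90] == "followup_after_curative"
        assert by_day[430] == "course_of_disease"  # after clinical recurrence

    def test_primary_chemo_patient_course_until_remission(self, timelines):
        df = assign_phases([timelines["LB-CRC-32"]])
        by_day = df.set_index("day")["phase"]
        assert by_day[-3] == "baseline"
        assert by_day[60] == "course_of_disease"
        # remission at day 130 precedes no further samples here
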