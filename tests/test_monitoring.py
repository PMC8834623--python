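"""MRD calling, recurrence lead time, trajectory and marker concordance."""

import pytest

from ctdna_monitor.classify import classify_ctdna_status
from ctdna_monitor.monitoring import (
    ClinicalEvent,
    Direction,
    EventKind,
    PatientTimeline,
    TimepointSample,
    call_mrd,
    classify_trajectory,
    detect_recurrence,
    marker_concordance,
)
from ctdna_monitor.validation import PUBLISHED_CUTOFFS

BRAF = PUBLISHED_CUTOFFS["BRAF_V600E"]


def tp(day, vaf, hw=0.01):
    call = classify_ctdna_status(vaf, BRAF, sample_id=f"d{day}", ci=(max(vaf - hw, 0), vaf + hw))
    return TimepointSample(day=day, call=call)


def timeline(samples, events, pid="P1"):
    return PatientTimeline(pid, "III", "BRAF_V600E", samples, events)


SURGERY = ClinicalEvent(0, EventKind.SURGERY)


class TestCallMrd:
    def test_reference_mrd_patient_is_positive(self, timelines):
        res = call_mrd(timelines["LB-CRC-38"])
        assert res.mrd is True
        assert res.supporting_sample.day == 14
        assert res.supporting_sample.call.vaf == pytest.approx(1.72)

    def test_all_negative_post_surgery_is_mrd_negative(self, timelines):
        assert call_mrd(timelines["LB-CRC-18"]).mrd is False

    def test_baseline_negative_patients_stay_negative(self, surgery_timelines):
        # consistency with the study: the nine baseline-negative patients
        # were also negative after surgery
        for tl in surgery_timelines.values():
            base = [s for s in tl.samples if s.day < 0][0]
            if not base.call.status.detected:
                assert call_mrd(tl).mrd is False

    def test_positive_sample_outside_window_does_not_count(self):
        tl = timeline([tp(-3, 2.0), tp(60, 2.0)], [SURGERY])
        assert call_mrd(tl).evaluable is False
        tl2 = timeline([tp(-3, 2.0), tp(14, 0.0), tp(60, 2.0)], [SURGERY])
        assert call_mrd(tl2).mrd is False

    def test_no_surgery_or_no_window_sample_not_evaluable(self):
        assert call_mrd(timeline([tp(14, 1.0)], [])).evaluable is False
        assert call_mrd(timeline([tp(-3, 1.0)], [SURGERY])).evaluable is False

    def test_adding_negative_sample_never_flips_to_positive(self):
        tl = timeline([tp(14, 0.0)], [SURGERY])
        assert call_mrd(tl).mrd is False
        tl2 = timeline([tp(14, 0.0), tp(30, 0.0)], [SURGERY])
        assert call_mrd(tl2).mrd is False


class TestDetectRecurrence:
    def test_reference_lead_time_is_ninety_days(self, timelines):
        calls = detect_recurrence(timelines["LB-CRC-07"])
        assert len(calls) == 1
        assert calls[0].lead_time_days == 90 and calls[0].confirmed

    def test_never_positive_followup_gives_empty_list(self, timelines):
        assert detect_recurrence(timelines["LB-CRC-29"]) == []

    def test_same_day_positive_gives_zero_lead(self):
        tl = timeline(
            [tp(14, 0.0), tp(200, 1.0)],
            [SURGERY, ClinicalEvent(200, EventKind.RECURRENCE_CLINICAL)],
        )
        calls = detect_recurrence(tl)
        assert calls[0].lead_time_days == 0

    def test_unconfirmed_without_clinical_event(self):
        tl = timeline([tp(14, 0.0), tp(200, 1.0)], [SURGERY])
        calls = detect_recurrence(tl)
        assert len(calls) == 1 and not calls[0].confirmed

    def test_requires_preceding_negativity(self):
        # persistent positivity after surgery is residual disease, not a
        # recurrence call
        tl = timeline([tp(14, 2.0), tp(60, 1.5)], [SURGERY])
        assert detect_recurrence(tl) == []

    def test_molecular_first_preserved_under_time_shift(self):
        for shift in (0, 37):
            tl = timeline(
                [tp(14 + shift, 0.0), tp(100 + shift, 1.0)],
                [
                    ClinicalEvent(shift, EventKind.SURGERY),
                    ClinicalEvent(190 + shift, EventKind.RECURRENCE_CLINICAL),
                ],
            )
            assert detect_recurrence(tl)[0].lead_time_days == 90


class TestClassifyTrajectory:
    def test_printed_first_month_response(self, timelines):
        calls = classify_trajectory(timelines["LB-CRC-02"])
        first = calls[0]
        assert first.vaf_from == pytest.approx(47.75)
        assert first.vaf_to == pytest.approx(12.19)
        assert first.direction is Direction.RESPONSE

    def test_clearance_to_undetectable(self, timelines):
        calls = classify_trajectory(timelines["LB-CRC-25"])
        directions = [c.direction for c in calls]
        assert Direction.CLEARED in directions
        cleared = calls[directions.index(Direction.CLEARED)]
        assert cleared.vaf_to == 0.0

    def test_overlapping_intervals_are_stable(self):
        tl = timeline(
            [tp(0, 5.0, hw=1.0), tp(30, 5.1, hw=1.0)],
            [ClinicalEvent(0, EventKind.CHEMO_START)],
        )
        calls = classify_trajectory(tl, interval=(0, 40))
        assert calls[0].direction is Direction.STABLE

    def test_subquantifiable_pair_not_evaluable(self):
        tl = timeline([tp(0, 0.10, hw=0.02), tp(30, 0.30, hw=0.05)], [])
        calls = classify_trajectory(tl, interval=(0, 40))
        assert calls[0].direction is Direction.NOT_EVALUABLE

    def test_direction_flips_under_time_reversal(self):
        fwd = timeline([tp(0, 10.0, hw=1.0), tp(30, 2.0, hw=0.5)], [])
        rev = timeline([tp(0, 2.0, hw=0.5), tp(30, 10.0, hw=1.0)], [])
        d_fwd = classify_trajectory(fwd, interval=(0, 40))[0].direction
        d_rev = classify_trajectory(rev, interval=(0, 40))[0].direction
        assert {d_fwd, d_rev} == {Direction.RESPONSE, Direction.RESISTANCE}

    def test_fewer_than_two_samples_empty(self):
        tl = timeline([tp(10, 1.0)], [ClinicalEvent(0, EventKind.CHEMO_START)])
        assert classify_trajectory(tl, interval=(0, 40)) == []

    def test_fold_change_rule_without_intervals(self, braf_cutoffs):
        def bare(day, vaf):
            return TimepointSample(day, classify_ctdna_status(vaf, braf_cutoffs))

        tl = timeline([bare(0, 10.0), bare(30, 4.0)], [])
        assert classify_trajectory(tl, interval=(0, 40))[0].direction is Direction.RESPONSE
        tl2 = timeline([bare(0, 10.0), bare(30, 8.0)], [])
        assert classify_trajectory(tl2, interval=(0, 40))[0].direction is Direction.STABLE


class TestMarkerConcordance:
    def test_recurrence_predicted_only_by_ctdna(self, timelines):
        rows = marker_concordance(timelines["LB-CRC-07"])
        rec = rows[rows["event"] == "recurrence"].iloc[0]
        assert rec["ctdna"] and not rec["cfdna"] and not rec["cea"]

    def test_mrd_predicted_by_cea_not_flat_elevated_cfdna(self, timelines):
        rows = marker_concordance(timelines["LB-CRC-25"])
        mrd = rows[rows["event"] == "mrd"].iloc[0]
        assert mrd["ctdna"] and mrd["cea"] and not mrd["cfdna"]

    def test_missing_cfdna_in_window_is_not_assessable(self, timelines):
        rows = marker_concordance(timelines["LB-CRC-09"])
        mrd = rows[rows["event"] == "mrd"].iloc[0]
        assert mrd["ctdna"] and mrd["cea"] and mrd["cfdna"] is None

    def test_patient_without_events_gives_empty_table(self):
        tl = timeline([tp(0, 1.0)], [])
        assert marker_concordance(tl).empty
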