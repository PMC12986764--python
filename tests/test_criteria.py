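from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ranovol.criteria import (
    AssessmentTrack,
    BaselineMissingError,
    CallReason,
    CriteriaConfig,
    Criterion,
    Label,
    ProgressionCall,
    RawLabel,
    Trigger,
    apply_nonimaging_events,
    classify_scan,
    detect_psp_events,
    run_criteria,
    select_baseline,
    total_volume,
)
from ranovol.timelines import Compartment, LesionMeasurement, PatientTimeline, ScanRecord

from conftest import ce, ne


def scan(day, lesions):
    return ScanRecord(day, tuple(lesions))


class TestConfig:
    def test_presets(self):
        rano = CriteriaConfig.preset("rano")
        mrano = CriteriaConfig.preset("mrano")
        rano2 = CriteriaConfig.preset("rano2")
        assert rano.baseline_rule.value == "postop"
        assert mrano.baseline_rule.value == "postrt"
        assert rano2.baseline_rule.value == "postrt"
        assert mrano.confirmation_rule.value == "always_required"

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            CriteriaConfig.preset("rano", measurable_min_cm3=0.0)
        with pytest.raises(ValueError):
            CriteriaConfig.preset("rano", confirmation_window_weeks=(8.0, 4.0))


class TestTotalVolume:
    def test_sums_targets(self):
        s = scan(0, [ce("a", 1.2), ce("b", 0.8)])
        assert total_volume(s, Compartment.CE) == pytest.approx(2.0)

    def test_empty_compartment_is_zero(self):
        assert total_volume(scan(0, [ne("n", 3.0)]), Compartment.CE) == 0.0

    def test_caps_at_five_largest(self):
        s = scan(0, [ce(f"l{i}", float(i)) for i in range(1, 7)])
        assert total_volume(s, Compartment.CE) == pytest.approx(20.0)  # 2+3+4+5+6


class TestClassifyScan:
    @pytest.fixture()
    def cfg(self):
        return CriteriaConfig.preset("rano")

    def test_forty_percent_over_nadir_is_pd_candidate(self, cfg):
        s = scan(10, [ce("a", 2.8)])
        assert classify_scan(s, 2.0, 2.0, 0.0, 0.0, cfg) is RawLabel.PD_CANDIDATE

    def test_sixty_five_percent_drop_is_pr(self, cfg):
        s = scan(10, [ce("a", 3.5)])
        assert classify_scan(s, 10.0, 10.0, 0.0, 0.0, cfg) is RawLabel.PR

    def test_ne_doubling_is_pd_candidate(self, cfg):
        s = scan(10, [ce("a", 2.0), ne("n", 8.0)])
        assert classify_scan(s, 2.0, 2.0, 4.0, 4.0, cfg) is RawLabel.PD_CANDIDATE

    def test_disappearance_is_cr(self, cfg):
        s = scan(10, [])
        assert classify_scan(s, 5.0, 1.0, 0.0, 0.0, cfg) is RawLabel.CR

    def test_negative_reference_rejected(self, cfg):
        with pytest.raises(ValueError):
            classify_scan(scan(10, []), -1.0, 0.0, 0.0, 0.0, cfg)


class TestSelectBaseline:
    def test_fig2_postop(self, fig2_timeline, configs):
        assert select_baseline(fig2_timeline, configs[Criterion.RANO]).scan_day == 8

    def test_fig2_postrt(self, fig2_timeline, configs):
        assert select_baseline(fig2_timeline, configs[Criterion.MRANO]).scan_day == 115
        assert select_baseline(fig2_timeline, configs[Criterion.RANO2]).scan_day == 115

    def test_missing_window_raises(self, fig2_timeline, configs):
        pruned = dataclasses.replace(
            fig2_timeline,
            scans=tuple(s for s in fig2_timeline.scans if s.scan_day != 115))
        with pytest.raises(BaselineMissingError):
            select_baseline(pruned, configs[Criterion.RANO2])


class TestFig2WorkedExample:
    """The representative patient must split the three criteria exactly."""

    def test_rano_pd_at_second_followup(self, fig2_timeline, configs):
        track = run_criteria(fig2_timeline, configs[Criterion.RANO])
        assert track.call.progressed and track.call.progression_day == 206
        labels = {a.scan_day: a.label for a in track.assessments}
        assert labels[206] is Label.PD

    def test_rano2_pd_at_second_followup_without_confirmation(self, fig2_timeline, configs):
        track = run_criteria(fig2_timeline, configs[Criterion.RANO2])
        assert track.call.progressed and track.call.progression_day == 206
        assert track.call.confirmed_day is None  # beyond the 12-week guard

    def test_mrano_psp_then_pd_at_fifth_followup(self, fig2_timeline, configs):
        track = run_criteria(fig2_timeline, configs[Criterion.MRANO])
        labels = {a.scan_day: a.label for a in track.assessments}
        assert labels[206] is Label.PSP
        assert labels[297] is Label.SD
        assert labels[388] is Label.SD
        assert labels[479] is Label.PD
        assert track.call.progression_day == 479
        assert track.call.confirmed_day == 570


class TestRunCriteria:
    def test_monotone_shrinkage_censors_at_last_scan(self, configs):
        scans = tuple(scan(d, [ce("a", v), ne("n", 5.0)])
                      for d, v in [(8, 4.0), (115, 3.0), (206, 2.0), (297, 1.5)])
        t = PatientTimeline("p1", 7, 45, 87, scans, 400, True)
        for cfg in configs.values():
            track = run_criteria(t, cfg)
            assert not track.call.progressed
            assert track.call.censor_day == 297
            assert track.call.reason is CallReason.CENSORED_SD_LAST_SCAN

    def test_guarded_candidate_at_last_scan_stays_preliminary(self, configs):
        # suspicion inside the 12-week guard with no later scan: censored
        scans = (scan(8, [ce("a", 2.0)]), scan(110, [ce("a", 4.0)]))
        t = PatientTimeline("p2", 7, 45, 87, scans, 140, True)
        track = run_criteria(t, configs[Criterion.RANO])
        assert track.assessments[-1].label is Label.PPD
        assert not track.call.progressed

    def test_determinism(self, fig2_timeline, configs):
        for cfg in configs.values():
            assert run_criteria(fig2_timeline, cfg) == run_criteria(fig2_timeline, cfg)

    def test_lesion_order_invariance(self, fig2_timeline, configs):
        rng = np.random.default_rng(0)
        shuffled_scans = []
        for s in fig2_timeline.scans:
            lesions = list(s.lesions)
            rng.shuffle(lesions)
            shuffled_scans.append(dataclasses.replace(s, lesions=tuple(lesions)))
        shuffled = dataclasses.replace(fig2_timeline, scans=tuple(shuffled_scans))
        for cfg in configs.values():
            assert run_criteria(shuffled, cfg) == run_criteria(fig2_timeline, cfg)

    def test_nadir_is_non_increasing_between_resets(self, small_cohort, configs):
        timelines, _ = small_cohort
        for t in timelines:
            for cfg in configs.values():
                track = run_criteria(t, cfg)
                prev = None
                for a in track.assessments:
                    if a.trigger is Trigger.RETRO_PSP:
                        prev = None  # reference restarts after refuted suspicion
                        continue
                    if prev is not None:
                        assert a.reference_nadir_cm3 <= prev + 1e-12
                    prev = a.reference_nadir_cm3


class TestNonImagingEvents:
    def _timeline(self, scan_days, reresection=None, bev=None):
        scans = tuple(scan(d, [ce("a", 2.0)]) for d in scan_days)
        return PatientTimeline("p", 7, 45, 87, scans, 600, True,
                               reresection_day=reresection, bevacizumab_start_day=bev)

    def _censored(self, day):
        return ProgressionCall("p", Criterion.RANO, False, censor_day=day,
                               reason=CallReason.CENSORED_SD_LAST_SCAN)

    def test_reresection_backdates_to_last_prior_scan(self):
        t = self._timeline([8, 115, 372], reresection=400)
        call = apply_nonimaging_events(self._censored(372), t)
        assert call.progressed and call.progression_day == 372
        assert call.reason is CallReason.RERESECTION

    def test_earlier_imaging_pd_is_never_overridden(self):
        t = self._timeline([8, 115, 300], bev=350)
        pd_call = ProgressionCall("p", Criterion.RANO, True, progression_day=300,
                                  reason=CallReason.IMAGING_PD)
        assert apply_nonimaging_events(pd_call, t) == pd_call

    def test_bevacizumab_uses_last_scan_before_start(self):
        t = self._timeline([100, 200, 480], bev=500)
        call = apply_nonimaging_events(self._censored(480), t)
        assert call.progression_day == 480
        assert call.reason is CallReason.BEVACIZUMAB

    def test_event_before_all_scans_is_invalid(self):
        t = self._timeline([100, 200], reresection=50)
        with pytest.raises(ValueError):
            apply_nonimaging_events(self._censored(200), t)


class TestPsPSummary:
    def test_no_psp(self, fig2_timeline, configs):
        track = run_criteria(fig2_timeline, configs[Criterion.RANO2])
        s = detect_psp_events([track], {"GB-0110": 87})
        assert s.count == 0 and s.rate == 0.0 and s.median_weeks is None

    def test_psp_week_arithmetic(self, fig2_timeline, configs):
        # mRANO relabels day 206 as PsP: (206 - 87) / 7 = 17 weeks after RT
        track = run_criteria(fig2_timeline, configs[Criterion.MRANO])
        s = detect_psp_events([track], {"GB-0110": 87})
        assert s.count == 1
        assert s.median_weeks == pytest.approx((206 - 87) / 7)
        assert s.within_12_weeks == 0

    def test_134_days_is_19_point_14_weeks(self, configs):
        scans = (scan(8, []), scan(115, []),
                 scan(87 + 134, [ce("bump", 1.5, new=True)]),
                 scan(87 + 134 + 60, []))
        t = PatientTimeline("p", 7, 45, 87, scans, 400, True)
        track = run_criteria(t, configs[Criterion.MRANO])
        s = detect_psp_events([track], {"p": 87})
        assert s.median_weeks == pytest.approx(19.142857, abs=1e-6)
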