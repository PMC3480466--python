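import math
from datetime import datetime, timedelta

import numpy as np
import pytest

from somnapose import Recording, Thresholds, summarize_night
from somnapose.indices import (
    detect_supine_episodes,
    posture_change_stats,
    rises,
    sleep_efficiency_turning,
    still_position_latency,
    time_supine,
    total_sleep_time,
    _segments_for_episodes,
)
from tests.conftest import NIGHT_T0, build_windows, repeat

W = 5.0  # window seconds
PER_MIN = 12
PER_HOUR = 720


def lying(n, angle=180.0, activity=0.01):
    return repeat("lying", angle, activity, n)


def sitting(n, activity=0.05):
    return repeat("sitting", None, activity, n)


def upright(n, activity=0.3):
    return repeat("upright", None, activity, n)


class TestDetectSupineEpisodes:
    def test_forty_five_seconds_no_episode(self, thresholds):
        labeled = build_windows(lying(9))
        assert detect_supine_episodes(labeled, thresholds) == []

    def test_fifty_seconds_one_episode(self, thresholds):
        labeled = build_windows(lying(10))
        eps = detect_supine_episodes(labeled, thresholds)
        assert len(eps) == 1
        assert eps[0].duration_s == pytest.approx(50.0)

    def test_sitting_break_excluded_from_supine(self, thresholds):
        # lying 4 h, sitting 10 min, lying 3 h -> time supine 7.0 h
        labeled = build_windows(
            lying(4 * PER_HOUR) + sitting(10 * PER_MIN) + lying(3 * PER_HOUR)
        )
        eps = detect_supine_episodes(labeled, thresholds)
        assert len(eps) == 2
        assert time_supine(eps) == pytest.approx(7.0)
        assert eps[0].interrupting_nonlying_s == pytest.approx(600.0)
        span = (eps[-1].end - eps[0].start).total_seconds() / 3600
        assert span == pytest.approx(7.0 + 10 / 60)

    def test_long_absence_ends_span(self, thresholds):
        labeled = build_windows(
            lying(2 * PER_HOUR) + upright(40 * PER_MIN) + lying(2 * PER_HOUR)
        )
        eps = detect_supine_episodes(labeled, thresholds)
        assert len(eps) == 1  # 40 min > max_rise_min ends the in-bed span
        assert time_supine(eps) == pytest.approx(2.0)

    def test_empty_input(self, thresholds):
        assert detect_supine_episodes([], thresholds) == []
        assert time_supine([]) == 0.0


class TestTotalSleepTime:
    def test_all_quiet_equals_time_supine(self, thresholds):
        labeled = build_windows(lying(PER_HOUR, activity=0.01))
        eps = detect_supine_episodes(labeled, thresholds)
        assert total_sleep_time(eps, labeled, thresholds) == pytest.approx(1.0)

    def test_half_active(self, thresholds):
        entries = lying(PER_HOUR, activity=0.01) + lying(PER_HOUR, activity=0.2)
        labeled = build_windows(entries)
        eps = detect_supine_episodes(labeled, thresholds)
        assert total_sleep_time(eps, labeled, thresholds) == pytest.approx(
            time_supine(eps) / 2
        )

    def test_boundary_excluded_strict(self, thresholds):
        labeled = build_windows(lying(PER_HOUR, activity=0.15))
        eps = detect_supine_episodes(labeled, thresholds)
        assert total_sleep_time(eps, labeled, thresholds) == 0.0


class TestStillPositionLatency:
    def test_quiet_from_onset(self, thresholds):
        labeled = build_windows(lying(PER_HOUR, activity=0.01))
        eps = detect_supine_episodes(labeled, thresholds)
        res = still_position_latency(eps, labeled, thresholds)
        assert res.minutes == pytest.approx(0.0)
        assert res.sustained_found

    def test_four_minutes_active_then_quiet(self, thresholds):
        entries = lying(4 * PER_MIN, activity=0.3) + lying(10 * PER_MIN, activity=0.01)
        labeled = build_windows(entries)
        eps = detect_supine_episodes(labeled, thresholds)
        res = still_position_latency(eps, labeled, thresholds)
        assert res.minutes == pytest.approx(4.0)
        assert res.sustained_found

    def test_no_sustained_run_flagged(self, thresholds):
        # 2-min quiet runs separated by active windows: never >= 3 min
        cell = lying(2 * PER_MIN, activity=0.01) + lying(1 * PER_MIN, activity=0.3)
        labeled = build_windows(cell * 20)
        eps = detect_supine_episodes(labeled, thresholds)
        res = still_position_latency(eps, labeled, thresholds)
        assert not res.sustained_found
        assert res.minutes == pytest.approx(time_supine(eps) * 60.0)

    def test_run_not_broken_across_episodes(self, thresholds):
        # quiet 2 min, rise, quiet 2 min: no single 3-min run
        entries = (
            lying(2 * PER_MIN, activity=0.01)
            + upright(2 * PER_MIN)
            + lying(2 * PER_MIN, activity=0.01)
        )
        labeled = build_windows(entries)
        eps = detect_supine_episodes(labeled, thresholds)
        assert not still_position_latency(eps, labeled, thresholds).sustained_found


class TestRises:
    def test_single_rise(self, thresholds):
        entries = lying(PER_HOUR) + upright(2 * PER_MIN) + lying(PER_HOUR)
        labeled = build_windows(entries)
        eps = detect_supine_episodes(labeled, thresholds)
        r = rises(labeled, eps, thresholds)
        assert r.total == 1
        assert r.first_hour == 0  # rise starts exactly at 60 min

    def test_no_rises(self, thresholds):
        labeled = build_windows(lying(PER_HOUR))
        eps = detect_supine_episodes(labeled, thresholds)
        r = rises(labeled, eps, thresholds)
        assert (r.total, r.first_hour) == (0, 0)

    def test_three_rises_rate(self, thresholds):
        # 7.5 h supine with 3 interruptions -> 0.4 rises per hour
        chunk = int(7.5 * PER_HOUR / 4)
        entries = (
            lying(chunk)
            + upright(PER_MIN)
            + lying(chunk)
            + upright(PER_MIN)
            + lying(chunk)
            + upright(PER_MIN)
            + lying(int(7.5 * PER_HOUR) - 3 * chunk)
        )
        labeled = build_windows(entries)
        eps = detect_supine_episodes(labeled, thresholds)
        assert time_supine(eps) == pytest.approx(7.5)
        r = rises(labeled, eps, thresholds)
        assert r.total == 3
        assert r.per_hour == pytest.approx(0.4)

    def test_first_hour_count(self, thresholds):
        entries = (
            lying(20 * PER_MIN)
            + upright(2 * PER_MIN)
            + lying(20 * PER_MIN)
            + upright(2 * PER_MIN)
            + lying(2 * PER_HOUR)
        )
        labeled = build_windows(entries)
        eps = detect_supine_episodes(labeled, thresholds)
        r = rises(labeled, eps, thresholds)
        assert r.total == 2
        assert r.first_hour == 2


class TestPostureChangeStats:
    def test_single_eight_hour_dorsal_segment(self, thresholds):
        labeled = build_windows(lying(8 * PER_HOUR, angle=180.0))
        eps = detect_supine_episodes(labeled, thresholds)
        segs = _segments_for_episodes(eps, labeled, thresholds)
        pcs = posture_change_stats(segs, eps, rises_total=0, thresholds=thresholds)
        assert pcs.changes_per_hour == pytest.approx(0.0)
        assert pcs.mean_duration_min == pytest.approx(480.0)
        assert pcs.gt15_per_hour == pytest.approx(1 / 8)
        assert pcs.fractions["dorsal"] == pytest.approx(1.0)
        assert pcs.first_posture == "dorsal"

    def test_turns_and_rises_counted(self, thresholds):
        # two 90-deg turns + one rise over 3 h supine -> 1 change per hour
        entries = (
            lying(PER_HOUR, angle=180.0)
            + lying(PER_HOUR, angle=90.0)
            + upright(2 * PER_MIN)
            + lying(PER_HOUR, angle=0.0)
        )
        labeled = build_windows(entries)
        eps = detect_supine_episodes(labeled, thresholds)
        segs = _segments_for_episodes(eps, labeled, thresholds)
        r = rises(labeled, eps, thresholds)
        pcs = posture_change_stats(segs, eps, r.total, thresholds)
        assert pcs.n_boundaries == 1  # the 180->90 turn inside episode 1
        assert r.total == 1
        assert pcs.changes_per_hour == pytest.approx((1 + 1) / 3.0)
        assert pcs.fractions["dorsal"] == pytest.approx(1 / 3)
        assert sum(pcs.fractions.values()) == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, thresholds):
        rng = np.random.default_rng(0)
        entries = []
        for angle in rng.choice([0.0, 90.0, 180.0, -90.0], size=12):
            entries += lying(int(rng.integers(10, 80)), angle=float(angle))
        labeled = build_windows(entries)
        eps = detect_supine_episodes(labeled, thresholds)
        segs = _segments_for_episodes(eps, labeled, thresholds)
        pcs = posture_change_stats(segs, eps, 0, thresholds)
        assert sum(pcs.fractions.values()) == pytest.approx(1.0)


class TestSleepEfficiency:
    def test_no_turns_no_rises_is_one(self, thresholds):
        labeled = build_windows(lying(8 * PER_HOUR))
        eps = detect_supine_episodes(labeled, thresholds)
        segs = _segments_for_episodes(eps, labeled, thresholds)
        eff_span, eff_supine = sleep_efficiency_turning(segs, eps, labeled, thresholds)
        assert eff_span == pytest.approx(1.0)
        assert eff_supine == pytest.approx(1.0)

    def test_thirty_minutes_of_rises(self, thresholds):
        # 8 h supine + 30 min risen inside the span -> 8.0 / 8.5
        entries = (
            lying(4 * PER_HOUR)
            + upright(30 * PER_MIN)
            + lying(4 * PER_HOUR)
        )
        labeled = build_windows(entries)
        eps = detect_supine_episodes(labeled, thresholds)
        segs = _segments_for_episodes(eps, labeled, thresholds)
        eff_span, eff_supine = sleep_efficiency_turning(segs, eps, labeled, thresholds)
        assert eff_span == pytest.approx(8.0 / 8.5)
        assert eff_supine == pytest.approx(1.0)

    def test_turn_charges_boundary_window(self, thresholds):
        entries = lying(PER_HOUR, angle=0.0) + lying(PER_HOUR, angle=90.0)
        labeled = build_windows(entries)
        eps = detect_supine_episodes(labeled, thresholds)
        segs = _segments_for_episodes(eps, labeled, thresholds)
        eff_span, _ = sleep_efficiency_turning(segs, eps, labeled, thresholds)
        assert eff_span == pytest.approx((7200 - 5) / 7200)

    def test_adjacent_active_windows_charged(self, thresholds):
        entries = (
            lying(PER_HOUR - 2, angle=0.0)
            + lying(2, angle=0.0, activity=0.3)  # restless just before the turn
            + lying(PER_HOUR, angle=90.0)
        )
        labeled = build_windows(entries)
        eps = detect_supine_episodes(labeled, thresholds)
        segs = _segments_for_episodes(eps, labeled, thresholds)
        eff_span, _ = sleep_efficiency_turning(segs, eps, labeled, thresholds)
        assert eff_span == pytest.approx((7200 - 15) / 7200)


class TestSummarizeNight:
    def quiet_supine_recording(self, hours=1.0, rate=16.0):
        n = int(hours * 3600 * rate)
        data = np.tile([0.0, -1.0, 0.0, -1.0], (n, 1))
        return Recording("s", NIGHT_T0, rate, data)

    def test_quiet_night(self, thresholds):
        s = summarize_night(self.quiet_supine_recording(), thresholds)
        assert s.time_supine_h == pytest.approx(1.0)
        assert s.total_sleep_time_h == pytest.approx(1.0)
        assert s.sleep_efficiency == pytest.approx(1.0)
        assert s.rises_total == 0
        assert s.first_posture == "dorsal"
        assert s.posture_fractions["dorsal"] == pytest.approx(1.0)
        assert s.still_position_latency_min == pytest.approx(0.0)

    def test_empty_night_flags_rates_missing(self, thresholds):
        # upright the whole time: no supine episode
        n = int(1800 * 16)
        data = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
        rec = Recording("s", NIGHT_T0, 16.0, data)
        s = summarize_night(rec, thresholds)
        assert s.time_supine_h == 0.0
        assert s.total_sleep_time_h == 0.0
        assert math.isnan(s.rises_per_hour)
        assert math.isnan(s.posture_changes_per_hour)
        assert s.posture_fractions is None
        assert s.first_posture is None

    def test_conservation_invariants(self, thresholds):
        s = summarize_night(self.quiet_supine_recording(hours=2), thresholds)
        assert s.total_sleep_time_h <= s.time_supine_h <= s.in_bed_span_h

    def test_night_gating_invariance(self, thresholds):
        """Prepending/appending data outside 20:00-10:00 changes nothing."""
        rate = 16.0
        night = np.tile([0.0, -1.0, 0.0, -1.0], (int(3600 * rate), 1))
        rec_a = Recording("s", NIGHT_T0, rate, night)
        # same physical night, but recording starts at 18:00 with upright data
        pre = np.tile([1.0, 0.0, 0.0, 0.0], (int(4 * 3600 * rate), 1))
        post = np.tile([1.0, 0.0, 0.0, 0.0], (int(3600 * rate), 1))
        early = datetime(2024, 3, 1, 18, 0, 0)
        rec_b = Recording("s", early, rate, np.concatenate([pre, night, post]))
        sa = summarize_night(rec_a, thresholds)
        sb = summarize_night(rec_b, thresholds)
        assert sa.time_supine_h == pytest.approx(sb.time_supine_h)
        assert sa.total_sleep_time_h == pytest.approx(sb.total_sleep_time_h)
        assert sa.rises_total == sb.rises_total

    def test_sampling_rate_robustness(self, thresholds):
        """Doubling the sampling rate of the same physical scenario moves
        no duration index by more than one window."""
        from somnapose.synth import NightScenario, simulate_night

        base = dict(
            seed=1,
            bedtime="22:00",
            latency_min=5.0,
            posture_schedule=(("dorsal", 60.0), ("left", 60.0)),
            sensor_noise_sd_g=0.0,
        )
        rec16, _ = simulate_night(NightScenario(sampling_rate=16.0, **base))
        rec32, _ = simulate_night(NightScenario(sampling_rate=32.0, **base))
        s16 = summarize_night(rec16, thresholds)
        s32 = summarize_night(rec32, thresholds)
        for attr in ("time_supine_h", "total_sleep_time_h"):
            assert abs(getattr(s16, attr) - getattr(s32, attr)) * 3600 <= 5.0
        assert abs(s16.still_position_latency_min - s32.still_position_latency_min) <= 5 / 60
        assert s16.rises_total == s32.rises_total
        assert s16.posture_changes_per_hour == pytest.approx(s32.posture_changes_per_hour)
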