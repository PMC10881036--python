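"""PE detection, burst construction, periodicity rules, antennal angles."""

import numpy as np
import pandas as pd
import pytest

from flysleep import SessionConfig, generate_session
from flysleep.intervals import Bout, BoutSet, segment_sleep_epochs
from flysleep.microbehavior import (antennal_angle, construct_pe_events,
                                    dist_eyeprob, filter_pose, match_events,
                                    pe_statistics, periodicity_segments,
                                    resting_pe_detection, threshold_pe_events)


def _pose(n=3000, fps=30.0, seed=0):
    rng = np.random.default_rng(seed)
    cols = {}
    for part in ("proboscis", "eye"):
        cols[f"{part}_x"] = rng.normal(40, 0.1, n)
        cols[f"{part}_y"] = rng.normal(30, 0.1, n)
        cols[f"{part}_likelihood"] = np.full(n, 0.95)
    return pd.DataFrame(cols)


class TestFilterPose:
    def test_constant_trace_unchanged(self):
        p = _pose()
        p["proboscis_x"] = 5.0
        f = filter_pose(p, 30.0)
        assert np.allclose(f["proboscis_x_lp"], 5.0, atol=1e-6)
        assert np.allclose(f["proboscis_x_ma"], 5.0, atol=1e-6)

    def test_moving_average_arithmetic(self):
        x = np.zeros(5)
        x[2] = 5.0
        assert np.convolve(x, np.ones(5) / 5, "same")[2] == pytest.approx(1.0)

    def test_2hz_attenuated_by_lowpass(self):
        fps = 30.0
        n = 3000
        t = np.arange(n) / fps
        p = _pose(n)
        p["proboscis_x"] = 40 + np.sin(2 * np.pi * 2.0 * t)
        f = filter_pose(p, fps)
        osc = f["proboscis_x_lp"] - f["proboscis_x_lp"].mean()
        atten = 20 * np.log10(np.std(osc[300:-300]) / (1 / np.sqrt(2)))
        assert atten < -20.0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            filter_pose(_pose(10), 30.0)


class TestDistEyeprob:
    def test_three_four_five(self):
        p = pd.DataFrame({"eye_x": [0.0], "eye_y": [0.0],
                          "eye_likelihood": [1.0],
                          "proboscis_x": [3.0], "proboscis_y": [4.0],
                          "proboscis_likelihood": [0.5]})
        assert dist_eyeprob(p)[0] == pytest.approx(2.5)

    def test_zero_likelihood_and_coincident(self):
        p = pd.DataFrame({"eye_x": [0.0, 1.0], "eye_y": [0.0, 1.0],
                          "eye_likelihood": [1.0, 1.0],
                          "proboscis_x": [3.0, 1.0],
                          "proboscis_y": [4.0, 1.0],
                          "proboscis_likelihood": [0.0, 1.0]})
        assert np.allclose(dist_eyeprob(p), [0.0, 0.0])

    def test_missing_part_rejected(self):
        with pytest.raises(ValueError):
            dist_eyeprob(pd.DataFrame({"eye_x": [0.0]}))


def _pose_with_pulses(times, n=6000, fps=30.0, amp=8.0):
    p = _pose(n)
    disp = np.zeros(n)
    for t in times:
        c = int(t * fps)
        half = 6
        w = amp * 0.5 * (1 + np.cos(np.linspace(-np.pi, np.pi, 2 * half + 1)))
        a, b = c - half, c + half + 1
        disp[a:b] = np.maximum(disp[a:b], w)
    p["proboscis_x"] = p["proboscis_x"] + disp / np.sqrt(2)
    p["proboscis_y"] = p["proboscis_y"] + disp / np.sqrt(2)
    return p


class TestEventConstruction:
    def test_ten_second_burst_rule(self):
        fps = 30.0
        p = _pose_with_pulses([10.0, 30.0])
        cand = np.zeros(len(p), bool)
        for t in (10.0, 30.0):
            cand[int((t - 0.2) * fps):int((t + 0.2) * fps)] = True
        events, bursts = construct_pe_events(cand, p, fps)
        assert len(events) == 2
        assert len(bursts) == 2
        assert all(b.is_single for b in bursts)

    def test_regular_burst_intervals(self):
        fps = 30.0
        p = _pose_with_pulses([10.0, 11.5, 13.0])
        cand = np.zeros(len(p), bool)
        for t in (10.0, 11.5, 13.0):
            cand[int((t - 0.2) * fps):int((t + 0.2) * fps)] = True
        events, bursts = construct_pe_events(cand, p, fps)
        assert len(bursts) == 1
        assert np.allclose(bursts[0].inter_pe_intervals, [1.5, 1.5],
                           atol=0.15)

    def test_state_tagging(self):
        fps = 30.0
        bouts = BoutSet([Bout(0.0, 60.0, "awake", True),
                         Bout(60.0, 400.0, "sleep", True),
                         Bout(400.0, 500.0, "awake", True)], 500.0, 8 * 3600.0)
        stages = segment_sleep_epochs(bouts)
        p = _pose_with_pulses([250.0], n=15000)
        cand = np.zeros(len(p), bool)
        cand[int(249.8 * fps):int(250.2 * fps)] = True
        events, _ = construct_pe_events(cand, p, fps, stages)
        assert events[0].state == "sleep"

    def test_empty_candidates(self):
        events, bursts = construct_pe_events(np.zeros(100, bool), _pose(100),
                                             30.0)
        assert events == [] and bursts == []


class TestPeriodicFlags:
    def test_printed_rule_sequence(self):
        """Events at 0, 2, 4, 12 s: the 8-s gap breaks periodicity; the
        first event follows the successor convention."""
        fps = 30.0
        times = [1.0, 3.0, 5.0, 13.0]
        p = _pose_with_pulses(times, n=600)
        cand = np.zeros(len(p), bool)
        for t in times:
            cand[int((t - 0.15) * fps):int((t + 0.15) * fps)] = True
        events, _ = construct_pe_events(cand, p, fps)
        assert [e.periodic for e in events] == [True, True, True, False]


class TestPEStatistics:
    def test_single_event(self):
        fps = 30.0
        p = _pose_with_pulses([10.0], n=900)
        cand = np.zeros(len(p), bool)
        cand[int(9.8 * fps):int(10.2 * fps)] = True
        events, bursts = construct_pe_events(cand, p, fps)
        st = pe_statistics(events, bursts)
        assert st["n_single"] == 1
        assert st["inter_pe_intervals"].size == 0

    def test_segment_normalization_sums_to_one(self):
        cfg = SessionConfig(duration=1800.0, seed=8, sleep_bout_rate=3.0,
                            with_lfp=False)
        s = generate_session(cfg)
        from flysleep.microbehavior import PEEvent
        events = [PEEvent(int(t * 30), t, "sleep", i)
                  for i, t in enumerate(s.truth.pe_events.time_s)]
        st = pe_statistics(events, [], s.truth.stages)
        total = sum(st["segment_normalized"].values())
        if sum(st["segment_counts"].values()):
            assert total == pytest.approx(1.0)

    def test_midsleep_events_dominate(self):
        """Bursts are placed mostly in midsleep; the normalized midsleep
        count exceeds every flanking segment."""
        counts = None
        for seed in (8, 9, 10):
            cfg = SessionConfig(duration=3600.0, seed=seed,
                                sleep_bout_rate=3.0, with_lfp=False,
                                with_pose=False)
            s = generate_session(cfg)
            from flysleep.microbehavior import PEEvent
            events = [PEEvent(int(t * 30), t, st_, i) for i, (t, st_) in
                      enumerate(zip(s.truth.pe_events.time_s,
                                    s.truth.pe_events.state))]
            st = pe_statistics(events, [], s.truth.stages)
            c = st["segment_normalized"]
            counts = c if counts is None else {
                k: counts[k] + c[k] for k in c}
        for seg in ("-2:-1", "-1:0", "+0:+1", "+1:+2", "x-2:x-1", "x-1:x"):
            assert counts["mid"] > counts[seg]


class TestAntennalAngle:
    def _pose(self, tip_angle_deg, head_rot_deg=0.0, n=10):
        th = np.deg2rad(head_rot_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        lb = R @ np.array([28.0, 10.0])
        rb = R @ np.array([52.0, 10.0])
        a = np.deg2rad(tip_angle_deg) + th
        lt = lb + 8.0 * np.array([np.cos(a), np.sin(a)])
        cols = {}
        for name, (x, y) in {"left_antenna_base": lb, "right_antenna_base": rb,
                             "left_antenna_tip": lt,
                             "right_antenna_tip": rb + [0.0, 8.0]}.items():
            cols[f"{name}_x"] = np.full(n, x)
            cols[f"{name}_y"] = np.full(n, y)
            cols[f"{name}_likelihood"] = np.full(n, 0.95)
        return pd.DataFrame(cols)

    def test_north_tip_is_90deg(self):
        ang = antennal_angle(self._pose(90.0), "left")
        assert np.allclose(ang, 90.0, atol=1e-9)

    def test_head_rotation_invariance(self):
        a0 = antennal_angle(self._pose(60.0, 0.0), "left")
        a1 = antennal_angle(self._pose(60.0, 10.0), "left")
        assert np.allclose(a0, a1, atol=1e-9)

    def test_coincident_base_tip_nan(self):
        p = self._pose(90.0)
        p["left_antenna_tip_x"] = p["left_antenna_base_x"]
        p["left_antenna_tip_y"] = p["left_antenna_base_y"]
        assert np.isnan(antennal_angle(p, "left")).all()

    def test_generator_angle_recovery(self):
        cfg = SessionConfig(duration=300.0, seed=2, with_lfp=False,
                            sleep_bout_rate=0.0)
        s = generate_session(cfg)
        ang = antennal_angle(s.pose, "left")
        assert np.isfinite(ang).mean() > 0.99


class TestPeriodicitySegments:
    def test_pure_sine_periodic(self):
        fps = 30.0
        t = np.arange(0, 60, 1 / fps)
        ang = 10 * np.sin(2 * np.pi * 1.0 * t)
        res = periodicity_segments(ang, fps, segment_s=30.0)
        assert res.periodic.all()
        assert np.allclose(res.dominant_freq, 1.0, atol=0.05)

    def test_white_noise_rarely_periodic(self):
        rng = np.random.default_rng(0)
        flags = []
        for _ in range(60):
            ang = rng.normal(size=900)
            res = periodicity_segments(ang, 30.0, segment_s=30.0)
            flags.extend(res.periodic.tolist())
        assert np.mean(flags) <= 0.05 + 2.5 * np.sqrt(0.05 / len(flags))

    def test_sleep_fraction_exceeds_wake(self):
        cfg = SessionConfig(duration=3600.0, seed=6, sleep_bout_rate=3.0,
                            with_lfp=False)
        s = generate_session(cfg)
        ang = antennal_angle(s.pose, "left")
        res = periodicity_segments(ang, s.fps, bouts=s.truth.bouts)
        assert res.fraction_sleep > res.fraction_wake

    def test_segment_too_short_rejected(self):
        with pytest.raises(ValueError):
            periodicity_segments(np.zeros(1000), 30.0, segment_s=5.0,
                                 min_freq=0.2)


class TestRestingDetection:
    def test_constant_trace_no_events(self):
        assert len(resting_pe_detection(_pose(600), 30.0)) == 0

    def test_single_frame_spike_excluded(self):
        p = _pose(600)
        p.loc[300, "proboscis_x"] = 60.0
        assert len(resting_pe_detection(p, 30.0)) == 0

    def test_smooth_extension_retained(self):
        p = _pose_with_pulses([10.0], n=900)
        df = resting_pe_detection(p, 30.0)
        assert len(df) == 1
        assert abs(df.time_s.iloc[0] - 10.0) < 0.2

    def test_threshold_detector_duration(self):
        p = _pose_with_pulses([10.0], n=900)
        df = threshold_pe_events(p, 30.0, threshold=3.0)
        assert len(df) == 1
        assert 0.05 < df.duration_s.iloc[0] < 0.6


class TestMatchEvents:
    def test_perfect_and_partial(self):
        m = match_events([1.0, 2.0], [1.0, 2.0])
        assert m["accuracy"] == 1.0
        m2 = match_events([1.0, 5.0], [1.0, 2.0])
        assert m2 == {"tp": 1, "fn": 1, "fp": 1, "accuracy": 1 / 3}


def test_event_recovery_on_generator():
    """Detected PE count within +-10% of truth, peaks within 2 frames."""
    from flysleep.microbehavior import detect_pe_frames, truth_pe_frame_mask
    cfg = SessionConfig(duration=1200.0, seed=202, with_lfp=False,
                        sleep_bout_rate=3.0)
    s = generate_session(cfg)
    truth_t = s.truth.pe_events.time_s.to_numpy()
    mask = truth_pe_frame_mask(len(s.pose), s.fps, truth_t)
    det = detect_pe_frames(s.pose, mask, s.fps, seed=0)
    events, _ = construct_pe_events(det.candidate_frames, s.pose, s.fps,
                                    s.truth.stages)
    assert abs(len(events) - len(truth_t)) <= max(0.1 * len(truth_t), 1)
    det_t = np.array([e.time_s for e in events])
    for t in truth_t:
        assert np.min(np.abs(det_t - t)) <= 2.5 / s.fps
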