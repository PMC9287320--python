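"""Activity-mask segmentation and daily-life features."""

from __future__ import annotations

import numpy as np
import pytest

from pdsense.passive_monitoring import (ActivityMask, arm_movement_power,
                                        daily_turn_speed, detect_gait_bouts,
                                        wear_time)
from pdsense.motion_features import detect_turns
from pdsense.session_model import InertialStream
from pdsense.synthetic_cohort import (synth_passive_phone_day,
                                      synth_passive_watch_day)

FS = 20.0
G = np.array([0.0, 0.0, 9.81])


def idle_stream(duration, rng, noise=0.03, fs=FS):
    t = np.arange(0.0, duration, 1 / fs)
    acc = G + rng.normal(0, noise, (len(t), 3))
    return InertialStream(t=t, acc=acc, gyro=rng.normal(0, 0.004, (len(t), 3)),
                          fs_nominal=fs)


class TestGaitDetection:
    def test_injected_walking_bursts_recovered(self, rng):
        """Jaccard overlap between detected gait and injected bursts >= 0.9."""
        t = np.arange(0.0, 1800.0, 1 / FS)
        acc = G + rng.normal(0, 0.03, (len(t), 3))
        truth = np.zeros(len(t), dtype=bool)
        for start in np.arange(120.0, 1500.0, 300.0):     # 5 bursts of 2 min
            sel = (t >= start) & (t < start + 120.0)
            acc[sel] += np.outer(2.4 * np.sin(2 * np.pi * 2.0 * (t[sel] - start)),
                                 [0.3, 0.2, 1.0])
            truth |= sel
        s = InertialStream(t=t, acc=acc, gyro=np.zeros((len(t), 3)), fs_nominal=FS)
        mask = detect_gait_bouts(s)
        detected = np.zeros(len(t), dtype=bool)
        for a, b in mask.of("gait"):
            detected |= (t >= a) & (t <= b)
        jac = (detected & truth).sum() / max((detected | truth).sum(), 1)
        assert jac >= 0.9

    def test_all_idle_stream_has_zero_gait(self, rng):
        mask = detect_gait_bouts(idle_stream(600.0, rng))
        assert mask.duration("gait") == 0.0

    def test_flat_stream_is_fully_off_body(self, rng):
        s = idle_stream(600.0, rng, noise=0.0005)
        mask = detect_gait_bouts(s)
        assert mask.duration("off_body") == pytest.approx(s.duration, rel=0.02)

    def test_labels_partition_recorded_time(self, rng):
        stream, _ = synth_passive_phone_day(6.0, FS, 1.5, rng)
        mask = detect_gait_bouts(stream)
        assert mask.duration() == pytest.approx(stream.duration, abs=1e-9)
        # intervals are ordered and non-overlapping
        for (s0, e0, _), (s1, e1, _) in zip(mask.intervals, mask.intervals[1:]):
            assert e0 <= s1 + 1e-12


class TestDailyTurnSpeed:
    def test_injected_turns_recovered(self, rng):
        stream, speeds = synth_passive_phone_day(8.0, FS, np.pi / 2, rng)
        mask = detect_gait_bouts(stream)
        out = daily_turn_speed(stream, mask)
        assert out.value == pytest.approx(np.pi / 2, rel=0.06)

    def test_gait_without_turning_is_undefined(self, rng):
        t = np.arange(0.0, 300.0, 1 / FS)
        acc = G + rng.normal(0, 0.03, (len(t), 3)) + \
            np.outer(2.4 * np.sin(2 * np.pi * 2.0 * t), [0.3, 0.2, 1.0])
        s = InertialStream(t=t, acc=acc, gyro=rng.normal(0, 0.01, (len(t), 3)),
                           fs_nominal=FS)
        out = daily_turn_speed(s, detect_gait_bouts(s))
        assert out.value is None and out.flag == "no turns"

    def test_matches_uturn_detector_on_concatenated_gait(self, rng):
        """Shared-oracle equivalence with the active-test turn detector."""
        stream, _ = synth_passive_phone_day(8.0, FS, 1.4, rng)
        mask = detect_gait_bouts(stream)
        out = daily_turn_speed(stream, mask)
        speeds = []
        for a, b in mask.of("gait"):
            sel = (stream.t >= a) & (stream.t <= b)
            sub = InertialStream(t=stream.t[sel] - stream.t[sel][0],
                                 acc=stream.acc[sel], gyro=stream.gyro[sel],
                                 fs_nominal=FS)
            speeds.extend(ev.speed for ev in detect_turns(sub))
        assert out.value == pytest.approx(float(np.median(speeds)), rel=1e-9)


class TestArmMovementPower:
    def test_constant_magnitude_movement_integral(self):
        """0.5 s at a constant gravity-removed 2 m/s^2 -> integral 2.0."""
        fs = 50.0
        t = np.arange(0.0, 60.0, 1 / fs)
        acc = np.tile(G, (len(t), 1)).astype(float)
        sel = (t >= 30.0) & (t < 30.5)
        acc[sel, 0] += 2.0
        s = InertialStream(t=t, acc=acc, gyro=np.zeros((len(t), 3)), fs_nominal=fs)
        mask = ActivityMask([(0.0, float(t[-1]), "non_gait_movement")])
        out = arm_movement_power(s, mask)
        assert out.value == pytest.approx(2.0, rel=0.15)

    def test_median_of_two_movements(self):
        fs = 50.0
        t = np.arange(0.0, 120.0, 1 / fs)
        acc = np.tile(G, (len(t), 1)).astype(float)
        acc[(t >= 30.0) & (t < 30.5), 0] += 1.0       # power ~0.5
        acc[(t >= 80.0) & (t < 80.5), 1] += 2.0       # power ~2.0
        s = InertialStream(t=t, acc=acc, gyro=np.zeros((len(t), 3)), fs_nominal=fs)
        mask = ActivityMask([(0.0, float(t[-1]), "non_gait_movement")])
        out = arm_movement_power(s, mask)
        assert out.extras["n_movements"] == 2
        assert out.value == pytest.approx((0.5 + 2.0) / 2, rel=0.15)

    def test_movements_during_gait_excluded(self):
        fs = 50.0
        t = np.arange(0.0, 120.0, 1 / fs)
        acc = np.tile(G, (len(t), 1)).astype(float)
        acc[(t >= 30.0) & (t < 30.5), 0] += 1.0       # inside gait interval
        acc[(t >= 80.0) & (t < 80.5), 1] += 2.0       # inside non-gait interval
        s = InertialStream(t=t, acc=acc, gyro=np.zeros((len(t), 3)), fs_nominal=fs)
        mask = ActivityMask([(0.0, 60.0, "gait"),
                             (60.0, float(t[-1]), "non_gait_movement")])
        out = arm_movement_power(s, mask)
        assert out.extras["n_movements"] == 1
        assert out.value == pytest.approx(2.0, rel=0.15)

    def test_idle_time_does_not_change_median(self, rng):
        stream, powers = synth_passive_watch_day(4.0, FS, 2.0, rng)
        mask = detect_gait_bouts(stream)
        base = arm_movement_power(stream, mask)
        # append pure idle: same movements, longer day
        extra = idle_stream(300.0, rng)
        t2 = np.concatenate([stream.t, extra.t + stream.t[-1] + 1 / FS])
        acc2 = np.vstack([stream.acc, extra.acc])
        gyro2 = np.vstack([stream.gyro, extra.gyro])
        s2 = InertialStream(t=t2, acc=acc2, gyro=gyro2, fs_nominal=FS)
        out2 = arm_movement_power(s2, detect_gait_bouts(s2))
        assert out2.value == pytest.approx(base.value, rel=1e-6)

    def test_ground_truth_movements_recovered(self, rng):
        stream, powers = synth_passive_watch_day(5.0, FS, 2.0, rng)
        mask = detect_gait_bouts(stream)
        out = arm_movement_power(stream, mask)
        assert out.extras["n_movements"] >= 0.8 * len(powers)


class TestWearTime:
    def test_fully_on_body(self, rng):
        s = idle_stream(3600.0, rng)
        out = wear_time(s, detect_gait_bouts(s))
        assert out.value == pytest.approx(1.0, rel=0.01)

    def test_off_body_hour_subtracted(self, rng):
        """10 h recording with 1 h off-body -> 9 h (constructed mask)."""
        t = np.arange(0.0, 10.0 * 3600, 1.0)
        s = InertialStream(t=t, acc=np.tile(G, (len(t), 1)),
                           gyro=np.zeros((len(t), 3)), fs_nominal=1.0)
        mask = ActivityMask([(0.0, 9 * 3600.0, "idle"),
                             (9 * 3600.0, float(t[-1]), "off_body")])
        assert wear_time(s, mask).value == pytest.approx(9.0, rel=1e-3)

    def test_no_recording_is_zero(self):
        s = InertialStream(t=[], acc=np.zeros((0, 3)), gyro=np.zeros((0, 3)),
                           fs_nominal=FS)
        assert wear_time(s, ActivityMask([])).value == 0.0
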