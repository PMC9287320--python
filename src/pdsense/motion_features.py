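"""Active-test features from inertial (accelerometer + gyroscope) streams.

Four tests wear the phone differently and target different motor signs:

* **Hand Turning** (pronation/supination, phone in outstretched hand, 10 s per
  side): angular velocity is projected onto the dominant rotation axis, the
  projected signal is segmented into individual rotations at hysteresis-guarded
  zero crossings, and the feature is the *median* per-rotation mean speed
  (rad/s) over rotations exceeding a qualifying angle.  Slow turning indexes
  bradykinesia.
* **Rest / Postural Tremor** (15 s per hand): the acceleration is band-passed
  to the tremor band (default 3-12 Hz, covering the 3.5-7.5 Hz parkinsonian
  rest tremor and its first harmonic), and the feature is the natural log of
  the median squared magnitude — *log median squared energy*, a proxy for
  tremor amplitude.  Rest and postural tests share the computation; only the
  posture differs.
* **Balance** (30 s standing, phone at the waist): acceleration is low-passed
  to the postural-sway band (3.5 Hz), differentiated to jerk, and the feature
  is ``ln`` of the time-averaged squared jerk magnitude — *log sway jerk*.
* **U-turn** (60 s of short walks with >= 5 U-turns): yaw rate about the
  gravity axis is integrated, turns are detected as contiguous high-yaw-rate
  intervals accumulating at least a threshold angle, and the feature is the
  median per-turn speed (rad/s).

All features are invariant to a constant re-orientation of the sensor frame
(they use magnitudes or data-driven axes) and, through filtering, to the
constant gravity offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from ._util import FeatureOutcome, contiguous_runs, zero_phase_filter
from .config import MOTION, MotionConfig
from .session_model import InertialStream

__all__ = ["RotationSegment", "TurnEvent", "hand_turn_speed", "tremor_energy",
           "sway_jerk", "uturn_speed", "detect_turns"]


@dataclass
class RotationSegment:
    """One segmented hand rotation."""

    start_t: float
    end_t: float
    angle: float          # rad, absolute value of integrated rate

    @property
    def mean_speed(self) -> float:
        return self.angle / (self.end_t - self.start_t)


@dataclass
class TurnEvent:
    """One detected walking turn."""

    start_t: float
    end_t: float
    yaw_angle: float      # rad, signed

    @property
    def speed(self) -> float:
        return abs(self.yaw_angle) / (self.end_t - self.start_t)


# ---------------------------------------------------------------------------
# Hand turning
# ---------------------------------------------------------------------------

def _principal_axis(x: np.ndarray) -> np.ndarray:
    """First principal axis of 3-axis samples (uncentered second moment)."""
    m = x.T @ x
    w, v = np.linalg.eigh(m)
    return v[:, -1]


def segment_rotations(stream: InertialStream,
                      cfg: MotionConfig = MOTION) -> list[RotationSegment]:
    """Segment pronation/supination rotations from the gyroscope.

    The projected rate is high-passed (drift removal) and cut at zero
    crossings with +-hysteresis so sensor noise near zero does not fragment
    rotations.  Partial segments at the stream edges are kept only if they
    meet the qualifying angle like any other.
    """
    axis = _principal_axis(stream.gyro)
    w = stream.gyro @ axis
    w = zero_phase_filter(w, stream.fs, cfg.hand_turn_highpass_hz, "highpass",
                          cfg.filter_order)
    h = cfg.hand_turn_hysteresis_rad_s
    # state: +1 / -1 once |w| exceeds the hysteresis band, held in between
    state = np.zeros(len(w), dtype=np.int8)
    state[w > h] = 1
    state[w < -h] = -1
    # hold previous state through the dead band
    idx = np.arange(len(state))
    known = state != 0
    if not known.any():
        return []
    last_known = np.maximum.accumulate(np.where(known, idx, -1))
    filled = np.where(last_known >= 0, state[np.clip(last_known, 0, None)], 0)

    segments: list[RotationSegment] = []
    for i0, i1 in contiguous_runs(filled > 0):
        segments.append(_make_segment(stream.t, w, i0, i1))
    for i0, i1 in contiguous_runs(filled < 0):
        segments.append(_make_segment(stream.t, w, i0, i1))
    segments.sort(key=lambda s: s.start_t)
    return [s for s in segments if s.end_t > s.start_t and s.angle > 0]


def _make_segment(t: np.ndarray, w: np.ndarray, i0: int, i1: int) -> RotationSegment:
    j1 = min(i1 + 1, len(t))         # include the crossing sample
    tt, ww = t[i0:j1], w[i0:j1]
    angle = abs(np.trapezoid(ww, tt)) if len(tt) > 1 else 0.0
    return RotationSegment(start_t=float(t[i0]), end_t=float(t[j1 - 1]),
                           angle=float(angle))


def hand_turn_speed(stream: InertialStream,
                    cfg: MotionConfig = MOTION) -> FeatureOutcome:
    """Median mean-speed (rad/s) over qualifying segmented hand rotations."""
    if len(stream.t) < 4:
        return FeatureOutcome(None, "rad/s", flag="no rotations")
    segs = [s for s in segment_rotations(stream, cfg)
            if s.angle >= cfg.hand_turn_min_angle_rad]
    if len(segs) < 2:
        return FeatureOutcome(None, "rad/s", flag="no rotations")
    speeds = np.array([s.mean_speed for s in segs])
    return FeatureOutcome(float(np.median(speeds)), "rad/s",
                          extras={"n_rotations": len(segs)})


# ---------------------------------------------------------------------------
# Tremor
# ---------------------------------------------------------------------------

def tremor_energy(stream: InertialStream,
                  band: tuple[float, float] = MOTION.tremor_band_hz,
                  cfg: MotionConfig = MOTION) -> FeatureOutcome:
    """ln of the median squared band-passed acceleration magnitude.

    Identical for the rest and postural tests.  A digitally silent stream is
    clipped at ``ln(floor)`` and flagged "floor".
    """
    acc = zero_phase_filter(stream.acc, stream.fs, band, "bandpass",
                            cfg.tremor_filter_order, axis=0)
    sq = (acc ** 2).sum(axis=1)
    med = float(np.median(sq))
    if med <= cfg.log_floor:
        return FeatureOutcome(float(np.log(cfg.log_floor)), "log(m^2/s^4)",
                              flag="floor")
    return FeatureOutcome(float(np.log(med)), "log(m^2/s^4)")


# ---------------------------------------------------------------------------
# Balance
# ---------------------------------------------------------------------------

def sway_jerk(stream: InertialStream,
              cfg: MotionConfig = MOTION) -> FeatureOutcome:
    """ln of the time-averaged squared jerk magnitude in the sway band."""
    acc = zero_phase_filter(stream.acc, stream.fs, cfg.sway_lowpass_hz,
                            "lowpass", cfg.filter_order, axis=0)
    jerk = np.gradient(acc, stream.t, axis=0)
    sq = (jerk ** 2).sum(axis=1)
    mean_sq = float(np.trapezoid(sq, stream.t) / (stream.t[-1] - stream.t[0]))
    if mean_sq <= cfg.log_floor:
        return FeatureOutcome(float(np.log(cfg.log_floor)), "log(m^2/s^6)",
                              flag="floor")
    return FeatureOutcome(float(np.log(mean_sq)), "log(m^2/s^6)")


# ---------------------------------------------------------------------------
# Turns (U-turn test; reused by passive monitoring)
# ---------------------------------------------------------------------------

def yaw_rate(stream: InertialStream, cfg: MotionConfig = MOTION) -> np.ndarray:
    """Angular rate about the gravity-aligned axis (rad/s).

    Gravity direction is tracked with a low-pass (0.25 Hz) of the
    accelerometer, so slow re-orientations of the phone are followed.
    """
    g = zero_phase_filter(stream.acc, stream.fs, cfg.gravity_lowpass_hz,
                          "lowpass", max(2, cfg.filter_order // 2), axis=0)
    norm = np.linalg.norm(g, axis=1)
    # fall back to global mean direction where the low-passed norm vanishes
    fallback = stream.acc.mean(axis=0)
    fallback = fallback / max(np.linalg.norm(fallback), 1e-12)
    bad = norm < 1e-6
    unit = np.where(bad[:, None], fallback[None, :], g / np.maximum(norm, 1e-12)[:, None])
    return (stream.gyro * unit).sum(axis=1)


def detect_turns(stream: InertialStream,
                 cfg: MotionConfig = MOTION) -> list[TurnEvent]:
    """Detect walking turns from integrated yaw.

    A turn is a contiguous interval with instantaneous |yaw rate| above
    ``turn_min_rate_rad_s`` whose accumulated yaw change reaches at least
    ``turn_min_angle_rad`` (default 140 deg, catching ~180 deg U-turns with
    undershoot margin).
    """
    if len(stream.t) < 4:
        return []
    rate = yaw_rate(stream, cfg)
    active = np.abs(rate) > cfg.turn_min_rate_rad_s
    yaw = np.concatenate([[0.0], cumulative_trapezoid(rate, stream.t)])
    events = []
    for i0, i1 in contiguous_runs(active):
        j1 = min(i1, len(stream.t) - 1)
        angle = yaw[j1] - yaw[i0]
        if abs(angle) >= cfg.turn_min_angle_rad and stream.t[j1] > stream.t[i0]:
            events.append(TurnEvent(start_t=float(stream.t[i0]),
                                    end_t=float(stream.t[j1]),
                                    yaw_angle=float(angle)))
    return events


def uturn_speed(stream: InertialStream,
                cfg: MotionConfig = MOTION) -> FeatureOutcome:
    """Median per-turn speed (rad/s) over all turns in the U-turn test."""
    turns = detect_turns(stream, cfg)
    if not turns:
        return FeatureOutcome(None, "rad/s", flag="no turns")
    speeds = np.array([ev.speed for ev in turns])
    return FeatureOutcome(float(np.median(speeds)), "rad/s",
                          extras={"n_turns": len(turns)})
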