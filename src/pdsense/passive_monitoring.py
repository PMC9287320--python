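"""Daily-life (passive monitoring) features.

A day-long inertial stream from the phone (worn at the waist/pocket) or the
watch (wrist) is first partitioned into activity states:

* ``gait`` — 6 s windows whose acceleration-magnitude spectrum has its
  dominant peak in the step band (1.4-2.5 Hz) with sufficient peak power
  fraction and amplitude;
* ``non_gait_movement`` — magnitude variance above the idle threshold;
* ``idle`` — device on body but still;
* ``off_body`` — variance below the noise floor sustained for >= 5 min
  (device on a table / charging).

The labels partition the recorded time exactly.  On this mask:

* *daily turn speed* (phone) applies the U-turn turn detector inside gait
  intervals only and reports the median per-turn speed of the day;
* *arm movement power* (watch) segments discrete arm movements during
  non-gait time as runs where the gravity-removed acceleration magnitude
  exceeds 0.15 m/s^2 for 0.25-10 s, and reports the median per-movement
  integrated squared magnitude (m^2/s^3);
* *wear time* is recorded time minus off-body time, in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

from ._util import FeatureOutcome, contiguous_runs, zero_phase_filter
from .config import MOTION, PASSIVE, MotionConfig, PassiveConfig
from .motion_features import detect_turns
from .session_model import InertialStream

__all__ = ["ActivityMask", "detect_gait_bouts", "daily_turn_speed",
           "arm_movement_power", "wear_time"]

LABELS = ("gait", "non_gait_movement", "idle", "off_body")


def _slice_stream(stream: InertialStream, sel: np.ndarray) -> InertialStream:
    """View of an already-validated stream (skips re-validation)."""
    sub = object.__new__(InertialStream)
    sub.t = stream.t[sel]
    sub.acc = stream.acc[sel]
    sub.gyro = stream.gyro[sel]
    sub.fs_nominal = stream.fs_nominal
    return sub


@dataclass
class ActivityMask:
    """Non-overlapping, time-ordered labelled intervals covering one recording."""

    intervals: list = field(default_factory=list)   # (start_t, end_t, label)

    def duration(self, label: str | None = None) -> float:
        return sum(e - s for s, e, lab in self.intervals
                   if label is None or lab == label)

    def of(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, lab in self.intervals if lab == label]


def detect_gait_bouts(stream: InertialStream,
                      cfg: PassiveConfig = PASSIVE) -> ActivityMask:
    """Label a day-long stream into gait / non-gait movement / idle / off-body."""
    n = len(stream.t)
    if n < 2:
        return ActivityMask([])
    fs = stream.fs
    win = max(int(round(cfg.gait_window_s * fs)), 4)

    labels: list[str] = []
    bounds: list[tuple[int, int]] = []
    # batch the full windows' spectra; the ragged tail is handled alone.
    # statistics use per-axis detrended windows (total dynamic power), so
    # movement orthogonal to gravity counts the same as vertical movement.
    full = n // win
    if full:
        block = stream.acc[:full * win].reshape(full, win, 3)
        block = block - block.mean(axis=1, keepdims=True)
        var = block.var(axis=1).sum(axis=1)
        power = (np.abs(sp_fft.rfft(block, axis=1)) ** 2).sum(axis=2)
        power[:, 0] = 0.0
        freqs = sp_fft.rfftfreq(win, 1.0 / fs)
        dom = power.argmax(axis=1)
        total = power.sum(axis=1)
        frac = power[np.arange(full), dom] / np.maximum(total, 1e-30)
        dom_f = freqs[dom]
        rms = np.sqrt(var)
        lo, hi = cfg.gait_band_hz
        is_gait = ((dom_f >= lo) & (dom_f <= hi) & (frac >= cfg.gait_peak_fraction)
                   & (rms >= cfg.gait_min_amplitude))
        for i in range(full):
            if var[i] < cfg.off_body_var_threshold:
                lab = "off_body_candidate"
            elif is_gait[i]:
                lab = "gait"
            elif var[i] >= cfg.idle_var_threshold:
                lab = "non_gait_movement"
            else:
                lab = "idle"
            labels.append(lab)
            bounds.append((i * win, min((i + 1) * win, n - 1)))
    if full * win < n - 1:
        tail = stream.acc[full * win:]
        var = float(tail.var(axis=0).sum()) if len(tail) > 1 else 0.0
        if var < cfg.off_body_var_threshold:
            lab = "off_body_candidate"
        elif var >= cfg.idle_var_threshold:
            lab = "non_gait_movement"
        else:
            lab = "idle"
        labels.append(lab)
        bounds.append((full * win, n - 1))

    # off-body only when the still period is sustained
    lab_arr = np.array(labels, dtype=object)
    cand = lab_arr == "off_body_candidate"
    for i0, i1 in contiguous_runs(cand):
        t0 = stream.t[bounds[i0][0]]
        t1 = stream.t[bounds[i1 - 1][1]]
        final = "off_body" if (t1 - t0) >= cfg.off_body_min_s else "idle"
        lab_arr[i0:i1] = final

    # merge consecutive equal labels into intervals
    intervals: list[tuple[float, float, str]] = []
    for lab, (i0, i1) in zip(lab_arr, bounds):
        t0, t1 = float(stream.t[i0]), float(stream.t[i1])
        if intervals and intervals[-1][2] == lab and intervals[-1][1] == t0:
            intervals[-1] = (intervals[-1][0], t1, lab)
        else:
            intervals.append((t0, t1, lab))
    return ActivityMask(intervals)


def daily_turn_speed(stream: InertialStream, mask: ActivityMask,
                     cfg: MotionConfig = MOTION,
                     pcfg: PassiveConfig = PASSIVE) -> FeatureOutcome:
    """Median speed (rad/s) over all turns detected within the day's gait time."""
    gait = mask.of("gait")
    gait_s = sum(e - s for s, e in gait)
    if gait_s < pcfg.min_gait_s_for_turns:
        return FeatureOutcome(None, "rad/s", flag="insufficient gait",
                              extras={"gait_s": gait_s})
    speeds = []
    n_turns = 0
    for s, e in gait:
        sel = (stream.t >= s) & (stream.t <= e)
        if sel.sum() < 8:
            continue
        turns = detect_turns(_slice_stream(stream, sel), cfg)
        n_turns += len(turns)
        speeds.extend(ev.speed for ev in turns)
    if not speeds:
        return FeatureOutcome(None, "rad/s", flag="no turns",
                              extras={"gait_s": gait_s})
    return FeatureOutcome(float(np.median(speeds)), "rad/s",
                          extras={"n_turns": n_turns, "gait_s": gait_s})


def arm_movement_power(stream: InertialStream, mask: ActivityMask,
                       cfg: PassiveConfig = PASSIVE,
                       mcfg: MotionConfig = MOTION) -> FeatureOutcome:
    """Median integrated squared gravity-removed acceleration per arm movement.

    Movements are contiguous runs above the amplitude threshold lasting
    0.25-10 s inside non-gait-movement intervals; each contributes
    ``integral of |a|^2 dt`` (m^2/s^3) and the day's value is their median.
    """
    if len(stream.t) < 8:
        return FeatureOutcome(None, "m^2/s^3", flag="no movements")
    # two-pass gravity estimate: a first low-pass flags moving samples, then
    # gravity is re-estimated from the still samples only (interpolated across
    # movement gaps) so short movements are not partially absorbed
    gravity = zero_phase_filter(stream.acc, stream.fs, mcfg.gravity_lowpass_hz,
                                "lowpass", 2, axis=0)
    dyn0 = np.linalg.norm(stream.acc - gravity, axis=1)
    still = dyn0 <= 0.5 * cfg.movement_amp_threshold
    if still.any() and not still.all():
        idx = np.arange(len(stream.t))
        acc_still = np.column_stack([
            np.interp(idx, idx[still], stream.acc[still, k]) for k in range(3)])
        gravity = zero_phase_filter(acc_still, stream.fs,
                                    mcfg.gravity_lowpass_hz, "lowpass", 2, axis=0)
    dyn = np.linalg.norm(stream.acc - gravity, axis=1)

    in_non_gait = np.zeros(len(stream.t), dtype=bool)
    for s, e in mask.of("non_gait_movement"):
        in_non_gait |= (stream.t >= s) & (stream.t <= e)

    powers = []
    active = (dyn > cfg.movement_amp_threshold) & in_non_gait
    for i0, i1 in contiguous_runs(active):
        j1 = min(i1, len(stream.t) - 1)
        dur = stream.t[j1 - 1] - stream.t[i0] if j1 - 1 > i0 else 0.0
        if cfg.movement_min_s <= dur <= cfg.movement_max_s:
            powers.append(float(np.trapezoid(dyn[i0:i1] ** 2, stream.t[i0:i1])))
    if not powers:
        return FeatureOutcome(None, "m^2/s^3", flag="no movements")
    return FeatureOutcome(float(np.median(powers)), "m^2/s^3",
                          extras={"n_movements": len(powers)})


def wear_time(stream: InertialStream, mask: ActivityMask) -> FeatureOutcome:
    """Hours of on-body recording: recorded time minus off-body time."""
    recorded = stream.duration if len(stream.t) > 1 else 0.0
    off = mask.duration("off_body")
    return FeatureOutcome((recorded - off) / 3600.0, "h",
                          extras={"recorded_h": recorded / 3600.0})
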