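"""Seeded synthetic-cohort simulator.

Generates raw sensor sessions plus clinical records with severity-coupled
structure so the whole pipeline — feature extraction, QC, fortnightly
aggregation and the validation statistics — is testable without clinical
data.  Each participant carries latent severities in [0, 1] per motor domain
(bradykinesia, tremor, axial, speech, cognition), lateralized domains get a
per-side split, and both the clinical item scores and the raw-signal emission
parameters are monotone functions of the same latents.  Emission models are
deliberately simple (sinusoids, pulse trains, Gaussian noise, square-pulse
turns) so analytic targets exist for every extracted feature; physiological
realism is a non-goal.

Randomness is counter-based: every (participant, day, test) draws from an
independent stream spawned from the master seed, so adding a test or day
never perturbs any other stream and a fixed (config, seed) reproduces the
output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .aggregation import Schedule
from .session_model import (AudioSignal, BundleData, ClinicalRecord,
                            InertialStream, SdmtResponses, TestSession,
                            TouchTrace)

__all__ = ["CohortSimConfig", "GroundTruth", "simulate_participant",
           "simulate_cohort", "phone_on_table_session",
           "synth_phonation", "synth_speech_question", "synth_tap_trace",
           "synth_hand_turning", "synth_tremor", "synth_balance",
           "synth_uturn", "synth_passive_phone_day", "synth_passive_watch_day",
           "synth_spiral_trace"]

GRAVITY = 9.81

#: Ordered-threshold discretization of latent severity into 0..4 item scores;
#: calibrated for early-PD marginals (most items score 0-2).
ITEM_CUTS = (0.45, 0.70, 0.88, 0.97)

#: MDS-UPDRS item -> (domain, side) used when discretizing latent severities.
ITEM_DOMAINS = {
    "1.1": ("cognition", None),
    "2.1": ("speech", None), "2.2": ("speech", None), "2.3": ("speech", None),
    "3.1": ("speech", None), "3.2": ("speech", None),
    "3.3L": ("bradykinesia", "left"), "3.3R": ("bradykinesia", "right"),
    "3.4L": ("bradykinesia", "left"), "3.4R": ("bradykinesia", "right"),
    "3.5L": ("bradykinesia", "left"), "3.5R": ("bradykinesia", "right"),
    "3.6L": ("bradykinesia", "left"), "3.6R": ("bradykinesia", "right"),
    "3.12": ("axial", None), "3.14": ("axial", None),
    "3.15L": ("tremor", "left"), "3.15R": ("tremor", "right"),
    "3.17L": ("tremor", "left"), "3.17R": ("tremor", "right"),
}


@dataclass(frozen=True)
class CohortSimConfig:
    """Study conditions for the simulator.

    Defaults follow the early-PD remote-monitoring protocol: 28 study days,
    alternating motor-test halves, fortnightly eSDMT, daily passive
    monitoring, and the published per-test durations.  ``desk_scale`` gives a
    size-reduced profile (same structure, shorter recordings) for fast
    in-memory experiments; see docs/methods.md.
    """

    n_participants: int = 316
    n_days: int = 28
    imu_fs: float = 50.0
    audio_fs: float = 16000.0
    # per-test recording lengths (seconds)
    dexterity_s: float = 20.0
    hand_turning_s: float = 10.0
    tremor_s: float = 15.0
    balance_s: float = 30.0
    uturn_s: float = 60.0
    phonation_s: float = 10.0
    speech_question_s: float = 20.0
    # passive monitoring
    passive_fs: float = 20.0
    passive_phone_min: float = 516.0      # 8.6 h/day
    passive_watch_min: float = 767.0      # ~12.8 h/day
    off_body_min: float = 45.0            # appended still block per day
    # adherence model: daily all-or-nothing completion plus rare single-session
    # drops; together these put the median day-level adherence at 26/27 days
    day_completion_p: float = 0.97
    session_drop_p: float = 0.003
    #: limit passive monitoring to the first k study days (None = every day)
    passive_days: int | None = None
    # latent-model parameters
    domain_sd: float = 0.15               # domain scatter around overall severity
    asym_lo: float = 0.10
    asym_hi: float = 0.35
    item_noise_sd: float = 0.12
    within_subject_sd: float = 0.15       # day-to-day severity wobble
    hy2_threshold: float = 0.25           # overall severity above -> stage II
    #: probability a hand-turning session is executed with the phone lying
    #: still (caught by the QC movement-energy gate); chosen so the overall
    #: active-test exclusion rate sits at the few-per-thousand scale
    misexecution_p: float = 0.02

    @classmethod
    def desk_scale(cls, n_participants: int = 100,
                   n_days: int = 28) -> "CohortSimConfig":
        """Size-reduced profile: same schedule/coupling, short recordings."""
        return cls(
            n_participants=n_participants, n_days=n_days,
            phonation_s=2.5, speech_question_s=2.2,
            passive_phone_min=6.0, passive_watch_min=5.0, off_body_min=0.0,
        )

    @classmethod
    def sign_recovery(cls, n_participants: int = 100) -> "CohortSimConfig":
        """Minimal cross-sectional profile for coupling-direction studies.

        Six study days give exactly the three data points per feature the
        first aggregation window requires; recordings are cut to the
        shortest lengths that keep every extractor well-defined.
        """
        return cls(
            n_participants=n_participants, n_days=6,
            phonation_s=0.8, speech_question_s=1.0, uturn_s=40.0,
            passive_phone_min=5.0, passive_watch_min=2.0, off_body_min=0.0,
            passive_days=3,
        )

    def expected_durations(self) -> dict:
        """Expected recording lengths for the QC duration-ratio check."""
        return {
            "dexterity": self.dexterity_s, "hand_turning": self.hand_turning_s,
            "postural_tremor": self.tremor_s, "rest_tremor": self.tremor_s,
            "balance": self.balance_s, "u_turn": self.uturn_s,
            "speech": 3 * self.speech_question_s,
        }


@dataclass
class GroundTruth:
    """Everything needed to score detectors and couplings exactly."""

    participant_id: str
    severities: dict                       # domain -> value or {side: value}
    hoehn_yahr: int
    more_affected: str
    turn_inventory: dict = field(default_factory=dict)   # day -> list of true speeds
    movement_inventory: dict = field(default_factory=dict)  # day -> list of powers
    emission: dict = field(default_factory=dict)         # per-test truth values


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


TEST_CODES = {name: i for i, name in enumerate(
    ("draw_a_shape", "dexterity", "hand_turning", "speech", "phonation",
     "postural_tremor", "rest_tremor", "balance", "u_turn", "esdmt",
     "passive_phone", "passive_watch", "clinical", "latent", "adherence"))}


# ---------------------------------------------------------------------------
# Emission models (exported so tests can drive them with known parameters)
# ---------------------------------------------------------------------------

def synth_tap_trace(duration_s: float, interval_mean_s: float,
                    interval_sd_s: float, rng: np.random.Generator,
                    screen=(1080.0, 1920.0)) -> TouchTrace:
    """Alternating two-button tap train with Gaussian inter-tap intervals."""
    intervals = np.maximum(rng.normal(interval_mean_s, interval_sd_s, 400), 0.05)
    times = np.concatenate([[0.3], 0.3 + np.cumsum(intervals)])
    times = times[times < duration_s]
    n = len(times)
    buttons = np.array([("A", 340.0), ("B", 740.0)], dtype=object)
    t_all, x_all, y_all, kind, target = [], [], [], [], []
    for i, td in enumerate(times):
        name, bx = buttons[i % 2]
        jx, jy = rng.normal(0, 8, 2)
        t_all += [td, td + 0.03]        # dwell below the minimum inter-tap gap
        x_all += [bx + jx] * 2
        y_all += [1500.0 + jy] * 2
        kind += ["down", "up"]
        target += [name, name]
    return TouchTrace(t=np.array(t_all), x=np.clip(x_all, 0, screen[0]),
                      y=np.clip(y_all, 0, screen[1]),
                      kind=np.array(kind, dtype=object),
                      target=np.array(target, dtype=object), screen=screen)


def synth_spiral_trace(template_waypoints: np.ndarray, duration_s: float,
                       noise_px: float, rng: np.random.Generator,
                       n_points: int = 160,
                       screen=(1080.0, 1920.0)) -> TouchTrace:
    """Spiral drawing attempt: template path plus i.i.d. positional noise."""
    wp = np.asarray(template_waypoints, dtype=float)
    # resample the polyline to n_points by arc length
    seg = np.linalg.norm(np.diff(wp, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    u = np.linspace(0, s[-1], n_points)
    x = np.interp(u, s, wp[:, 0]) + rng.normal(0, noise_px, n_points)
    y = np.interp(u, s, wp[:, 1]) + rng.normal(0, noise_px, n_points)
    t = np.linspace(0.0, duration_s, n_points)
    kind = np.array(["down"] + ["move"] * (n_points - 2) + ["up"], dtype=object)
    return TouchTrace(t=t, x=np.clip(x, 0, screen[0]), y=np.clip(y, 0, screen[1]),
                      kind=kind, target=np.full(n_points, "spiral", dtype=object),
                      screen=screen)


def synth_hand_turning(duration_s: float, fs: float, amplitude_rad_s: float,
                       freq_hz: float, rng: np.random.Generator) -> InertialStream:
    """Sinusoidal pronation/supination about a random axis + sensor noise."""
    t = np.arange(int(round(duration_s * fs))) / fs
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    w = amplitude_rad_s * np.sin(2 * np.pi * freq_hz * t)
    gyro = np.outer(w, axis) + rng.normal(0, 0.02, (len(t), 3))
    # phone rotates in hand: dynamic acceleration accompanies the turning
    acc_axis = rng.normal(size=3)
    acc_axis /= np.linalg.norm(acc_axis)
    acc = np.array([0.0, 0.0, GRAVITY]) + \
        np.outer(1.2 * np.sin(2 * np.pi * freq_hz * t + 0.7), acc_axis) + \
        rng.normal(0, 0.05, (len(t), 3))
    return InertialStream(t=t, acc=acc, gyro=gyro, fs_nominal=fs)


def synth_tremor(duration_s: float, fs: float, tremor_amp: float,
                 tremor_freq_hz: float, rng: np.random.Generator,
                 noise_sd: float = 0.03) -> InertialStream:
    """Hand-held phone: gravity + in-band tremor sinusoid + white noise."""
    t = np.arange(int(round(duration_s * fs))) / fs
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    phase = rng.uniform(0, 2 * np.pi)
    tre = tremor_amp * np.sin(2 * np.pi * tremor_freq_hz * t + phase)
    acc = np.array([0.3, 0.1, GRAVITY]) + np.outer(tre, axis) + \
        rng.normal(0, noise_sd, (len(t), 3))
    gyro = rng.normal(0, 0.01, (len(t), 3))
    return InertialStream(t=t, acc=acc, gyro=gyro, fs_nominal=fs)


def synth_balance(duration_s: float, fs: float, sway_amp: float,
                  rng: np.random.Generator) -> InertialStream:
    """Quiet standing: gravity + low-frequency sway + noise."""
    t = np.arange(int(round(duration_s * fs))) / fs
    sway = (sway_amp * np.sin(2 * np.pi * 0.4 * t + rng.uniform(0, 6.28)) +
            0.5 * sway_amp * np.sin(2 * np.pi * 0.9 * t + rng.uniform(0, 6.28)))
    acc = np.array([0.0, 0.0, GRAVITY]) + \
        np.outer(sway, np.array([0.8, 0.6, 0.1])) + \
        rng.normal(0, 0.02, (len(t), 3))
    gyro = rng.normal(0, 0.01, (len(t), 3))
    return InertialStream(t=t, acc=acc, gyro=gyro, fs_nominal=fs)


def _turn_pulse_rate(t: np.ndarray, start: float, duration: float,
                     rate: float) -> np.ndarray:
    return np.where((t >= start) & (t < start + duration), rate, 0.0)


def synth_uturn(duration_s: float, fs: float, turn_rate_rad_s: float,
                rng: np.random.Generator, n_turns: int = 6,
                turn_angle_rad: float = math.pi) -> tuple[InertialStream, list]:
    """Walking with ~180-degree square-pulse turns; returns (stream, true speeds).

    The phone is worn upright at the waist: gravity along z, yaw about z.
    """
    t = np.arange(int(round(duration_s * fs))) / fs
    walk = 2.2 * np.sin(2 * np.pi * 2.0 * t)
    acc = np.array([0.0, 0.0, GRAVITY]) + \
        np.outer(walk, np.array([0.3, 0.2, 1.0])) + \
        rng.normal(0, 0.05, (len(t), 3))
    yaw = np.zeros(len(t))
    true_speeds = []
    turn_dur = turn_angle_rad / turn_rate_rad_s
    gap = (duration_s - n_turns * turn_dur) / (n_turns + 1)
    start = gap
    sign = 1.0
    for _ in range(n_turns):
        yaw += sign * _turn_pulse_rate(t, start, turn_dur, turn_rate_rad_s)
        true_speeds.append(turn_rate_rad_s)
        start += turn_dur + gap
        sign = -sign
    gyro = np.column_stack([rng.normal(0, 0.02, len(t)),
                            rng.normal(0, 0.02, len(t)),
                            yaw + rng.normal(0, 0.02, len(t))])
    return InertialStream(t=t, acc=acc, gyro=gyro, fs_nominal=fs), true_speeds


def synth_phonation(duration_s: float, fs: float, period_s: float,
                    period_jitter_mad_s: float,
                    rng: np.random.Generator,
                    noise_sd: float = 0.004) -> AudioSignal:
    """Sustained-phonation surrogate: glottal pulse train with period jitter.

    ``period_jitter_mad_s`` is the target mean absolute difference between
    adjacent periods; i.i.d. Gaussian period perturbations with
    sigma = mad * sqrt(pi)/2 achieve it in expectation.
    """
    sigma = period_jitter_mad_s * math.sqrt(math.pi) / 2.0
    n_cycles = int(duration_s / period_s) + 8
    periods = period_s + rng.normal(0, sigma, n_cycles)
    periods = np.clip(periods, 0.4 * period_s, 1.8 * period_s)
    times = 0.05 + np.cumsum(periods)
    times = times[times < duration_s - 0.05]
    n = int(round(duration_s * fs))
    x = rng.normal(0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    pulse_len = max(int(0.002 * fs) | 1, 3)      # odd: unambiguous peak sample
    pulse = 0.6 * np.hanning(pulse_len)
    idx = np.round(times * fs).astype(int)
    for i in idx:
        j = min(i + pulse_len, n)
        x[i:j] += pulse[:j - i]
    return AudioSignal(samples=x, fs=fs)      # amplitudes < 1 by construction


def _resonator(x: np.ndarray, fs: float, freq: float, r: float = 0.97) -> np.ndarray:
    from scipy.signal import lfilter
    w = 2 * np.pi * freq / fs
    a = [1.0, -2 * r * np.cos(w), r * r]
    return lfilter([1.0 - r], a, x)


def synth_speech_question(duration_s: float, fs: float, formant_contrast: float,
                          rng: np.random.Generator) -> AudioSignal:
    """Two vowel-like segments separated by a pause.

    ``formant_contrast`` in [0, 1] scales the spectral separation of the two
    vowels; smaller contrast yields more monotone speech (lower MFCC2
    variability).
    """
    v_dur = 0.36 * duration_s
    pause = 0.14 * duration_s
    base = np.array([[700.0, 1200.0], [300.0, 2300.0]])   # /a/-like, /i/-like
    mean = base.mean(axis=0)
    formants = mean + (base - mean) * formant_contrast
    n = int(round(duration_s * fs))
    x = rng.normal(0, 0.0015, n)
    start = 0.0
    for f1, f2 in formants:
        i0 = int(start * fs)
        i1 = min(int((start + v_dur) * fs), n)
        seg_n = i1 - i0
        if seg_n <= 0:
            break
        src = np.zeros(seg_n)
        period = int(fs / 120.0)
        src[::period] = 1.0
        v = _resonator(src, fs, f1) + _resonator(src, fs, f2)
        v *= 0.25 / max(np.abs(v).max(), 1e-9)
        env = np.ones(seg_n)
        ramp = min(int(0.02 * fs), seg_n // 4)
        env[:ramp] = np.linspace(0, 1, ramp)
        env[-ramp:] = np.linspace(1, 0, ramp)
        x[i0:i1] += v * env
        start += v_dur + pause
    return AudioSignal(samples=x, fs=fs)      # amplitudes < 1 by construction


def synth_passive_phone_day(minutes: float, fs: float, turn_rate_rad_s: float,
                            rng: np.random.Generator,
                            off_body_min: float = 0.0) -> tuple[InertialStream, list]:
    """One phone day: idle / walking-with-turns / non-gait blocks (+ off-body tail).

    Returns (stream, list of true turn speeds injected inside gait blocks).
    """
    blocks = []          # (duration_s, kind)
    total = 0.0
    day_s = minutes * 60.0
    cycle = [(40.0, "idle"), (36.0, "walk"), (20.0, "idle"), (24.0, "move")]
    while total < day_s:
        for dur, kind in cycle:
            dur = min(dur, max(day_s - total, 0.0))
            if dur <= 0:
                break
            blocks.append((dur, kind))
            total += dur
    if off_body_min > 0:
        blocks.append((off_body_min * 60.0, "off"))

    n = int(round(sum(d for d, _ in blocks) * fs))
    t = np.arange(n) / fs
    acc = np.tile(np.array([0.0, 0.0, GRAVITY]), (n, 1))
    gyro = np.zeros((n, 3))
    true_speeds = []
    pos = 0.0
    for dur, kind in blocks:
        i0, i1 = int(pos * fs), min(int((pos + dur) * fs), n)
        m = i1 - i0
        if m <= 0:
            pos += dur
            continue
        tt = t[i0:i1] - t[i0]
        if kind == "walk":
            acc[i0:i1] += np.outer(2.4 * np.sin(2 * np.pi * 2.0 * tt),
                                   np.array([0.3, 0.2, 1.0]))
            acc[i0:i1] += rng.normal(0, 0.08, (m, 3))
            gyro[i0:i1] += rng.normal(0, 0.02, (m, 3))
            # two turns per walk block, opposite directions
            turn_dur = math.pi / turn_rate_rad_s
            if dur > 2 * turn_dur + 9.0:
                for j, frac in enumerate((0.25, 0.65)):
                    start = frac * dur
                    sel = (tt >= start) & (tt < start + turn_dur)
                    gyro[i0:i1, 2] += np.where(sel, (1 if j == 0 else -1)
                                               * turn_rate_rad_s, 0.0)
                    true_speeds.append(turn_rate_rad_s)
        elif kind == "move":
            acc[i0:i1] += np.outer(0.7 * np.sin(2 * np.pi * 0.8 * tt),
                                   np.array([0.7, 0.7, 0.2]))
            acc[i0:i1] += rng.normal(0, 0.10, (m, 3))
            gyro[i0:i1] += rng.normal(0, 0.05, (m, 3))
        elif kind == "idle":
            acc[i0:i1] += rng.normal(0, 0.035, (m, 3))
            gyro[i0:i1] += rng.normal(0, 0.004, (m, 3))
        else:                                   # off-body: on the table
            acc[i0:i1] += rng.normal(0, 0.001, (m, 3))
        pos += dur
    return InertialStream(t=t, acc=acc, gyro=gyro, fs_nominal=fs), true_speeds


def synth_passive_watch_day(minutes: float, fs: float, movement_amp: float,
                            rng: np.random.Generator,
                            off_body_min: float = 0.0) -> tuple[InertialStream, list]:
    """One watch day: idle with discrete arm movements, some gait, off-body tail.

    Returns (stream, list of true per-movement powers integral |a|^2 dt).
    """
    day_s = minutes * 60.0
    extra = off_body_min * 60.0
    n = int(round((day_s + extra) * fs))
    t = np.arange(n) / fs
    acc = np.tile(np.array([0.0, 0.0, GRAVITY]), (n, 1))
    acc[:int(day_s * fs)] += rng.normal(0, 0.035, (int(day_s * fs), 3))
    if extra > 0:
        acc[int(day_s * fs):] += rng.normal(0, 0.001, (n - int(day_s * fs), 3))
    gyro = rng.normal(0, 0.004, (n, 3))

    true_powers = []
    # one walking block (arm swing) to exercise the non-gait exclusion
    walk_start, walk_dur = 0.35 * day_s, min(40.0, 0.2 * day_s)
    sel = (t >= walk_start) & (t < walk_start + walk_dur)
    acc[sel] += np.outer(2.0 * np.sin(2 * np.pi * 2.0 * (t[sel] - walk_start)),
                         np.array([0.5, 0.8, 0.4]))[:]
    # discrete arm movements every ~20 s outside the walking block
    mdur = 0.8
    start = 6.0
    axis = np.array([0.8, 0.55, 0.25])
    axis /= np.linalg.norm(axis)
    while start + mdur < day_s:
        if not (walk_start - 5 < start < walk_start + walk_dur + 5):
            amp = movement_amp * rng.uniform(0.85, 1.15)
            sel = (t >= start) & (t < start + mdur)
            m = int(sel.sum())
            if m:
                env = np.sin(np.pi * np.linspace(0, 1, m)) ** 0.5
                acc[sel] += np.outer(amp * env, axis)
                true_powers.append(float(np.trapezoid((amp * env) ** 2,
                                                      t[sel])))
        start += 20.0
    return InertialStream(t=t, acc=acc, gyro=gyro, fs_nominal=fs), true_powers


def phone_on_table_session(participant_id: str, day: int, side: str,
                           rng: np.random.Generator,
                           duration_s: float = 10.0,
                           fs: float = 50.0) -> TestSession:
    """A hand-turning session recorded with the phone lying still (QC failure)."""
    t = np.arange(int(duration_s * fs)) / fs
    acc = np.array([0.0, 0.0, GRAVITY]) + rng.normal(0, 0.002, (len(t), 3))
    gyro = rng.normal(0, 0.001, (len(t), 3))
    return TestSession(participant_id=participant_id, test_name="hand_turning",
                       body_side=side, day_index=day,
                       payload=InertialStream(t=t, acc=acc, gyro=gyro,
                                              fs_nominal=fs))


# ---------------------------------------------------------------------------
# Latent model
# ---------------------------------------------------------------------------

def _draw_latents(rng: np.random.Generator, cfg: CohortSimConfig) -> dict:
    overall = rng.uniform(0.02, 0.98)
    sev = {}
    for dom in ("bradykinesia", "tremor", "axial", "speech", "cognition"):
        sev[dom] = float(np.clip(overall + rng.normal(0, cfg.domain_sd), 0, 1))
    asym = rng.uniform(cfg.asym_lo, cfg.asym_hi)
    more = "left" if rng.random() < 0.5 else "right"
    for dom in ("bradykinesia", "tremor"):
        base = sev[dom]
        hi = float(np.clip(base + asym / 2, 0, 1))
        lo = float(np.clip(base - asym / 2, 0, 1))
        sev[dom] = {"left": hi if more == "left" else lo,
                    "right": hi if more == "right" else lo}
    sev["overall"] = overall
    sev["more_affected"] = more
    return sev


def _item_scores(sev: dict, rng: np.random.Generator,
                 cfg: CohortSimConfig) -> dict:
    items = {}
    for item, (dom, side) in ITEM_DOMAINS.items():
        base = sev[dom]
        if isinstance(base, dict):
            base = base["left" if side == "left" else "right"]
        eff = base + rng.normal(0, cfg.item_noise_sd)
        items[item] = int(sum(eff > c for c in ITEM_CUTS))
    return items


def _day_sev(base: float, rng: np.random.Generator, cfg: CohortSimConfig) -> float:
    return float(np.clip(base + rng.normal(0, cfg.within_subject_sd), 0, 1))


# ---------------------------------------------------------------------------
# Participant / cohort simulation
# ---------------------------------------------------------------------------

def simulate_participant(cfg: CohortSimConfig, master_seed: int,
                         participant_index: int,
                         spiral_waypoints: np.ndarray | None = None
                         ) -> tuple[BundleData, GroundTruth]:
    """Generate one participant's 4-week bundle and its ground truth."""
    if spiral_waypoints is None:
        from .touch_features import load_shape_template
        spiral_waypoints = load_shape_template("spiral").waypoints
    pid = f"SIM{participant_index:04d}"
    p = participant_index

    lat_rng = _rng(master_seed, p, 0, TEST_CODES["latent"])
    sev = _draw_latents(lat_rng, cfg)
    more = sev["more_affected"]
    hy = 2 if sev["overall"] > cfg.hy2_threshold else 1
    items = _item_scores(sev, _rng(master_seed, p, 0, TEST_CODES["clinical"]), cfg)
    clinical = ClinicalRecord(participant_id=pid, mds_updrs_items=items,
                              hoehn_yahr=hy)
    truth = GroundTruth(participant_id=pid, severities=sev, hoehn_yahr=hy,
                        more_affected=more)

    schedule = Schedule(n_days=cfg.n_days)
    adh_rng = _rng(master_seed, p, 0, TEST_CODES["adherence"])
    sessions: list[TestSession] = []

    def sev_of(test: str, side: str) -> float:
        if test in ("dexterity", "hand_turning", "draw_a_shape"):
            return sev["bradykinesia"][side]
        if test in ("postural_tremor", "rest_tremor"):
            return sev["tremor"][side]
        if test in ("balance", "u_turn"):
            return sev["axial"]
        if test in ("speech", "phonation"):
            return sev["speech"]
        if test == "esdmt":
            return sev["cognition"]
        raise KeyError(test)

    for day in range(1, cfg.n_days + 1):
        # remote days can be skipped wholesale; day 1 happens in clinic
        day_done = day == 1 or adh_rng.random() < cfg.day_completion_p
        expected = schedule.expected_sessions(day)
        for test, side in expected:
            if not day_done:
                continue
            if adh_rng.random() < cfg.session_drop_p:
                continue
            rng = _rng(master_seed, p, day, TEST_CODES[test],
                       0 if side in ("none", "left") else 1)
            s = _day_sev(sev_of(test, side), rng, cfg)
            if test == "hand_turning" and rng.random() < cfg.misexecution_p:
                # phone left on the table: the QC gate should catch this
                sessions.append(phone_on_table_session(
                    pid, day, side, rng, duration_s=cfg.hand_turning_s,
                    fs=cfg.imu_fs))
                truth.emission.setdefault("misexecuted", []).append((day, test, side))
                continue
            payload = _emit(test, s, cfg, rng, spiral_waypoints, truth, day)
            sessions.append(TestSession(participant_id=pid, test_name=test,
                                        body_side=side, day_index=day,
                                        payload=payload))
        # passive monitoring happens daily regardless of active-test adherence
        if cfg.passive_days is not None and day > cfg.passive_days:
            continue
        rngp = _rng(master_seed, p, day, TEST_CODES["passive_phone"])
        s_ax = _day_sev(sev["axial"], rngp, cfg)
        turn_rate = 1.9 / (1.0 + 1.3 * s_ax)
        stream, speeds = synth_passive_phone_day(
            cfg.passive_phone_min, cfg.passive_fs, turn_rate, rngp,
            off_body_min=cfg.off_body_min)
        truth.turn_inventory[day] = speeds
        sessions.append(TestSession(participant_id=pid, test_name="passive_phone",
                                    body_side="none", day_index=day, payload=stream))

        rngw = _rng(master_seed, p, day, TEST_CODES["passive_watch"])
        brady_mean = 0.5 * (sev["bradykinesia"]["left"] + sev["bradykinesia"]["right"])
        s_b = _day_sev(brady_mean, rngw, cfg)
        amp = 2.3 - 1.5 * s_b
        wstream, powers = synth_passive_watch_day(
            cfg.passive_watch_min, cfg.passive_fs, amp, rngw,
            off_body_min=cfg.off_body_min)
        truth.movement_inventory[day] = powers
        sessions.append(TestSession(participant_id=pid, test_name="passive_watch",
                                    body_side="none", day_index=day, payload=wstream))

    return BundleData(sessions=sessions, clinical=clinical), truth


def _emit(test: str, s: float, cfg: CohortSimConfig, rng: np.random.Generator,
          spiral_waypoints: np.ndarray, truth: GroundTruth, day: int):
    """Raw payload for one active test at effective day severity ``s``."""
    if test == "dexterity":
        return synth_tap_trace(cfg.dexterity_s, 0.35, 0.015 + 0.10 * s, rng)
    if test == "draw_a_shape":
        return synth_spiral_trace(spiral_waypoints, 6.0 + 12.0 * s,
                                  2.0 + 22.0 * s, rng)
    if test == "hand_turning":
        # bradykinetic turning is slower but still complete: amplitude and
        # frequency both fall so the per-rotation angle A/(pi*f) stays above
        # the qualifying angle across the whole severity range
        return synth_hand_turning(cfg.hand_turning_s, cfg.imu_fs,
                                  5.0 - 3.2 * s, 1.8 - 1.2 * s, rng)
    if test in ("postural_tremor", "rest_tremor"):
        return synth_tremor(cfg.tremor_s, cfg.imu_fs, 0.05 + 1.2 * s,
                            rng.uniform(4.0, 6.0), rng)
    if test == "balance":
        return synth_balance(cfg.balance_s, cfg.imu_fs, 0.05 + 0.55 * s, rng)
    if test == "u_turn":
        stream, speeds = synth_uturn(cfg.uturn_s, cfg.imu_fs,
                                     2.0 / (1.0 + 1.4 * s), rng,
                                     n_turns=int(rng.integers(5, 8)))
        truth.emission.setdefault("uturn_speeds", {})[day] = speeds
        return stream
    if test == "phonation":
        period = 1.0 / 120.0
        mad = (0.003 + 0.055 * s) * period
        truth.emission.setdefault("jitter_pct", {})[day] = 100.0 * mad / period
        return synth_phonation(cfg.phonation_s, cfg.audio_fs, period, mad, rng)
    if test == "speech":
        contrast = float(np.clip(1.0 - 0.75 * s, 0.05, 1.0))
        return [synth_speech_question(cfg.speech_question_s, cfg.audio_fs,
                                      contrast, rng) for _ in range(3)]
    if test == "esdmt":
        n_resp = max(5, int(round(44 - 18 * s + rng.normal(0, 2))))
        key = {i: (i % 9) + 1 for i in range(1, 10)}
        times = np.sort(rng.uniform(1.0, 89.0, n_resp))
        responses = []
        for td in times:
            sym = int(rng.integers(1, 10))
            digit = key[sym] if rng.random() < 0.96 else int(rng.integers(1, 10))
            responses.append((float(td), sym, digit))
        return SdmtResponses(responses=responses, key=key)
    raise KeyError(test)


def simulate_cohort(cfg: CohortSimConfig, master_seed: int
                    ) -> tuple[list[BundleData], list[GroundTruth]]:
    """Simulate the full cohort; participants draw from independent streams."""
    from .touch_features import load_shape_template
    wp = load_shape_template("spiral").waypoints
    bundles, truths = [], []
    for i in range(cfg.n_participants):
        b, g = simulate_participant(cfg, master_seed, i, spiral_waypoints=wp)
        bundles.append(b)
        truths.append(g)
    return bundles, truths
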