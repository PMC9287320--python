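"""Voice and speech features.

* **Phonation** (sustained "aaaah"): *voice jitter* (jitter:local, %), the
  mean absolute difference between adjacent pitch-cycle periods normalised by
  the mean period, times 100.  Cycle-level periods come from peak-picking
  glottal cycles inside voiced stretches found by autocorrelation pitch
  tracking (40 ms frames, 10 ms hop, 50-500 Hz search).  Higher jitter means
  less stable vocal-fold vibration.
* **Speech** (three 20 s open-ended answers): *MFCC2 variability*.  The
  second Mel-frequency cepstral coefficient is computed per 25 ms frame
  (26 mel filters, 10 ms hop, C0 excluded), averaged within each consecutively
  voiced segment longer than 200 ms, and the feature is the sample standard
  deviation across segment means — lower values indicate more monotone
  speech.  The three questions are processed independently and the session
  value is the mean of the per-question values.

The whole MFCC recipe is pinned in :mod:`pdsense.config` so results are
reproducible bit-for-bit across environments.  All features are invariant to
DC offset and overall gain (C0, the only gain-sensitive coefficient, is
excluded by construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import fft as sp_fft
from scipy.signal import find_peaks, get_window

from ._util import FeatureOutcome, contiguous_runs, frame_signal
from .config import AUDIO, AudioConfig
from .session_model import AudioSignal

__all__ = ["PitchPeriodSequence", "VoicedSegment", "detect_pitch_periods",
           "voice_jitter", "voiced_segments", "mfcc2_variability", "mfcc"]


@dataclass
class PitchPeriodSequence:
    """Ordered glottal-cycle durations (ms) with a voicing summary."""

    periods_ms: np.ndarray
    voiced_fraction: float
    flag: str | None = None

    def __post_init__(self) -> None:
        self.periods_ms = np.asarray(self.periods_ms, dtype=float)


@dataclass
class VoicedSegment:
    """A consecutively voiced stretch of speech (> 200 ms by construction)."""

    start_t: float
    end_t: float
    mean_mfcc2: float | None = None

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


# ---------------------------------------------------------------------------
# Voicing / pitch tracking
# ---------------------------------------------------------------------------

def _frame_voicing(x: np.ndarray, fs: float, frame_s: float, hop_s: float,
                   cfg: AudioConfig):
    """Per-frame (energy, periodicity, best_lag) from normalised autocorrelation."""
    frame = max(int(round(frame_s * fs)), 32)
    hop = max(int(round(hop_s * fs)), 1)
    frames = frame_signal(x, frame, hop)
    if not len(frames):
        return np.empty(0), np.empty(0), np.empty(0, dtype=int), frame, hop
    frames = frames - frames.mean(axis=1, keepdims=True)   # frame-local DC removal
    energy = (frames ** 2).mean(axis=1)
    lmin = max(int(fs / cfg.pitch_fmax_hz), 2)
    lmax = min(int(np.ceil(fs / cfg.pitch_fmin_hz)), frame - 1)
    # linear autocorrelation needs nfft >= frame + lmax; voicing decisions are
    # thresholded, so single precision is ample here
    nfft = sp_fft.next_fast_len(frame + lmax + 1)
    spec = sp_fft.rfft(frames.astype(np.float32), n=nfft, axis=1)
    r = sp_fft.irfft(np.abs(spec) ** 2, n=nfft, axis=1)[:, :lmax + 1]
    r0 = np.maximum(r[:, 0], 1e-30)
    band = r[:, lmin:lmax + 1] / r0[:, None]
    best = band.argmax(axis=1)
    periodicity = band[np.arange(len(band)), best]
    return energy, periodicity, best + lmin, frame, hop


def _audio_cache(audio: AudioSignal) -> dict:
    # QC and feature extraction share voicing/MFCC analyses of the same
    # recording; memoise per AudioSignal instance (config-keyed).
    return audio.__dict__.setdefault("_analysis_cache", {})


def detect_pitch_periods(audio: AudioSignal,
                         cfg: AudioConfig = AUDIO) -> PitchPeriodSequence:
    """Cycle-level pitch periods from a sustained-phonation recording.

    Frames are marked voiced when the normalised autocorrelation peak in the
    pitch search band exceeds the voicing threshold and the frame carries
    non-negligible energy (both criteria are amplitude-relative, so gain
    scaling leaves the result unchanged).  Glottal-cycle peaks are then picked
    within voiced stretches at a minimum spacing of 0.7 median periods.
    A recording with voiced fraction below 0.5 is flagged "poor phonation".
    """
    cache = _audio_cache(audio)
    key = ("pitch", cfg)
    if key in cache:
        return cache[key]
    result = _detect_pitch_periods(audio, cfg)
    cache[key] = result
    return result


def _detect_pitch_periods(audio: AudioSignal,
                          cfg: AudioConfig) -> PitchPeriodSequence:
    x = audio.samples - audio.samples.mean()
    fs = audio.fs
    energy, periodicity, lags, frame, hop = _frame_voicing(
        x, fs, cfg.pitch_frame_s, cfg.pitch_hop_s, cfg)
    if not len(energy):
        return PitchPeriodSequence(np.empty(0), 0.0, flag="poor phonation")
    e_ref = energy.max()
    voiced = (periodicity > cfg.voicing_corr_threshold) & \
             (energy > cfg.voicing_rel_energy * max(e_ref, 1e-30))
    vf = float(voiced.mean())
    flag = "poor phonation" if vf < cfg.min_voiced_fraction else None
    if not voiced.any():
        return PitchPeriodSequence(np.empty(0), vf, flag=flag)

    lag_med = float(np.median(lags[voiced]))
    # sample-level voiced mask from frame decisions
    mask = np.zeros(len(x), dtype=bool)
    for i in np.flatnonzero(voiced):
        mask[i * hop:i * hop + frame] = True
    amp_ref = np.percentile(np.abs(x[mask]), 95)
    peaks, _ = find_peaks(x, distance=max(int(0.7 * lag_med), 1),
                          height=0.3 * amp_ref)
    peaks = peaks[mask[peaks]]
    if len(peaks) < 3:
        return PitchPeriodSequence(np.empty(0), vf, flag=flag or "poor phonation")
    periods_ms = np.diff(peaks) / fs * 1000.0
    lo, hi = cfg.period_bounds_ms
    keep = (periods_ms >= lo) & (periods_ms <= hi)
    # also drop cycles spanning voicing gaps (implausibly long vs. running median)
    med = np.median(periods_ms[keep]) if keep.any() else np.inf
    keep &= periods_ms <= 1.8 * med
    return PitchPeriodSequence(periods_ms[keep], vf, flag=flag)


def voice_jitter(periods: PitchPeriodSequence) -> FeatureOutcome:
    """jitter:local — 100 * mean|p_{i+1} - p_i| / mean(p)."""
    p = periods.periods_ms
    if len(p) < 2:
        return FeatureOutcome(None, "%", flag="insufficient pitch cycles")
    value = 100.0 * float(np.abs(np.diff(p)).mean() / p.mean())
    return FeatureOutcome(value, "%", flag=periods.flag,
                          extras={"n_periods": int(len(p)),
                                  "voiced_fraction": periods.voiced_fraction})


# ---------------------------------------------------------------------------
# Voiced segmentation (speech)
# ---------------------------------------------------------------------------

def voiced_segments(audio: AudioSignal, min_dur: float | None = None,
                    cfg: AudioConfig = AUDIO) -> list[VoicedSegment]:
    """Energy+periodicity voicing per 25 ms frame, merged; short segments dropped."""
    if min_dur is None:
        min_dur = cfg.min_segment_s
    cache = _audio_cache(audio)
    key = ("segments", min_dur, cfg)
    if key in cache:
        return cache[key]
    result = _voiced_segments(audio, min_dur, cfg)
    cache[key] = result
    return result


def _voiced_segments(audio: AudioSignal, min_dur: float,
                     cfg: AudioConfig) -> list[VoicedSegment]:
    x = audio.samples - audio.samples.mean()
    energy, periodicity, _, frame, hop = _frame_voicing(
        x, audio.fs, cfg.seg_frame_s, cfg.seg_hop_s, cfg)
    if not len(energy):
        return []
    e_ref = energy.max()
    if e_ref <= 1e-30:
        return []
    voiced = (periodicity > 0.25) & (energy > cfg.voicing_rel_energy * e_ref)
    segs = []
    for i0, i1 in contiguous_runs(voiced):
        start = i0 * hop / audio.fs
        end = ((i1 - 1) * hop + frame) / audio.fs
        if end - start > min_dur:
            segs.append(VoicedSegment(start_t=float(start), end_t=float(end)))
    return segs


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


@lru_cache(maxsize=16)
def _mel_filterbank(n_filters: int, nfft: int, fs: float,
                    fmin: float, fmax: float) -> np.ndarray:
    """Triangular mel filterbank, (n_filters, nfft//2 + 1)."""
    fmax = min(fmax, fs / 2.0)
    mels = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_filters + 2)
    hz = _mel_to_hz(mels)
    bins = np.floor((nfft + 1) * hz / fs).astype(int)
    fb = np.zeros((n_filters, nfft // 2 + 1))
    for i in range(n_filters):
        left, center, right = bins[i], bins[i + 1], bins[i + 2]
        if center > left:
            fb[i, left:center] = (np.arange(left, center) - left) / (center - left)
        if right > center:
            fb[i, center:right] = (right - np.arange(center, right)) / (right - center)
    return fb


def mfcc(audio: AudioSignal, cfg: AudioConfig = AUDIO):
    """Per-frame MFCCs.  Returns (frame_center_times, coefficients).

    Coefficient 0 (C0) is the gain term; downstream features exclude it and
    index the remaining coefficients 1-based, so "MFCC2" is DCT row 2.
    """
    x = audio.samples - audio.samples.mean()
    fs = audio.fs
    frame = int(round(cfg.mfcc_frame_s * fs))
    hop = int(round(cfg.mfcc_hop_s * fs))
    frames = frame_signal(x, frame, hop)
    if not len(frames):
        return np.empty(0), np.empty((0, cfg.mfcc_n_filters))
    win = get_window("hamming", frame, fftbins=True)
    nfft = sp_fft.next_fast_len(frame)
    power = np.abs(sp_fft.rfft(frames * win, n=nfft, axis=1)) ** 2
    fb = _mel_filterbank(cfg.mfcc_n_filters, nfft, float(fs),
                         cfg.mfcc_fmin_hz, cfg.mfcc_fmax_hz)
    mel_energy = power @ fb.T
    log_mel = np.log(np.maximum(mel_energy, 1e-30))
    coeffs = sp_fft.dct(log_mel, type=2, axis=1, norm="ortho")
    times = (np.arange(len(frames)) * hop + frame / 2) / fs
    return times, coeffs


def _question_mfcc2_variability(audio: AudioSignal, cfg: AudioConfig):
    segs = voiced_segments(audio, cfg=cfg)
    if len(segs) < 2:
        return None, segs
    times, coeffs = mfcc(audio, cfg)
    c2 = coeffs[:, cfg.mfcc_coefficient]
    means = []
    for seg in segs:
        sel = (times >= seg.start_t) & (times <= seg.end_t)
        if sel.any():
            seg.mean_mfcc2 = float(c2[sel].mean())
            means.append(seg.mean_mfcc2)
    if len(means) < 2:
        return None, segs
    return float(np.std(means, ddof=1)), segs


def mfcc2_variability(audio, cfg: AudioConfig = AUDIO) -> FeatureOutcome:
    """SD of per-segment MFCC2 means (dimensionless; lower = more monotone).

    ``audio`` is one :class:`AudioSignal` or a list of them (one per speech
    question); per-question values are averaged.  Fewer than two voiced
    segments in every question makes the feature undefined.
    """
    questions = audio if isinstance(audio, (list, tuple)) else [audio]
    values = []
    n_segments = 0
    for q in questions:
        v, segs = _question_mfcc2_variability(q, cfg)
        n_segments += len(segs)
        if v is not None:
            values.append(v)
    if not values:
        return FeatureOutcome(None, "", flag="insufficient speech",
                              extras={"n_segments": n_segments})
    return FeatureOutcome(float(np.mean(values)), "",
                          extras={"n_segments": n_segments,
                                  "n_questions": len(values)})
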