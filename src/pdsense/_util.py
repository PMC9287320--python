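"""Shared helpers: feature outcome container and cached zero-phase filters."""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal


@dataclass
class FeatureOutcome:
    """Result of one feature extraction.

    ``value`` is None when the feature is undefined for the session; ``flag``
    then carries the reason (it may also carry a non-fatal flag such as
    "floor" alongside a defined value).
    """

    value: float | None
    unit: str
    flag: str | None = None
    extras: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.value is not None


@lru_cache(maxsize=256)
def _butter_design(order: int, cutoffs, btype: str, fs: float):
    sos = signal.butter(order, cutoffs, btype=btype, fs=fs, output="sos")
    return sos, signal.sosfilt_zi(sos)


def zero_phase_filter(x: np.ndarray, fs: float, cutoffs, btype: str,
                      order: int = 4, axis: int = 0) -> np.ndarray:
    """Forward-backward Butterworth filtering (phase-delay-free).

    Equivalent to ``scipy.signal.sosfiltfilt`` with odd-reflection padding,
    but with the filter design and initial conditions cached per
    (order, cutoff, type, fs) so repeated short-segment filtering is cheap.
    Cutoffs are clipped just below Nyquist so nominal bands remain usable at
    low sampling rates.
    """
    nyq = fs / 2.0
    c = np.atleast_1d(np.asarray(cutoffs, dtype=float))
    c = np.clip(c, 1e-6, nyq * 0.99)
    if btype in ("bandpass", "bandstop") and c[0] >= c[1]:
        raise ValueError("invalid band")
    cut = float(c[0]) if len(c) == 1 else tuple(float(v) for v in c)
    sos, zi = _butter_design(order, cut, btype, float(fs))

    x = np.asarray(x, dtype=float)
    if axis != 0:
        x = np.moveaxis(x, axis, 0)
    squeeze = x.ndim == 1
    x2 = x[:, None] if squeeze else x
    n = x2.shape[0]
    padlen = min(3 * (2 * order + 1), max(n - 2, 0))
    # odd reflection about the end points
    ext = np.concatenate([2 * x2[0] - x2[1:padlen + 1][::-1], x2,
                          2 * x2[-1] - x2[-padlen - 1:-1][::-1]], axis=0) \
        if padlen > 0 else x2
    zi_shaped = zi[:, :, None]
    y, _ = signal.sosfilt(sos, ext, axis=0, zi=zi_shaped * ext[0])
    y = y[::-1]
    y, _ = signal.sosfilt(sos, y, axis=0, zi=zi_shaped * y[0])
    y = y[::-1]
    if padlen > 0:
        y = y[padlen:-padlen]
    if squeeze:
        y = y[:, 0]
    if axis != 0:
        y = np.moveaxis(y, 0, axis)
    return np.ascontiguousarray(y)


def frame_signal(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    """(n_frames, frame) view of 1-D ``x`` (no copy)."""
    if len(x) < frame:
        return np.empty((0, frame))
    n_frames = 1 + (len(x) - frame) // hop
    return np.lib.stride_tricks.as_strided(
        x, shape=(n_frames, frame),
        strides=(x.strides[0] * hop, x.strides[0]), writeable=False)


def contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs in a boolean vector."""
    if not len(mask):
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))
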