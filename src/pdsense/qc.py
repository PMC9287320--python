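"""Pre-feature quality control.

Every session yields a map of QC metrics (always computable, possibly 0):

* ``movement_energy`` — mean gravity-removed squared acceleration magnitude,
  computed for every inertial test; the default thresholds gate it for Hand
  Turning and U-turn only, where a still phone means the test was not
  performed (a phone lying on a table).
* ``tap_count`` (Dexterity), ``trace_length`` px (Draw A Shape),
  ``voiced_fraction`` (Phonation/Speech), and a ``duration_ratio``
  (recorded/expected) for every test.

``apply_qc`` partitions sessions into retained and excluded sets against
(low, high) threshold bounds; a session is excluded on its first failing
metric (full metric maps are kept for audit).  Tightening any threshold can
only shrink the retained set.  Default thresholds in :mod:`pdsense.config`
are calibrated once against the synthetic cohort so correctly executed
sessions pass at well over 99%; only the movement-energy check mirrors a
published QC example, the rest of the metric list is this package's design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import FIXED_DURATION_TESTS, QC_DEFAULTS
from .audio_features import detect_pitch_periods, voiced_segments
from .session_model import (AudioSignal, InertialStream, SdmtResponses,
                            TestSession, TouchTrace)

__all__ = ["qc_metrics", "apply_qc", "QCResult"]

KNOWN_METRICS = ("movement_energy", "tap_count", "trace_length",
                 "voiced_fraction", "duration_ratio")


def _movement_energy(stream: InertialStream) -> float:
    # gravity removal by per-axis session mean: active tests hold one posture,
    # so the mean acceleration is the gravity vector to good approximation
    if len(stream.t) < 8:
        return 0.0
    dyn = stream.acc - stream.acc.mean(axis=0)
    return float((dyn ** 2).sum(axis=1).mean())


def _payload_duration(payload) -> float:
    if isinstance(payload, (InertialStream, TouchTrace, AudioSignal)):
        return payload.duration
    if isinstance(payload, list):
        return sum(a.duration for a in payload)
    if isinstance(payload, SdmtResponses):
        return max((t for t, _, _ in payload.responses), default=0.0)
    return 0.0


def qc_metrics(session: TestSession,
               expected_durations: dict | None = None) -> dict[str, float]:
    """Per-test QC metric map; metrics are always computable (possibly 0).

    ``expected_durations`` maps test name to the expected recording length
    in seconds for the duration-ratio check (default: the fixed-length tests
    of the standard protocol); tests absent from the map skip the check.
    """
    if expected_durations is None:
        expected_durations = FIXED_DURATION_TESTS
    p = session.payload
    metrics: dict[str, float] = {}
    expected = expected_durations.get(session.test_name)
    if expected:
        metrics["duration_ratio"] = _payload_duration(p) / expected

    if isinstance(p, InertialStream):
        metrics["movement_energy"] = _movement_energy(p)
    elif isinstance(p, TouchTrace):
        if session.test_name == "dexterity":
            metrics["tap_count"] = float(len(p.down_times()))
        else:
            if len(p.t) > 1:
                steps = np.hypot(np.diff(p.x), np.diff(p.y))
                metrics["trace_length"] = float(steps.sum())
            else:
                metrics["trace_length"] = 0.0
    elif isinstance(p, AudioSignal):
        metrics["voiced_fraction"] = detect_pitch_periods(p).voiced_fraction
    elif isinstance(p, list) and all(isinstance(a, AudioSignal) for a in p):
        total = sum(a.duration for a in p)
        voiced = sum(sum(s.duration for s in voiced_segments(a)) for a in p)
        metrics["voiced_fraction"] = voiced / total if total > 0 else 0.0
    return metrics


@dataclass
class QCResult:
    retained: list = field(default_factory=list)
    excluded: list = field(default_factory=list)     # (session, metric, value, bound)
    metrics: list = field(default_factory=list)      # per-session metric maps

    @property
    def exclusion_rate(self) -> float:
        total = len(self.retained) + len(self.excluded)
        return len(self.excluded) / total if total else 0.0


def apply_qc(sessions, thresholds: dict | None = None,
             expected_durations: dict | None = None) -> QCResult:
    """Partition sessions by QC thresholds.

    ``thresholds`` maps a metric name — or ``test_name:metric`` for a
    test-scoped bound — to (low, high); either bound may be None.  A session
    is excluded with the first failing metric as reason (metric iteration
    order follows the thresholds dict).  Unknown metric names are a
    configuration error.
    """
    if thresholds is None:
        thresholds = QC_DEFAULTS.thresholds
    for key in thresholds:
        metric = key.split(":", 1)[-1]
        if metric not in KNOWN_METRICS:
            raise ValueError(f"unknown QC metric in thresholds: {key!r}")

    result = QCResult()
    for session in sessions:
        m = qc_metrics(session, expected_durations)
        result.metrics.append(m)
        failure = None
        for key, (low, high) in thresholds.items():
            test_scope, _, metric = key.rpartition(":")
            if test_scope and test_scope != session.test_name:
                continue
            if metric not in m:
                continue
            v = m[metric]
            if (low is not None and v < low) or (high is not None and v > high):
                failure = (session, metric, v, (low, high))
                break
        if failure is None:
            result.retained.append(session)
        else:
            result.excluded.append(failure)
    return result
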