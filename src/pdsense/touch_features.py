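"""Touchscreen-test features.

Three active tests produce touchscreen traces:

* **Dexterity** — alternate tapping of two on-screen buttons for 20 s per
  hand.  Feature: *tapping variability*, the sample standard deviation of
  consecutive inter-tap intervals (ms).  Larger values mean less regular
  tapping, a bradykinesia sign.
* **Draw A Shape** — tracing six shapes with the index finger.  The
  pre-specified feature is *spiral celerity*: drawing accuracy divided by
  completion time (1/s).  Accuracy is bounded in (0, 1] and defined as
  ``1 / (1 + dbar/w)`` where ``dbar`` is the mean orthogonal distance of
  touch points to the template polyline and ``w`` the template tolerance
  radius; drawing exactly on the path gives accuracy 1.
* **eSDMT** — symbol-digit substitution for 90 s.  Feature: number of
  correct responses.

Only tap *down* events enter the inter-tap intervals: the down event marks
tapping intent while up timing varies with dwell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from ._util import FeatureOutcome
from .session_model import SdmtResponses, TouchTrace

__all__ = ["ShapeTemplate", "tapping_variability", "shape_celerity",
           "sdmt_correct", "load_shape_template", "point_polyline_distance"]

SHAPE_NAMES = ("line_up", "line_down", "square", "circle", "figure8", "spiral")


@dataclass
class ShapeTemplate:
    """Target path for a Draw A Shape trial."""

    name: str
    waypoints: np.ndarray          # (n, 2) px
    tolerance_px: float = 20.0

    def __post_init__(self) -> None:
        self.waypoints = np.asarray(self.waypoints, dtype=float).reshape(-1, 2)
        if len(self.waypoints) < 2:
            raise ValueError("template needs >= 2 waypoints")
        if (np.linalg.norm(np.diff(self.waypoints, axis=0), axis=1) == 0).any():
            raise ValueError("consecutive waypoints must be distinct")
        if self.tolerance_px <= 0:
            raise ValueError("tolerance must be > 0")


def load_shape_template(name: str) -> ShapeTemplate:
    """Load one of the shipped shape templates by name."""
    if name not in SHAPE_NAMES:
        raise KeyError(name)
    text = resources.files("pdsense.resources").joinpath("shape_templates.json").read_text()
    obj = json.loads(text)[name]
    return ShapeTemplate(name=name, waypoints=np.asarray(obj["waypoints"]),
                         tolerance_px=float(obj["tolerance_px"]))


def tapping_variability(trace: TouchTrace, duration_s: float = 20.0) -> FeatureOutcome:
    """SD of consecutive inter-tap-down intervals, in milliseconds.

    All down events within the test window count regardless of whether the
    participant alternated buttons correctly.  Fewer than 3 down events make
    the feature undefined ("insufficient taps").
    """
    downs = trace.down_times()
    if len(downs):
        downs = downs[downs <= downs[0] + duration_s]
    if len(downs) < 3:
        return FeatureOutcome(None, "ms", flag="insufficient taps")
    intervals_ms = np.diff(downs) * 1000.0
    return FeatureOutcome(float(np.std(intervals_ms, ddof=1)), "ms",
                          extras={"n_taps": int(len(downs))})


def point_polyline_distance(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Orthogonal distance of each point to the nearest polyline segment."""
    p = np.asarray(points, dtype=float).reshape(-1, 2)
    a = polyline[:-1]                        # (m, 2) segment starts
    b = polyline[1:]                         # (m, 2) segment ends
    ab = b - a                               # (m, 2)
    denom = (ab ** 2).sum(axis=1)            # (m,)
    # (n, m) projection parameter, clipped to the segment
    ap = p[:, None, :] - a[None, :, :]
    tproj = np.clip((ap * ab[None, :, :]).sum(-1) / denom[None, :], 0.0, 1.0)
    closest = a[None, :, :] + tproj[..., None] * ab[None, :, :]
    d = np.linalg.norm(p[:, None, :] - closest, axis=-1)
    return d.min(axis=1)


def shape_celerity(trace: TouchTrace, template: ShapeTemplate,
                   timeout_s: float = 30.0) -> FeatureOutcome:
    """Accuracy per unit completion time (1/s) for one continuous drawing.

    accuracy = 1 / (1 + dbar/w); completion time = last-event t - first-event t.
    Completion beyond the timeout is truncated at the timeout and flagged.
    """
    if len(trace.t) == 0:
        return FeatureOutcome(None, "1/s", flag="empty trace")
    duration = trace.duration
    if duration <= 0:
        return FeatureOutcome(None, "1/s", flag="no movement")
    flag = None
    keep = trace.t <= trace.t[0] + timeout_s
    if not keep.all():
        flag = "timeout"
        duration = timeout_s
    pts = np.column_stack([trace.x[keep], trace.y[keep]])
    dbar = float(point_polyline_distance(pts, template.waypoints).mean())
    accuracy = 1.0 / (1.0 + dbar / template.tolerance_px)
    return FeatureOutcome(accuracy / duration, "1/s", flag=flag,
                          extras={"accuracy": accuracy, "mean_distance_px": dbar,
                                  "completion_s": duration})


def sdmt_correct(responses, key: dict | None = None,
                 duration_s: float = 90.0) -> FeatureOutcome:
    """Number of correct symbol->digit responses within the test window.

    ``responses`` is either an :class:`SdmtResponses` (key embedded) or a list
    of ``(symbol_index, answered_digit)`` / ``(t, symbol_index, answered_digit)``
    tuples with ``key`` given separately.  Responses after ``duration_s`` are
    discarded, not errors.
    """
    if isinstance(responses, SdmtResponses):
        key = responses.key
        responses = responses.responses
    if key is None:
        raise ValueError("key required")
    count = 0
    for resp in responses:
        if len(resp) == 3:
            t, symbol, digit = resp
            if t > duration_s:
                continue
        else:
            symbol, digit = resp
        if key.get(symbol) == digit:
            count += 1
    return FeatureOutcome(float(count), "count",
                          extras={"n_responses": len(responses)})
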