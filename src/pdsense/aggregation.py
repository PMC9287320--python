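"""Fortnightly aggregation, affected-side assignment, schedule, adherence.

Daily feature values are summarised as the median over contiguous 2-week
windows anchored at the baseline visit (window 1 = days 1-14, window 2 =
days 15-28).  A window's median is reported only when at least 3 data points
fell in it; the fortnightly eSDMT, which can contribute at most one point per
window, is exempt from that rule (per-feature ``min_points`` in config).

Lateralized features are relabelled from left/right to the participant's
more/less affected side, defined as the side with the larger sum of the
lateralized MDS-UPDRS Part III item scores (3.4, 3.5, 3.6, 3.15, 3.17); ties
fall back to the side contralateral to self-reported onset when available,
else to the right side.  The mapping is applied uniformly to all lateralized
features of a participant.

Adherence is the share of fully completed scheduled active-test sessions.
The baseline visit day (day 1) is performed in clinic, so the remote-testing
denominator over a 28-day span is 27 days; both a session-level and a
day-level percentage are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (ESDMT_PERIOD_DAYS, FEATURE_MIN_POINTS, LATERALIZED_TESTS,
                     LATERALIZED_PART3_ITEMS, MOTOR_HALF_A, MOTOR_HALF_B)
from .session_model import ClinicalRecord, FeatureRecord

__all__ = ["FortnightWindow", "Schedule", "aggregate_fortnight",
           "aggregate_windows", "assign_sides", "more_affected_side",
           "adherence"]


@dataclass(frozen=True)
class FortnightWindow:
    """2-week aggregation window anchored at the baseline visit."""

    index: int                 # 1 or 2

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("window index is 1-based")

    @property
    def day_range(self) -> tuple[int, int]:
        first = (self.index - 1) * 14 + 1
        return first, first + 13

    def contains(self, day: int) -> bool:
        a, b = self.day_range
        return a <= day <= b


@dataclass(frozen=True)
class Schedule:
    """Expected active tests per study day.

    Motor-test halves alternate daily (half A on odd days); the eSDMT runs on
    days 1, 15, ...  Lateralized tests expect one session per side.
    """

    n_days: int = 28
    half_a: tuple = MOTOR_HALF_A
    half_b: tuple = MOTOR_HALF_B

    def expected_sessions(self, day: int) -> list[tuple[str, str]]:
        if not 1 <= day <= self.n_days:
            return []
        tests = self.half_a if day % 2 == 1 else self.half_b
        out = []
        for t in tests:
            if t in LATERALIZED_TESTS:
                out.append((t, "left"))
                out.append((t, "right"))
            else:
                out.append((t, "none"))
        if (day - 1) % ESDMT_PERIOD_DAYS == 0:
            out.append(("esdmt", "none"))
        return out


# ---------------------------------------------------------------------------
# Fortnightly medians
# ---------------------------------------------------------------------------

def aggregate_fortnight(records, window: FortnightWindow,
                        min_points: dict | None = None) -> pd.DataFrame:
    """Median per (participant, feature, side) over one window.

    Returns a DataFrame with columns participant_id, feature_name, side,
    window, value, n; ``value`` is NaN when fewer than the feature's minimum
    number of QC-passed points fell in the window.
    """
    if min_points is None:
        min_points = FEATURE_MIN_POINTS
    rows = []
    grouped: dict[tuple, list[float]] = {}
    for r in records:
        if not (r.qc_pass and r.value is not None):
            continue
        if not window.contains(r.day_index):
            continue
        grouped.setdefault((r.participant_id, r.feature_name, r.side), []).append(r.value)
    for (pid, feat, side), values in grouped.items():
        need = min_points.get(feat, 3)
        value = float(np.median(values)) if len(values) >= need else np.nan
        rows.append({"participant_id": pid, "feature_name": feat, "side": side,
                     "window": window.index, "value": value, "n": len(values)})
    return pd.DataFrame(rows, columns=["participant_id", "feature_name", "side",
                                       "window", "value", "n"])


def aggregate_windows(records, windows=(1, 2),
                      min_points: dict | None = None) -> pd.DataFrame:
    """Fortnightly medians for several windows, concatenated."""
    parts = [df for w in windows
             if len(df := aggregate_fortnight(records, FortnightWindow(w),
                                              min_points))]
    if not parts:
        return pd.DataFrame(columns=["participant_id", "feature_name", "side",
                                     "window", "value", "n"])
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Affected-side assignment
# ---------------------------------------------------------------------------

def more_affected_side(clinical: ClinicalRecord,
                       onset_side: str | None = None) -> tuple[str, bool]:
    """(more-affected side, tie flag) from lateralized Part III sums."""
    items = clinical.mds_updrs_items
    lsum = rsum = 0
    found = False
    for item in LATERALIZED_PART3_ITEMS:
        if item + "L" in items or item + "R" in items:
            found = True
        lsum += items.get(item + "L", 0)
        rsum += items.get(item + "R", 0)
    if not found:
        raise ValueError("cannot lateralize: no lateralized Part III items")
    if lsum > rsum:
        return "left", False
    if rsum > lsum:
        return "right", False
    if onset_side in ("left", "right"):
        return onset_side, True
    return "right", True          # documented default on full ties


def assign_sides(records, clinical: ClinicalRecord,
                 onset_side: str | None = None) -> list[FeatureRecord]:
    """Relabel left/right feature records to more/less affected side.

    Records already carrying more/less (or none) pass through unchanged, so
    applying the assignment twice equals applying it once.
    """
    more, _tie = more_affected_side(clinical, onset_side)
    out = []
    for r in records:
        if r.side in ("left", "right"):
            side = "more" if r.side == more else "less"
            out.append(FeatureRecord(
                participant_id=r.participant_id, feature_name=r.feature_name,
                side=side, day_index=r.day_index, value=r.value, unit=r.unit,
                qc_pass=r.qc_pass, qc_reason=r.qc_reason, extras=r.extras))
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Adherence
# ---------------------------------------------------------------------------

def adherence(sessions, schedule: Schedule | None = None,
              n_days: int = 28) -> dict:
    """Adherence of one participant's sessions against the schedule.

    Day 1 (baseline, in clinic) is excluded from the remote-testing
    denominator, leaving 27 testing days for a 28-day span.  Completing
    unscheduled extra sessions never raises adherence above 100%.
    Returns session-level and day-level percentages with their counts.
    """
    if schedule is None:
        schedule = Schedule(n_days=n_days)
    completed = {(s.day_index, s.test_name, s.body_side)
                 for s in sessions if s.completed}
    days = range(2, n_days + 1)
    n_expected = n_done = 0
    days_expected = days_done = 0
    for day in days:
        expected = schedule.expected_sessions(day)
        if not expected:
            continue
        days_expected += 1
        done = sum((day, t, side) in completed for t, side in expected)
        n_expected += len(expected)
        n_done += min(done, len(expected))
        if done >= len(expected):
            days_done += 1
    if n_expected == 0:
        return {"session_pct": None, "day_pct": None,
                "sessions_completed": 0, "sessions_expected": 0,
                "days_completed": 0, "days_expected": 0}
    return {
        "session_pct": 100.0 * n_done / n_expected,
        "day_pct": 100.0 * days_done / days_expected,
        "sessions_completed": n_done, "sessions_expected": n_expected,
        "days_completed": days_done, "days_expected": days_expected,
    }
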