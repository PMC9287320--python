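"""End-to-end pipeline: sessions -> QC -> features -> aggregation -> validation.

This is the orchestration layer the CLI and the acceptance checks run: it
dispatches each test session to its feature extractor, applies the QC gate to
active tests, relabels lateralized features to more/less affected side,
aggregates over the two fortnights, and assembles the cohort table for the
validation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregation import Schedule, adherence, aggregate_windows, assign_sides
from .audio_features import detect_pitch_periods, mfcc2_variability, voice_jitter
from .config import FEATURE_DEFS, QC_DEFAULTS
from .motion_features import hand_turn_speed, sway_jerk, tremor_energy, uturn_speed
from .passive_monitoring import (arm_movement_power, daily_turn_speed,
                                 detect_gait_bouts, wear_time)
from .qc import apply_qc
from .session_model import BundleData, FeatureRecord, TestSession
from .touch_features import (load_shape_template, sdmt_correct, shape_celerity,
                             tapping_variability)
from .validation_stats import build_cohort_table, validity_report

__all__ = ["extract_features", "process_bundle", "run_cohort_pipeline",
           "CohortResult"]

ACTIVE_TESTS_WITH_QC = ("draw_a_shape", "dexterity", "hand_turning", "speech",
                        "phonation", "postural_tremor", "rest_tremor",
                        "balance", "u_turn", "esdmt")


def extract_features(session: TestSession,
                     spiral_template=None) -> list[FeatureRecord]:
    """Feature records (raw left/right side labels) for one session."""
    t = session.test_name
    out: list[tuple[str, object]] = []
    extras: dict = {}
    if t == "dexterity":
        out.append(("tapping_variability", tapping_variability(session.payload)))
    elif t == "draw_a_shape":
        if spiral_template is None:
            spiral_template = load_shape_template("spiral")
        out.append(("spiral_celerity", shape_celerity(session.payload, spiral_template)))
    elif t == "hand_turning":
        out.append(("hand_turning_speed", hand_turn_speed(session.payload)))
    elif t == "postural_tremor":
        out.append(("postural_tremor_energy", tremor_energy(session.payload)))
    elif t == "rest_tremor":
        out.append(("rest_tremor_energy", tremor_energy(session.payload)))
    elif t == "balance":
        out.append(("sway_jerk", sway_jerk(session.payload)))
    elif t == "u_turn":
        out.append(("uturn_speed", uturn_speed(session.payload)))
    elif t == "phonation":
        out.append(("voice_jitter", voice_jitter(detect_pitch_periods(session.payload))))
    elif t == "speech":
        out.append(("mfcc2_variability", mfcc2_variability(session.payload)))
    elif t == "esdmt":
        out.append(("esdmt_correct", sdmt_correct(session.payload)))
    elif t == "passive_phone":
        mask = detect_gait_bouts(session.payload)
        out.append(("passive_turn_speed", daily_turn_speed(session.payload, mask)))
        extras["wear_phone_h"] = wear_time(session.payload, mask).value
    elif t == "passive_watch":
        mask = detect_gait_bouts(session.payload)
        out.append(("arm_movement_power", arm_movement_power(session.payload, mask)))
        extras["wear_watch_h"] = wear_time(session.payload, mask).value
    else:
        return []

    records = []
    for name, outcome in out:
        records.append(FeatureRecord(
            participant_id=session.participant_id, feature_name=name,
            side=session.body_side, day_index=session.day_index,
            value=outcome.value, unit=FEATURE_DEFS[name]["unit"],
            qc_pass=outcome.value is not None, qc_reason=outcome.flag,
            extras={**outcome.extras, **extras}))
    return records


@dataclass
class BundleResult:
    records: list = field(default_factory=list)
    clinical: object = None
    adherence: dict | None = None
    qc_excluded: list = field(default_factory=list)
    n_active_sessions: int = 0
    wear_phone_h: list = field(default_factory=list)
    wear_watch_h: list = field(default_factory=list)


def process_bundle(bundle: BundleData, qc_thresholds: dict | None = None,
                   schedule: Schedule | None = None,
                   spiral_template=None,
                   expected_durations: dict | None = None) -> BundleResult:
    """QC + feature extraction + side assignment for one participant."""
    if qc_thresholds is None:
        qc_thresholds = QC_DEFAULTS.thresholds
    if spiral_template is None:
        spiral_template = load_shape_template("spiral")

    active = [s for s in bundle.sessions if s.test_name in ACTIVE_TESTS_WITH_QC]
    passive = [s for s in bundle.sessions if s.test_name not in ACTIVE_TESTS_WITH_QC]
    qc_res = apply_qc(active, qc_thresholds, expected_durations)

    result = BundleResult(clinical=bundle.clinical,
                          n_active_sessions=len(active),
                          qc_excluded=qc_res.excluded)
    for session in qc_res.retained + passive:
        for rec in extract_features(session, spiral_template):
            if "wear_phone_h" in rec.extras:
                result.wear_phone_h.append(rec.extras["wear_phone_h"])
            if "wear_watch_h" in rec.extras:
                result.wear_watch_h.append(rec.extras["wear_watch_h"])
            result.records.append(rec)

    if bundle.clinical is not None:
        result.records = assign_sides(result.records, bundle.clinical)
    if schedule is None:
        n_days = max((s.day_index for s in bundle.sessions), default=28)
        schedule = Schedule(n_days=max(n_days, 2))
    result.adherence = adherence(active, schedule, n_days=schedule.n_days)
    return result


@dataclass
class CohortResult:
    """Cohort-level products of the full pipeline."""

    aggregated: pd.DataFrame
    cohort_table: pd.DataFrame
    validation_rows: list
    matrix: pd.DataFrame
    adherence_day_pct: list
    adherence_session_pct: list
    qc_exclusion_rate: float
    wear_phone_h: float | None
    wear_watch_h: float | None

    @property
    def median_adherence_pct(self) -> float:
        return float(np.median(self.adherence_day_pct))

    def summary(self) -> dict:
        iccs = np.array([r.icc for r in self.validation_rows], dtype=float)
        rhos = np.array([r.rho for r in self.validation_rows], dtype=float)
        ok = np.isfinite(iccs)
        directions = [r.direction_expected for r in self.validation_rows]
        return {
            "n_features": len(self.validation_rows),
            "median_icc": float(np.median(iccs[ok])) if ok.any() else None,
            "icc_min": float(np.min(iccs[ok])) if ok.any() else None,
            "icc_max": float(np.max(iccs[ok])) if ok.any() else None,
            "abs_rho_min": float(np.nanmin(np.abs(rhos))),
            "abs_rho_max": float(np.nanmax(np.abs(rhos))),
            "n_direction_expected": int(sum(bool(d) for d in directions
                                            if d is not None)),
            "median_adherence_pct": self.median_adherence_pct,
            "median_session_adherence_pct": float(np.median(self.adherence_session_pct)),
            "qc_exclusion_rate_pct": 100.0 * self.qc_exclusion_rate,
            "wear_phone_h": self.wear_phone_h,
            "wear_watch_h": self.wear_watch_h,
        }


def run_cohort_pipeline(bundles: list[BundleData],
                        qc_thresholds: dict | None = None,
                        schedule: Schedule | None = None,
                        expected_durations: dict | None = None) -> CohortResult:
    """Process every bundle and compute the cohort validation statistics."""
    spiral = load_shape_template("spiral")
    all_records = []
    clinicals = []
    day_pct, sess_pct = [], []
    n_excluded = n_active = 0
    wear_p, wear_w = [], []
    for b in bundles:
        r = process_bundle(b, qc_thresholds, schedule, spiral, expected_durations)
        all_records.extend(r.records)
        if r.clinical is not None:
            clinicals.append(r.clinical)
        if r.adherence and r.adherence["day_pct"] is not None:
            day_pct.append(r.adherence["day_pct"])
            sess_pct.append(r.adherence["session_pct"])
        n_excluded += len(r.qc_excluded)
        n_active += r.n_active_sessions
        wear_p.extend(h for h in r.wear_phone_h if h is not None)
        wear_w.extend(h for h in r.wear_watch_h if h is not None)

    aggregated = aggregate_windows(all_records, windows=(1, 2))
    cohort = build_cohort_table(aggregated, clinicals)
    rows, matrix = validity_report(cohort)
    return CohortResult(
        aggregated=aggregated, cohort_table=cohort, validation_rows=rows,
        matrix=matrix, adherence_day_pct=day_pct, adherence_session_pct=sess_pct,
        qc_exclusion_rate=(n_excluded / n_active if n_active else 0.0),
        wear_phone_h=float(np.median(wear_p)) if wear_p else None,
        wear_watch_h=float(np.median(wear_w)) if wear_w else None)
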