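"""Pinned analysis configuration.

Every tunable of the feature-extraction and validation layers lives here so a
single place documents the numerical contract: filter bands, segmentation
thresholds, the active-test schedule split, the 17 pre-specified feature names,
their clinical comparator items and expected association directions, and the
default QC thresholds.  Values that the underlying methodology leaves open
(tremor band edges, turn-detection thresholds, QC cutoffs, MFCC recipe) are
deliberate package choices, documented in docs/methods.md, and overridable per
call where the function signatures expose them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

# ---------------------------------------------------------------------------
# Test catalogue
# ---------------------------------------------------------------------------

#: Active tests performed once per side of the body.
LATERALIZED_TESTS = frozenset(
    {"draw_a_shape", "dexterity", "hand_turning", "postural_tremor", "rest_tremor"}
)

#: All active-test names plus the passive modalities.
ALL_TESTS = (
    "draw_a_shape",
    "dexterity",
    "hand_turning",
    "speech",
    "phonation",
    "postural_tremor",
    "rest_tremor",
    "balance",
    "u_turn",
    "esdmt",
    "passive_phone",
    "passive_watch",
)

# Alternating-day split of the motor tests.  Which tests form which half is
# not dictated by the methodology; this split is an arbitrary, frozen choice.
MOTOR_HALF_A = ("dexterity", "hand_turning", "postural_tremor", "rest_tremor")
MOTOR_HALF_B = ("draw_a_shape", "phonation", "speech", "balance", "u_turn")

#: eSDMT is administered once per fortnight (study days 1, 15, ...).
ESDMT_PERIOD_DAYS = 14

#: Nominal test durations, seconds (per side where lateralized).
TEST_DURATIONS_S = {
    "draw_a_shape": 30.0,   # timeout
    "dexterity": 20.0,
    "hand_turning": 10.0,
    "speech": 60.0,         # three 20 s questions
    "phonation": 30.0,      # timeout
    "postural_tremor": 15.0,
    "rest_tremor": 15.0,
    "balance": 30.0,
    "u_turn": 60.0,
    "esdmt": 90.0,
}

# ---------------------------------------------------------------------------
# Pre-specified sensor features
# ---------------------------------------------------------------------------

#: Feature names, whether they are lateralized, and their units.
FEATURE_DEFS = {
    "spiral_celerity": {"test": "draw_a_shape", "lateralized": True, "unit": "1/s"},
    "tapping_variability": {"test": "dexterity", "lateralized": True, "unit": "ms"},
    "hand_turning_speed": {"test": "hand_turning", "lateralized": True, "unit": "rad/s"},
    "mfcc2_variability": {"test": "speech", "lateralized": False, "unit": ""},
    "voice_jitter": {"test": "phonation", "lateralized": False, "unit": "%"},
    "postural_tremor_energy": {"test": "postural_tremor", "lateralized": True,
                               "unit": "log(m^2/s^4)"},
    "rest_tremor_energy": {"test": "rest_tremor", "lateralized": True,
                           "unit": "log(m^2/s^4)"},
    "sway_jerk": {"test": "balance", "lateralized": False, "unit": "log(m^2/s^6)"},
    "uturn_speed": {"test": "u_turn", "lateralized": False, "unit": "rad/s"},
    "esdmt_correct": {"test": "esdmt", "lateralized": False, "unit": "count"},
    "passive_turn_speed": {"test": "passive_phone", "lateralized": False, "unit": "rad/s"},
    "arm_movement_power": {"test": "passive_watch", "lateralized": False, "unit": "m^2/s^3"},
}

def prespecified_feature_keys() -> list[tuple[str, str]]:
    """The 17 pre-specified (feature_name, side) rows, sides in {more, less, none}."""
    keys: list[tuple[str, str]] = []
    for name, d in FEATURE_DEFS.items():
        if d["lateralized"]:
            keys.append((name, "less"))
            keys.append((name, "more"))
        else:
            keys.append((name, "none"))
    return keys


#: Clinical comparator item for each pre-specified feature.  Lateralized
#: features compare against the same-side item.  The passive arm-movement
#: power maps to the *left-hand* pronation-supination item specifically (a
#: quirk of the pre-specification, reproduced deliberately and flagged).
FEATURE_ITEM_MAP = {
    "spiral_celerity": "3.5",
    "tapping_variability": "3.4",
    "hand_turning_speed": "3.6",
    "mfcc2_variability": "3.1",
    "voice_jitter": "3.1",
    "postural_tremor_energy": "3.15",
    "rest_tremor_energy": "3.17",
    "sway_jerk": "3.12",
    "uturn_speed": "3.14",
    "esdmt_correct": "1.1",
    "passive_turn_speed": "3.14",
    "arm_movement_power": "3.6L",
}

#: Expected sign of the Spearman correlation between each feature and its
#: comparator item score (severity up).  Speed/celerity/counts fall with
#: severity; variability/energy/jitter rise; MFCC2 variability falls (speech
#: becomes more monotone); arm-movement power falls (bradykinesia).
FEATURE_EXPECTED_SIGN = {
    "spiral_celerity": -1,
    "tapping_variability": +1,
    "hand_turning_speed": -1,
    "mfcc2_variability": -1,
    "voice_jitter": +1,
    "postural_tremor_energy": +1,
    "rest_tremor_energy": +1,
    "sway_jerk": +1,
    "uturn_speed": -1,
    "esdmt_correct": -1,
    "passive_turn_speed": -1,
    "arm_movement_power": -1,
}

#: Minimum data points per 2-week window for the aggregated value to be
#: reported.  Daily features use the >=3-point rule; the fortnightly eSDMT can
#: contribute at most one point per window, so the rule cannot apply to it.
FEATURE_MIN_POINTS = {name: (1 if name == "esdmt_correct" else 3) for name in FEATURE_DEFS}

# ---------------------------------------------------------------------------
# MDS-UPDRS item catalogue and subscales
# ---------------------------------------------------------------------------

#: Items carried by ClinicalRecord.  "L"/"R" suffix marks lateralized items.
MDS_UPDRS_ITEMS = (
    "1.1",                       # cognitive impairment
    "2.1", "2.2", "2.3",         # speech, saliva, chewing/swallowing
    "3.1", "3.2",                # speech, facial expression
    "3.3L", "3.3R",              # rigidity (upper extremities)
    "3.4L", "3.4R",              # finger tapping
    "3.5L", "3.5R",              # hand movements
    "3.6L", "3.6R",              # pronation-supination
    "3.12",                      # postural stability
    "3.14",                      # global spontaneity of movement (body bradykinesia)
    "3.15L", "3.15R",            # postural tremor
    "3.17L", "3.17R",            # rest tremor amplitude
)

#: Items whose left/right scores define the more-affected side.
LATERALIZED_PART3_ITEMS = ("3.4", "3.5", "3.6", "3.15", "3.17")

#: Bulbar composite: 2.1 Speech + 2.2 Saliva and Drooling + 2.3 Chewing and
#: Swallowing + 3.1 Speech + 3.2 Facial expression (range 0-20).
BULBAR_ITEMS = ("2.1", "2.2", "2.3", "3.1", "3.2")

#: Subscale groupings over the collected item subset.
SUBSCALE_ITEMS = {
    "bradykinesia": ("3.4L", "3.4R", "3.5L", "3.5R", "3.6L", "3.6R", "3.14"),
    "tremor": ("3.15L", "3.15R", "3.17L", "3.17R"),
    "rigidity": ("3.3L", "3.3R"),
    "pigd": ("3.12",),
    "bulbar": BULBAR_ITEMS,
}

# ---------------------------------------------------------------------------
# Signal-processing parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionConfig:
    """Inertial feature-extraction parameters."""

    tremor_band_hz: tuple[float, float] = (3.0, 12.0)
    sway_lowpass_hz: float = 3.5
    gravity_lowpass_hz: float = 0.25
    filter_order: int = 4
    # band-pass design order 2: forward-backward filtering doubles it to an
    # effective 4th-order zero-phase response with a flat in-band gain
    tremor_filter_order: int = 2
    # hand turning
    hand_turn_highpass_hz: float = 0.5
    hand_turn_hysteresis_rad_s: float = 0.1
    hand_turn_min_angle_rad: float = math.pi / 4
    # turn detection (U-turn active test and passive gait)
    turn_min_angle_rad: float = math.radians(140.0)
    turn_min_rate_rad_s: float = 0.2
    log_floor: float = 1e-12


@dataclass(frozen=True)
class AudioConfig:
    """Pitch-tracking, voicing and MFCC recipe (fully pinned for reproducibility)."""

    pitch_fmin_hz: float = 50.0
    pitch_fmax_hz: float = 500.0
    pitch_frame_s: float = 0.040
    pitch_hop_s: float = 0.010
    voicing_corr_threshold: float = 0.30
    voicing_rel_energy: float = 1e-3   # frame energy vs. max frame energy
    min_voiced_fraction: float = 0.5
    period_bounds_ms: tuple[float, float] = (2.0, 20.0)
    # voiced segmentation for speech
    seg_frame_s: float = 0.025
    seg_hop_s: float = 0.010
    min_segment_s: float = 0.2
    # MFCC
    mfcc_frame_s: float = 0.025
    mfcc_hop_s: float = 0.010
    mfcc_n_filters: int = 26
    mfcc_fmin_hz: float = 0.0
    mfcc_fmax_hz: float = 8000.0
    mfcc_coefficient: int = 2          # 1-based after excluding C0


@dataclass(frozen=True)
class PassiveConfig:
    """Passive-monitoring segmentation thresholds."""

    gait_band_hz: tuple[float, float] = (1.4, 2.5)
    gait_window_s: float = 6.0
    gait_peak_fraction: float = 0.30   # spectral power fraction at dominant peak
    gait_min_amplitude: float = 0.5    # m/s^2 RMS in window
    idle_var_threshold: float = 0.02   # (m/s^2)^2; below -> idle (or off-body)
    off_body_var_threshold: float = 1e-5
    off_body_min_s: float = 300.0
    movement_amp_threshold: float = 0.15   # m/s^2, gravity-removed |a|
    movement_min_s: float = 0.25
    movement_max_s: float = 10.0
    min_gait_s_for_turns: float = 60.0
    min_wear_hours: float = 4.0


#: Tests with a fixed recording length, eligible for the duration-ratio check
#: (timeout-bounded tests like Draw A Shape or Phonation legitimately end early).
FIXED_DURATION_TESTS = {
    "dexterity": 20.0, "hand_turning": 10.0, "postural_tremor": 15.0,
    "rest_tremor": 15.0, "balance": 30.0, "u_turn": 60.0, "speech": 60.0,
}


@dataclass(frozen=True)
class QCConfig:
    """Default QC thresholds: (low, high) bounds, None = unbounded.

    Keys are either a metric name (applies to every session carrying the
    metric) or ``test_name:metric`` (applies to that test only).  The
    movement-energy gate targets tests where the phone must move — it is the
    "phone lying on a table" check — so it is scoped to Hand Turning and
    U-turn; a still phone is indistinguishable from correct execution of the
    tremor and balance tests at rest.  Calibrated once against the synthetic
    cohort so correctly executed sessions pass at > 99%, echoing an exclusion
    rate on the order of 0.3%.
    """

    thresholds: dict = field(default_factory=lambda: {
        "hand_turning:movement_energy": (0.05, None),   # (m/s^2)^2
        "u_turn:movement_energy": (0.3, None),
        "tap_count": (3, None),
        "trace_length": (50.0, None),                   # px
        "voiced_fraction": (0.3, None),
        "duration_ratio": (0.5, None),
    })


MOTION = MotionConfig()
AUDIO = AudioConfig()
PASSIVE = PassiveConfig()
QC_DEFAULTS = QCConfig()
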