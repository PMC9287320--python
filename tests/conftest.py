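"""Shared fixtures: small deterministic signals and a mini simulated bundle."""

from __future__ import annotations

import numpy as np
import pytest

from pdsense.session_model import InertialStream, TestSession, TouchTrace

TestSession.__test__ = False          # dataclass, not a pytest test class
from pdsense.synthetic_cohort import CohortSimConfig, simulate_participant
from pdsense.touch_features import load_shape_template


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def spiral_template():
    return load_shape_template("spiral")


@pytest.fixture(scope="session")
def mini_bundle():
    """One simulated participant at desk scale (6-day schedule)."""
    cfg = CohortSimConfig.sign_recovery(1)
    bundle, truth = simulate_participant(cfg, master_seed=7, participant_index=0)
    return cfg, bundle, truth


def make_stream(t, acc, gyro=None, fs_nominal=100.0) -> InertialStream:
    t = np.asarray(t, dtype=float)
    acc = np.asarray(acc, dtype=float)
    if acc.ndim == 1:
        acc = np.column_stack([acc, np.zeros_like(t), np.zeros_like(t)])
    if gyro is None:
        gyro = np.zeros((len(t), 3))
    else:
        gyro = np.asarray(gyro, dtype=float)
        if gyro.ndim == 1:
            gyro = np.column_stack([gyro, np.zeros_like(t), np.zeros_like(t)])
    return InertialStream(t=t, acc=acc, gyro=gyro, fs_nominal=fs_nominal)


def tap_trace(times, screen=(1080.0, 1920.0)) -> TouchTrace:
    """Down/up event pairs at the given down times."""
    times = np.asarray(times, dtype=float)
    t, kind, target = [], [], []
    for i, td in enumerate(times):
        t += [td, td + 0.02]
        kind += ["down", "up"]
        target += ["A" if i % 2 == 0 else "B"] * 2
    n = len(t)
    return TouchTrace(t=np.array(t), x=np.full(n, 500.0), y=np.full(n, 1500.0),
                      kind=np.array(kind, dtype=object),
                      target=np.array(target, dtype=object), screen=screen)
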