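"""Domain types and session-bundle I/O.

A *session bundle* is one participant's raw data for the whole observation
period, stored as an inspectable directory::

    bundle/
      manifest.json          participant id, schedule, session index
      clinical.csv           MDS-UPDRS item scores + Hoehn & Yahr stage
      sessions/              one file (or file set) per test session
        <pid>_d###_<test>_<side>.csv      inertial (t,ax,ay,az,gx,gy,gz)
                                          or touch (t,x,y,kind,target)
        <pid>_d###_<test>_<side>.wav      16-bit mono PCM audio
        <pid>_d###_speech_none_q#.wav     one file per speech question
        <pid>_d###_esdmt_none.json        responses + symbol->digit key

Readers validate every session and return malformed ones in a rejects list
with a reason; they never silently drop data.  Writers emit canonical bytes
(sorted JSON keys, shortest round-trip float formatting) so that
``write(read(bundle))`` reproduces a canonical bundle byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .config import ALL_TESTS, LATERALIZED_TESTS, MDS_UPDRS_ITEMS

log = logging.getLogger(__name__)

TOUCH_KINDS = ("down", "move", "up")

#: Tests with side == "none" (non-lateralized).
NON_LATERALIZED_TESTS = frozenset(ALL_TESTS) - LATERALIZED_TESTS


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class InertialStream:
    """Timestamped 3-axis accelerometer + gyroscope samples for one recording.

    ``t`` is seconds since recording start; ``acc`` is specific force in
    m/s^2 (gravity included); ``gyro`` is angular velocity in rad/s.
    Duplicate timestamps are collapsed keeping the first occurrence.
    """

    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    fs_nominal: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float).reshape(-1, 3)
        self.gyro = np.asarray(self.gyro, dtype=float).reshape(-1, 3)
        if not (len(self.t) == len(self.acc) == len(self.gyro)):
            raise ValueError("length mismatch")
        if self.fs_nominal <= 0:
            raise ValueError("fs_nominal must be > 0")
        if len(self.t):
            if not (np.isfinite(self.t).all() and np.isfinite(self.acc).all()
                    and np.isfinite(self.gyro).all()):
                raise ValueError("non-finite sample")
            dt = np.diff(self.t)
            if (dt < 0).any():
                raise ValueError("timestamps")
            if (dt == 0).any():
                keep = np.concatenate([[True], dt > 0])
                log.info("collapsed %d duplicate timestamps", int((~keep).sum()))
                self.t = self.t[keep]
                self.acc = self.acc[keep]
                self.gyro = self.gyro[keep]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0

    @property
    def fs(self) -> float:
        """Empirical sampling rate (falls back to nominal for tiny streams)."""
        if len(self.t) > 1 and self.duration > 0:
            return (len(self.t) - 1) / self.duration
        return self.fs_nominal


@dataclass
class TouchTrace:
    """Ordered touchscreen events with screen coordinates in pixels."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    kind: np.ndarray                       # of {"down","move","up"}
    target: np.ndarray                     # str button/region id, "" if none
    screen: tuple[float, float] = (1080.0, 1920.0)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.kind = np.asarray(self.kind, dtype=object)
        self.target = np.asarray(self.target, dtype=object)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.kind) == len(self.target) == n):
            raise ValueError("length mismatch")
        if n:
            if not (np.isfinite(self.t).all() and np.isfinite(self.x).all()
                    and np.isfinite(self.y).all()):
                raise ValueError("non-finite sample")
            if (np.diff(self.t) < 0).any():
                raise ValueError("timestamps")
            bad = set(self.kind) - set(TOUCH_KINDS)
            if bad:
                raise ValueError(f"unknown event kind {sorted(bad)}")
            w, h = self.screen
            if (self.x < 0).any() or (self.x > w).any() or (self.y < 0).any() or (self.y > h).any():
                raise ValueError("coordinates out of screen bounds")
            # every down eventually followed by up
            downs = int(np.sum(self.kind == "down"))
            ups = int(np.sum(self.kind == "up"))
            if downs and ups == 0:
                raise ValueError("down without up")

    def down_times(self, target: str | None = None) -> np.ndarray:
        sel = self.kind == "down"
        if target is not None:
            sel &= self.target == target
        return self.t[sel]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0


@dataclass
class AudioSignal:
    """Mono PCM recording, amplitude in [-1, 1]."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs < 16000:
            raise ValueError("fs must be >= 16 kHz")
        if len(self.samples) and not np.isfinite(self.samples).all():
            raise ValueError("non-finite sample")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class SdmtResponses:
    """Symbol-digit test responses: (t, symbol_index, answered_digit) plus key."""

    responses: list            # list of (t: float, symbol: int, digit: int)
    key: dict                  # symbol index -> correct digit


@dataclass
class TestSession:
    """One administration of one test (one side, one study day)."""

    participant_id: str
    test_name: str
    body_side: str             # left | right | none
    day_index: int             # 1-based; day 1 = baseline visit
    payload: object            # InertialStream | TouchTrace | AudioSignal | list | SdmtResponses
    completed: bool = True

    def __post_init__(self) -> None:
        if self.test_name not in ALL_TESTS:
            raise ValueError(f"unknown test {self.test_name!r}")
        if self.test_name in LATERALIZED_TESTS:
            if self.body_side not in ("left", "right"):
                raise ValueError(f"{self.test_name} requires body_side left/right")
        elif self.body_side != "none":
            raise ValueError(f"{self.test_name} requires body_side 'none'")
        if self.day_index < 1:
            raise ValueError("day_index is 1-based")


@dataclass
class FeatureRecord:
    """One (participant, feature, side, day) -> value with QC status.

    ``extras`` holds per-record audit values (event counts, wear hours);
    it is not serialized by the feature-table writer.
    """

    participant_id: str
    feature_name: str
    side: str                  # left | right | none before side assignment; more | less after
    day_index: int
    value: float | None
    unit: str
    qc_pass: bool = True
    qc_reason: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.qc_pass and self.value is not None and not np.isfinite(self.value):
            raise ValueError("value must be finite when qc_pass")


@dataclass
class ClinicalRecord:
    """Baseline MDS-UPDRS item scores and Hoehn & Yahr stage."""

    participant_id: str
    mds_updrs_items: dict      # item id -> ordinal score 0..4
    hoehn_yahr: int

    def __post_init__(self) -> None:
        for item, score in self.mds_updrs_items.items():
            if score not in (0, 1, 2, 3, 4):
                raise ValueError(f"item {item} score {score} not in 0..4")
        if self.hoehn_yahr not in (1, 2):
            raise ValueError("hoehn_yahr must be 1 or 2 for this population")


@dataclass
class RejectedSession:
    path: str
    reason: str


@dataclass
class BundleData:
    sessions: list
    clinical: ClinicalRecord | None
    rejects: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

def _session_stem(s: TestSession) -> str:
    return f"{s.participant_id}_d{s.day_index:03d}_{s.test_name}_{s.body_side}"


def _write_inertial_csv(stream: InertialStream, path: Path) -> None:
    df = pd.DataFrame({
        "t": stream.t,
        "ax": stream.acc[:, 0], "ay": stream.acc[:, 1], "az": stream.acc[:, 2],
        "gx": stream.gyro[:, 0], "gy": stream.gyro[:, 1], "gz": stream.gyro[:, 2],
    })
    df.to_csv(path, index=False, lineterminator="\n")


def _read_inertial_csv(path: Path, fs_nominal: float) -> InertialStream:
    df = pd.read_csv(path, float_precision="round_trip")
    return InertialStream(
        t=df["t"].to_numpy(),
        acc=df[["ax", "ay", "az"]].to_numpy(),
        gyro=df[["gx", "gy", "gz"]].to_numpy(),
        fs_nominal=fs_nominal,
    )


def _write_touch_csv(trace: TouchTrace, path: Path) -> None:
    df = pd.DataFrame({"t": trace.t, "x": trace.x, "y": trace.y,
                       "kind": trace.kind, "target": trace.target})
    df.to_csv(path, index=False, lineterminator="\n")


def _read_touch_csv(path: Path, screen: tuple[float, float]) -> TouchTrace:
    df = pd.read_csv(path, keep_default_na=False,
                     float_precision="round_trip")
    return TouchTrace(
        t=df["t"].to_numpy(), x=df["x"].to_numpy(), y=df["y"].to_numpy(),
        kind=df["kind"].to_numpy(dtype=object),
        target=df["target"].astype(str).to_numpy(dtype=object),
        screen=screen,
    )


def _write_wav(audio: AudioSignal, path: Path) -> None:
    pcm = np.clip(np.round(audio.samples * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(audio.fs), pcm)


def _read_wav(path: Path) -> AudioSignal:
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("audio must be mono")
    return AudioSignal(samples=data.astype(float) / 32767.0, fs=float(fs))


def write_session_bundle(bundle: BundleData, path: str | Path) -> Path:
    """Write a bundle directory; returns its path.  Output is canonical."""
    root = Path(path)
    (root / "sessions").mkdir(parents=True, exist_ok=True)
    manifest_sessions = []
    pid = None
    for s in sorted(bundle.sessions,
                    key=lambda s: (s.day_index, s.test_name, s.body_side)):
        pid = s.participant_id
        stem = _session_stem(s)
        entry = {"test": s.test_name, "side": s.body_side, "day": s.day_index,
                 "completed": s.completed, "files": []}
        p = s.payload
        if isinstance(p, InertialStream):
            fname = f"{stem}.csv"
            _write_inertial_csv(p, root / "sessions" / fname)
            entry["files"] = [fname]
            entry["fs_nominal"] = p.fs_nominal
            entry["payload"] = "inertial"
        elif isinstance(p, TouchTrace):
            fname = f"{stem}.csv"
            _write_touch_csv(p, root / "sessions" / fname)
            entry["files"] = [fname]
            entry["screen"] = list(p.screen)
            entry["payload"] = "touch"
        elif isinstance(p, AudioSignal):
            fname = f"{stem}.wav"
            _write_wav(p, root / "sessions" / fname)
            entry["files"] = [fname]
            entry["payload"] = "audio"
        elif isinstance(p, list) and all(isinstance(a, AudioSignal) for a in p):
            for i, a in enumerate(p, start=1):
                fname = f"{stem}_q{i}.wav"
                _write_wav(a, root / "sessions" / fname)
                entry["files"].append(fname)
            entry["payload"] = "audio_list"
        elif isinstance(p, SdmtResponses):
            fname = f"{stem}.json"
            obj = {"responses": [[float(t), int(sym), int(d)] for t, sym, d in p.responses],
                   "key": {str(k): int(v) for k, v in p.key.items()}}
            (root / "sessions" / fname).write_text(
                json.dumps(obj, indent=2, sort_keys=True) + "\n")
            entry["files"] = [fname]
            entry["payload"] = "sdmt"
        else:
            raise TypeError(f"unsupported payload {type(p)}")
        manifest_sessions.append(entry)

    manifest = {"participant_id": pid, "sessions": manifest_sessions}
    (root / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    if bundle.clinical is not None:
        c = bundle.clinical
        rows = [{"field": "participant_id", "value": c.participant_id},
                {"field": "hoehn_yahr", "value": c.hoehn_yahr}]
        rows += [{"field": item, "value": c.mds_updrs_items[item]}
                 for item in sorted(c.mds_updrs_items)]
        pd.DataFrame(rows).to_csv(root / "clinical.csv", index=False,
                                  lineterminator="\n")
    return root


def read_session_bundle(path: str | Path) -> BundleData:
    """Read and validate a bundle; malformed sessions land in ``rejects``."""
    root = Path(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    pid = manifest["participant_id"]

    sessions: list[TestSession] = []
    rejects: list[RejectedSession] = []
    for entry in manifest["sessions"]:
        files = entry["files"]
        try:
            kind = entry.get("payload")
            if kind == "inertial":
                payload = _read_inertial_csv(root / "sessions" / files[0],
                                             float(entry.get("fs_nominal", 50.0)))
            elif kind == "touch":
                payload = _read_touch_csv(root / "sessions" / files[0],
                                          tuple(entry.get("screen", (1080.0, 1920.0))))
            elif kind == "audio":
                payload = _read_wav(root / "sessions" / files[0])
            elif kind == "audio_list":
                payload = [_read_wav(root / "sessions" / f) for f in files]
            elif kind == "sdmt":
                obj = json.loads((root / "sessions" / files[0]).read_text())
                payload = SdmtResponses(
                    responses=[(float(t), int(s), int(d)) for t, s, d in obj["responses"]],
                    key={int(k): int(v) for k, v in obj["key"].items()})
            else:
                raise ValueError(f"unknown payload kind {kind!r}")
            sessions.append(TestSession(
                participant_id=pid, test_name=entry["test"], body_side=entry["side"],
                day_index=int(entry["day"]), payload=payload,
                completed=bool(entry["completed"])))
        except (ValueError, KeyError, OSError) as exc:
            rejects.append(RejectedSession(path=str(files[0]) if files else "?",
                                           reason=str(exc)))

    clinical = None
    cpath = root / "clinical.csv"
    if cpath.exists():
        df = pd.read_csv(cpath, dtype={"field": str})
        fields = dict(zip(df["field"], df["value"]))
        items = {item: int(fields[item]) for item in MDS_UPDRS_ITEMS if item in fields}
        clinical = ClinicalRecord(participant_id=str(fields["participant_id"]),
                                  mds_updrs_items=items,
                                  hoehn_yahr=int(fields["hoehn_yahr"]))
    return BundleData(sessions=sessions, clinical=clinical, rejects=rejects)


# ---------------------------------------------------------------------------
# Feature table I/O
# ---------------------------------------------------------------------------

_FEATURE_COLUMNS = ["participant_id", "feature_name", "side", "day_index",
                    "value", "unit", "qc_pass", "qc_reason"]


def feature_frame(records: Iterable[FeatureRecord]) -> pd.DataFrame:
    """Tidy DataFrame with one row per FeatureRecord (stable column order)."""
    rows = [{
        "participant_id": r.participant_id, "feature_name": r.feature_name,
        "side": r.side, "day_index": r.day_index,
        "value": np.nan if r.value is None else r.value, "unit": r.unit,
        "qc_pass": r.qc_pass, "qc_reason": "" if r.qc_reason is None else r.qc_reason,
    } for r in records]
    df = pd.DataFrame(rows, columns=_FEATURE_COLUMNS)
    if not len(df):
        df = pd.DataFrame(columns=_FEATURE_COLUMNS)
    return df


def write_feature_table(records: Sequence[FeatureRecord], path: str | Path) -> Path:
    """Write the tidy feature CSV; duplicate keys are an error."""
    df = feature_frame(records)
    if len(df):
        key = df[["participant_id", "feature_name", "side", "day_index"]]
        dup = key[key.duplicated(keep=False)]
        if len(dup):
            raise ValueError("duplicate feature keys:\n" + dup.drop_duplicates().to_string())
    path = Path(path)
    with open(path, "w") as fh:
        units = sorted({(r, u) for r, u in zip(df["feature_name"], df["unit"])}) if len(df) else []
        for name, unit in units:
            fh.write(f"# unit {name} = {unit}\n")
        df.to_csv(fh, index=False, lineterminator="\n")
    return path


def read_feature_table(path: str | Path) -> list[FeatureRecord]:
    df = pd.read_csv(path, comment="#", keep_default_na=False,
                     float_precision="round_trip",
                     dtype={"participant_id": str, "qc_reason": str})
    records = []
    for row in df.itertuples(index=False):
        value = float(row.value) if row.value != "" else None
        if value is not None and np.isnan(value):
            value = None
        qc_pass = (row.qc_pass if isinstance(row.qc_pass, (bool, np.bool_))
                   else str(row.qc_pass).strip() == "True")
        records.append(FeatureRecord(
            participant_id=row.participant_id, feature_name=row.feature_name,
            side=row.side, day_index=int(row.day_index), value=value,
            unit=str(row.unit), qc_pass=bool(qc_pass),
            qc_reason=None if row.qc_reason == "" else row.qc_reason))
    return records
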