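"""Domain-type invariants and lossless bundle / feature-table round-trips."""

from __future__ import annotations

import filecmp

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdsense.session_model import (AudioSignal, FeatureRecord, InertialStream,
                                   TestSession, TouchTrace,
                                   read_feature_table, read_session_bundle,
                                   write_feature_table, write_session_bundle)


class TestInertialStream:
    def test_rejects_non_monotone_timestamps(self):
        with pytest.raises(ValueError, match="timestamps"):
            InertialStream(t=[0.0, 0.2, 0.1], acc=np.zeros((3, 3)),
                           gyro=np.zeros((3, 3)), fs_nominal=50.0)

    def test_rejects_non_finite_samples(self):
        acc = np.zeros((3, 3))
        acc[1, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            InertialStream(t=[0.0, 0.1, 0.2], acc=acc, gyro=np.zeros((3, 3)),
                           fs_nominal=50.0)

    def test_duplicate_timestamps_collapsed_keeping_first(self):
        acc = np.arange(12, dtype=float).reshape(4, 3)
        s = InertialStream(t=[0.0, 0.1, 0.1, 0.2], acc=acc,
                           gyro=np.zeros((4, 3)), fs_nominal=50.0)
        assert len(s.t) == 3
        assert s.acc[1, 0] == 3.0          # first of the duplicate pair kept


class TestTouchTrace:
    def test_rejects_out_of_bounds_coordinates(self):
        with pytest.raises(ValueError, match="bounds"):
            TouchTrace(t=[0.0], x=[2000.0], y=[100.0],
                       kind=np.array(["down"], dtype=object),
                       target=np.array([""], dtype=object))

    def test_down_without_up_rejected(self):
        with pytest.raises(ValueError, match="down without up"):
            TouchTrace(t=[0.0], x=[10.0], y=[10.0],
                       kind=np.array(["down"], dtype=object),
                       target=np.array([""], dtype=object))


def test_audio_requires_16k_sampling():
    with pytest.raises(ValueError, match="16 kHz"):
        AudioSignal(samples=np.zeros(100), fs=8000.0)


def test_lateralized_test_requires_side():
    with pytest.raises(ValueError, match="left/right"):
        TestSession(participant_id="p", test_name="dexterity", body_side="none",
                    day_index=1, payload=None)
    with pytest.raises(ValueError, match="'none'"):
        TestSession(participant_id="p", test_name="balance", body_side="left",
                    day_index=1, payload=None)


class TestBundleRoundTrip:
    def test_missing_manifest_is_hard_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_session_bundle(tmp_path / "nope")

    def test_malformed_session_rejected_with_reason(self, tmp_path, mini_bundle):
        _, bundle, _ = mini_bundle
        root = write_session_bundle(bundle, tmp_path / "b")
        # corrupt one inertial CSV with a NaN accelerometer row
        victim = next(p for p in (root / "sessions").glob("*rest_tremor*.csv"))
        lines = victim.read_text().splitlines()
        parts = lines[1].split(",")
        parts[1] = "nan"
        lines[1] = ",".join(parts)
        victim.write_text("\n".join(lines) + "\n")
        data = read_session_bundle(root)
        assert len(data.rejects) == 1
        assert "non-finite" in data.rejects[0].reason

    def test_write_read_write_is_byte_identical(self, tmp_path, mini_bundle):
        """Canonical bundles survive a read/write cycle byte-for-byte."""
        _, bundle, _ = mini_bundle
        a = write_session_bundle(bundle, tmp_path / "a")
        b = write_session_bundle(read_session_bundle(a), tmp_path / "b")
        files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert filecmp.cmp(a / rel, b / rel, shallow=False), rel

    def test_clinical_record_round_trips(self, tmp_path, mini_bundle):
        _, bundle, _ = mini_bundle
        root = write_session_bundle(bundle, tmp_path / "b")
        data = read_session_bundle(root)
        assert data.clinical.mds_updrs_items == bundle.clinical.mds_updrs_items
        assert data.clinical.hoehn_yahr == bundle.clinical.hoehn_yahr


record_strategy = st.builds(
    FeatureRecord,
    participant_id=st.sampled_from(["P01", "P02", "P03"]),
    feature_name=st.sampled_from(["voice_jitter", "sway_jerk", "tapping_variability"]),
    side=st.sampled_from(["left", "right", "none"]),
    day_index=st.integers(1, 28),
    value=st.one_of(st.none(),
                    st.floats(-1e6, 1e6, allow_nan=False, allow_subnormal=False)),
    unit=st.sampled_from(["%", "ms", "log(m^2/s^6)"]),
    qc_pass=st.booleans(),
    qc_reason=st.one_of(st.none(), st.sampled_from(["floor", "no turns"])),
)


class TestFeatureTable:
    def test_three_records_three_rows(self, tmp_path):
        recs = [FeatureRecord("P", "voice_jitter", "none", d, 1.0 * d, "%")
                for d in (1, 2, 3)]
        path = write_feature_table(recs, tmp_path / "f.csv")
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(body) == 4                      # header + 3 rows
        assert body[0].startswith("participant_id,feature_name,side,day_index")

    def test_empty_collection_gives_header_only(self, tmp_path):
        path = write_feature_table([], tmp_path / "f.csv")
        assert read_feature_table(path) == []

    def test_duplicate_keys_rejected(self, tmp_path):
        recs = [FeatureRecord("P", "voice_jitter", "none", 1, 1.0, "%")] * 2
        with pytest.raises(ValueError, match="duplicate"):
            write_feature_table(recs, tmp_path / "f.csv")

    @settings(max_examples=20, derandomize=True)
    @given(st.lists(record_strategy, max_size=40))
    def test_round_trip_identity(self, tmp_path_factory, records):
        """read(write(x)) == x, values bit-exact, for random record sets."""
        # de-duplicate keys (writer rejects duplicates by contract)
        seen, unique = set(), []
        for r in records:
            key = (r.participant_id, r.feature_name, r.side, r.day_index)
            if key not in seen:
                seen.add(key)
                # a failing value must be None by the type invariant
                if not r.qc_pass:
                    r.value = None
                unique.append(r)
        path = tmp_path_factory.mktemp("ft") / "f.csv"
        write_feature_table(unique, path)
        back = read_feature_table(path)
        assert len(back) == len(unique)
        for a, b in zip(unique, back):
            assert (a.participant_id, a.feature_name, a.side, a.day_index) == \
                   (b.participant_id, b.feature_name, b.side, b.day_index)
            if a.value is None:
                assert b.value is None
            else:
                assert a.value == b.value          # exact float round-trip
            assert a.qc_pass == b.qc_pass
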