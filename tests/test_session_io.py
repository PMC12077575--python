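import numpy as np
import pytest

from nirsfeed.errors import NirsFeedError, RecordError
from nirsfeed.feedback_engine import FeedbackSettings
from nirsfeed.protocol_session import (
    Epoch,
    Schedule,
    build_example_schedule,
    validate_schedule,
)
from nirsfeed.session_io import (
    SessionRecord,
    Settings,
    export_summary,
    load_settings,
    read_session_record,
    save_settings,
    write_session_record,
)


def example_study_settings():
    return Settings(
        device_name="NIRx NIRSport2 (26CH)",
        protocol="MovAvg_SS",
        nf_channels=(5, 6, 10, 11, 13, 15, 20, 21),
        ss_channels=(22, 23),
        window_s=5.0,
        session_length_s=1800.0,
        study="test",
        subject="1",
        run="1",
        schedule=build_example_schedule(),
        feedback=FeedbackSettings(),
    )


def tiny_record(n=40, c=3):
    rng = np.random.default_rng(7)
    return SessionRecord(
        sample_rate=10.17,
        started_at=100.0,
        ended_at=100.0 + n / 10.17,
        thermometer_series=np.concatenate(
            [np.full(min(10, n), np.nan), rng.random(max(0, n - 10))]
        ),
        marker_series=np.repeat([1, 2, 3, 2], n // 4),
        channel_ids=np.arange(1, c + 1),
        raw_wl1=rng.random((n, c)),
        raw_wl2=rng.random((n, c)),
        hbo=rng.normal(size=(n, c)),
        hbr=rng.normal(size=(n, c)),
        settings_snapshot={"nf_channels": [1, 2], "window_s": 5.0},
    )


def assert_records_equal(a, b):
    assert a.sample_rate == pytest.approx(b.sample_rate)
    assert a.started_at == pytest.approx(b.started_at)
    assert a.ended_at == pytest.approx(b.ended_at)
    np.testing.assert_allclose(a.thermometer_series, b.thermometer_series)
    np.testing.assert_array_equal(a.marker_series, b.marker_series)
    np.testing.assert_array_equal(a.channel_ids, b.channel_ids)
    for f in ("raw_wl1", "raw_wl2", "hbo", "hbr"):
        np.testing.assert_allclose(getattr(a, f), getattr(b, f))
    assert a.settings_snapshot == b.settings_snapshot


class TestSettingsRoundTrip:
    def test_example_study_settings_round_trip(self, tmp_path):
        settings = example_study_settings()
        path = save_settings(settings, tmp_path / "settings.json")
        again = load_settings(path)
        assert again == settings

    def test_load_save_load_idempotent(self, tmp_path):
        p1 = save_settings(example_study_settings(), tmp_path / "a.json")
        s1 = load_settings(p1)
        p2 = save_settings(s1, tmp_path / "b.json")
        assert load_settings(p2) == s1

    def test_unknown_protocol_rejected(self, tmp_path):
        import json

        d = example_study_settings().to_dict()
        d["protocol"] = "DoesNotExist"
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(d))
        with pytest.raises(NirsFeedError, match="DoesNotExist"):
            load_settings(path)

    def test_schedule_gap_loads_but_validator_reports(self, tmp_path):
        import json

        d = example_study_settings().to_dict()
        d["epochs"][3]["start_s"] += 2.0  # insert a gap
        path = tmp_path / "gap.json"
        path.write_text(json.dumps(d))
        loaded = load_settings(path)  # load succeeds
        assert validate_schedule(loaded.schedule)  # validator flags it


class TestRecordRoundTrip:
    @pytest.mark.parametrize("fmt", ["mat", "h5"])
    def test_round_trip_identity(self, tmp_path, fmt):
        rec = tiny_record()
        path = write_session_record(rec, "test", "1", "1", tmp_path, fmt=fmt)
        assert path.name == f"test_1_1.{'mat' if fmt == 'mat' else 'h5'}"
        assert_records_equal(read_session_record(path), rec)

    def test_dialects_read_back_identically(self, tmp_path):
        rec = tiny_record()
        p_mat = write_session_record(rec, "s", "1", "1", tmp_path, fmt="mat")
        p_h5 = write_session_record(rec, "s", "1", "1", tmp_path, fmt="h5")
        assert_records_equal(read_session_record(p_mat), read_session_record(p_h5))

    def test_existing_file_refused_without_overwrite(self, tmp_path):
        rec = tiny_record()
        write_session_record(rec, "s", "1", "1", tmp_path)
        with pytest.raises(RecordError, match="exists"):
            write_session_record(rec, "s", "1", "1", tmp_path)
        write_session_record(rec, "s", "1", "1", tmp_path, overwrite=True)

    def test_mismatched_series_lengths_refused(self, tmp_path):
        rec = tiny_record()
        rec.marker_series = rec.marker_series[:-3]
        with pytest.raises(RecordError, match="marker_series"):
            write_session_record(rec, "s", "1", "1", tmp_path)

    def test_truncated_file_is_a_format_error(self, tmp_path):
        rec = tiny_record()
        path = write_session_record(rec, "s", "1", "1", tmp_path)
        path.write_bytes(path.read_bytes()[:100])
        with pytest.raises(RecordError):
            read_session_record(path)

    def test_missing_file_is_an_error(self, tmp_path):
        with pytest.raises(RecordError):
            read_session_record(tmp_path / "nope.mat")


class TestSummary:
    def test_summary_series_equal_length(self):
        rec = tiny_record()
        s = export_summary(rec)
        n = rec.n_frames
        assert (
            s.mean_nf_series.shape[0]
            == s.feedback_series.shape[0]
            == s.marker_series.shape[0]
            == n
        )

    def test_mean_restricted_to_nf_channels(self):
        rec = tiny_record()
        s = export_summary(rec)
        np.testing.assert_allclose(s.mean_nf_series, rec.hbo[:, :2].mean(axis=1))

    def test_markers_are_schedule_markers(self):
        s = export_summary(tiny_record())
        assert set(np.unique(s.marker_series)) <= {1, 2, 3}

    def test_empty_record_gives_empty_summary(self):
        rec = tiny_record(n=0, c=0)
        rec.channel_ids = np.empty(0, dtype=int)
        s = export_summary(rec)
        assert s.mean_nf_series.size == 0
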