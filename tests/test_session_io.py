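"""Session container invariants and CSV round-trip fidelity."""

import numpy as np
import pandas as pd
import pytest

from smo2kinetics.session import (
    AthleteMeta,
    PunchLog,
    SampleSeries,
    SessionFormatError,
    SessionLayout,
    SessionValidationError,
    check_signal_validity,
    read_punch_log,
    read_session,
    write_punch_log,
    write_session,
)
from smo2kinetics.preprocess import extract_windows
from smo2kinetics.simulate import preset_scenarios, simulate_session


def _write_csv(path, time, lead, rear, hr):
    pd.DataFrame(
        {"time_s": time, "smo2_lead": lead, "smo2_rear": rear, "hr": hr}
    ).to_csv(path, index=False)


def _write_layout(path, **overrides):
    kv = dict(n_rounds=6, round_s=180, rest_s=60, athlete_id="a1",
              fat_thickness_mm=5.2, modality="bag")
    kv.update(overrides)
    path.write_text("\n".join(f"{k} = {v}" for k, v in kv.items()))


class TestSampleSeries:
    def test_rejects_out_of_range_smo2(self):
        with pytest.raises(SessionValidationError):
            SampleSeries(np.arange(5.0), np.array([50, 60, 105, 60, 50.0]))

    def test_rejects_non_monotone_time(self):
        with pytest.raises(SessionValidationError):
            SampleSeries(np.array([0.0, 2.0, 1.0, 3.0]), np.full(4, 50.0))

    def test_rejects_irregular_step(self):
        with pytest.raises(SessionValidationError):
            SampleSeries(np.array([0.0, 1.0, 2.5, 3.5]), np.full(4, 50.0))


class TestReadSession:
    def test_default_layout_fits_1440s_recording(self, tmp_path):
        t = np.arange(1440.0)
        _write_csv(tmp_path / "ts.csv", t, np.full(t.size, 60.0),
                   np.full(t.size, 55.0), np.full(t.size, 120.0))
        _write_layout(tmp_path / "layout.cfg")
        rec = read_session(tmp_path / "ts.csv", tmp_path / "layout.cfg")
        windows = extract_windows(rec)
        kinds = [(w.kind, w.leg) for w in windows]
        assert kinds.count(("round", "lead")) == 6
        assert kinds.count(("rest", "lead")) == 5

    def test_round_and_rest_window_spans(self, tmp_path):
        t = np.arange(1440.0)
        _write_csv(tmp_path / "ts.csv", t, np.full(t.size, 60.0),
                   np.full(t.size, 55.0), np.full(t.size, 120.0))
        _write_layout(tmp_path / "layout.cfg")
        rec = read_session(tmp_path / "ts.csv", tmp_path / "layout.cfg")
        assert rec.layout.round_window(1) == (0.0, 180.0)
        assert rec.layout.rest_window(1) == (180.0, 240.0)

    def test_smo2_out_of_bounds_rejected(self, tmp_path):
        t = np.arange(1440.0)
        lead = np.full(t.size, 60.0)
        lead[100] = 105.0
        _write_csv(tmp_path / "ts.csv", t, lead, np.full(t.size, 55.0),
                   np.full(t.size, 120.0))
        _write_layout(tmp_path / "layout.cfg")
        with pytest.raises(SessionValidationError):
            read_session(tmp_path / "ts.csv", tmp_path / "layout.cfg")

    def test_malformed_header_is_format_error(self, tmp_path):
        (tmp_path / "ts.csv").write_text("t,smo2\n0,50\n1,51\n")
        _write_layout(tmp_path / "layout.cfg")
        with pytest.raises(SessionFormatError):
            read_session(tmp_path / "ts.csv", tmp_path / "layout.cfg")

    def test_layout_exceeding_span_rejected(self, tmp_path):
        t = np.arange(600.0)  # < 1380 s needed by the default layout
        _write_csv(tmp_path / "ts.csv", t, np.full(t.size, 60.0),
                   np.full(t.size, 55.0), np.full(t.size, 120.0))
        _write_layout(tmp_path / "layout.cfg")
        with pytest.raises(SessionValidationError):
            read_session(tmp_path / "ts.csv", tmp_path / "layout.cfg")

    def test_short_gap_interpolated_and_flagged(self, tmp_path):
        t = np.arange(1440.0)
        keep = ~np.isin(t, [500.0, 501.0])
        _write_csv(tmp_path / "ts.csv", t[keep], np.full(keep.sum(), 60.0),
                   np.full(keep.sum(), 55.0), np.full(keep.sum(), 120.0))
        _write_layout(tmp_path / "layout.cfg")
        rec = read_session(tmp_path / "ts.csv", tmp_path / "layout.cfg")
        assert 500.0 in rec.interpolated_times and 501.0 in rec.interpolated_times
        assert rec.series["lead"].time.size == 1440
        assert not rec.bad_spans

    def test_long_gap_marks_window_unanalysable(self, tmp_path):
        t = np.arange(1440.0)
        keep = (t < 300) | (t >= 305)  # 5 s dropout inside round 2
        _write_csv(tmp_path / "ts.csv", t[keep], np.full(keep.sum(), 60.0),
                   np.full(keep.sum(), 55.0), np.full(keep.sum(), 120.0))
        _write_layout(tmp_path / "layout.cfg")
        rec = read_session(tmp_path / "ts.csv", tmp_path / "layout.cfg")
        assert rec.bad_spans
        windows = extract_windows(rec)
        assert ("round", 2) not in {(w.kind, w.index) for w in windows}


class TestRoundTrip:
    def test_simulated_session_roundtrips_losslessly(self, tmp_path, spar_record):
        rec, _ = spar_record
        write_session(rec, tmp_path / "ts.csv", tmp_path / "layout.cfg",
                      tmp_path / "punches.csv")
        back = read_session(tmp_path / "ts.csv", tmp_path / "layout.cfg",
                            tmp_path / "punches.csv")
        for leg in ("lead", "rear"):
            np.testing.assert_allclose(back.series[leg].smo2,
                                       rec.series[leg].smo2, atol=1e-9)
            np.testing.assert_allclose(back.series[leg].time,
                                       rec.series[leg].time, atol=1e-9)
        np.testing.assert_allclose(back.punches.event_times,
                                   rec.punches.event_times, atol=1e-9)
        assert back.layout == rec.layout
        assert back.meta.athlete_id == rec.meta.athlete_id

    def test_window_extraction_partitions_layout(self, spar_record):
        rec, _ = spar_record
        windows = extract_windows(rec, legs=("lead",))
        total = sum(w.local_time.size for w in windows)
        assert total == 6 * 180 + 5 * 60
        starts = sorted(w.start for w in windows)
        assert starts == sorted(set(starts))  # no overlaps

    def test_punch_log_count_dialect(self, tmp_path):
        log = PunchLog(modality="spar", round_counts={1: 55, 2: 60})
        write_punch_log(tmp_path / "p.csv", log)
        back = read_punch_log(tmp_path / "p.csv", "spar")
        assert back.round_counts == {1: 55, 2: 60}
        assert not back.has_events


class TestSignalValidity:
    @pytest.mark.parametrize(
        "thickness, valid",
        [(5.2, True), (14.0, True), (15.0, False)],
    )
    def test_fat_thickness_rule(self, thickness, valid):
        meta = AthleteMeta("a1", fat_thickness_mm=thickness)
        assert check_signal_validity(meta).valid is valid

    def test_negative_thickness_rejected(self):
        with pytest.raises(SessionValidationError):
            AthleteMeta("a1", fat_thickness_mm=-1.0)
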