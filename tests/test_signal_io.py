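"""Recording data model, CSV round-trips and resampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thighlie.errors import GapError, ParseError
from thighlie.signal_io import (
    EpochSeries,
    NonwearIntervals,
    TriaxialRecording,
    read_recording,
    resample_uniform,
    write_recording,
)

T0 = pd.Timestamp("2024-01-01", tz="UTC")


class TestTriaxialRecording:
    def test_validation_rejects_bad_shapes_and_values(self):
        with pytest.raises(ValueError):
            TriaxialRecording(np.zeros((5, 2)), 25.0, T0)
        with pytest.raises(ValueError):
            TriaxialRecording(np.zeros((0, 3)), 25.0, T0)
        with pytest.raises(ValueError):
            TriaxialRecording(np.full((5, 3), np.nan), 25.0, T0)
        with pytest.raises(ValueError):
            TriaxialRecording(np.full((5, 3), 17.0), 25.0, T0)
        with pytest.raises(ValueError):
            TriaxialRecording(np.zeros((5, 3)), -1.0, T0)
        with pytest.raises(ValueError):
            TriaxialRecording(np.zeros((5, 3)), 25.0, T0, placement="wrist")

    def test_uniform_timestamps(self):
        rec = TriaxialRecording(np.zeros((50, 3)), 25.0, T0)
        t = rec.times()
        assert t[0] == T0
        assert np.allclose(np.diff(t.asi8) / 1e9, 0.04)

    def test_slice_seconds(self):
        rec = TriaxialRecording(np.arange(300).reshape(100, 3) / 100.0, 10.0, T0)
        sub = rec.slice_seconds(2.0, 4.0)
        assert sub.n_samples == 20
        assert sub.start_time == T0 + pd.Timedelta(seconds=2)
        np.testing.assert_array_equal(sub.samples, rec.samples[20:40])


class TestCsvRoundTrip:
    def test_three_row_identity_read(self, tmp_path):
        path = tmp_path / "tiny.csv"
        rec = TriaxialRecording(np.tile([0.0, 0.0, 1.0], (3, 1)), 25.0, T0)
        write_recording(rec, path)
        back = read_recording(path)
        assert back.n_samples == 3
        assert back.sample_rate == pytest.approx(25.0)
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-6)

    def test_round_trip_lossless(self, tmp_path):
        rng = np.random.default_rng(7)
        rec = TriaxialRecording(rng.normal(0, 0.5, (500, 3)), 50.0, T0, "back", "ax3")
        path = tmp_path / "rt.csv"
        write_recording(rec, path)
        back = read_recording(path, "back")
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-6)
        assert abs((back.start_time - rec.start_time).total_seconds()) < 1e-3

    def test_gap_raises_with_interval(self, tmp_path):
        path = tmp_path / "gap.csv"
        t = np.concatenate([np.arange(50), np.arange(50) + 50 + 10 * 25]) / 25.0
        times = (T0 + pd.to_timedelta(t, unit="s")).strftime("%Y-%m-%dT%H:%M:%S.%f")
        pd.DataFrame({"time": times, "ax": 0.0, "ay": 0.0, "az": 1.0}).to_csv(
            path, index=False)
        with pytest.raises(GapError) as err:
            read_recording(path)
        (a, b), = err.value.gaps
        assert (b - a).total_seconds() == pytest.approx(10.0 + 0.04, abs=0.05)
        filled = read_recording(path, allow_gaps=True)
        assert filled.n_samples == int(round(t[-1] * 25)) + 1

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "time,ax,ay,az\n"
            "2024-01-01T00:00:00,0,0,1\n"
            "2024-01-01T00:00:00.04,0,zzz,1\n"
            "2024-01-01T00:00:00.08,0,0,1\n"
        )
        with pytest.raises(ParseError) as err:
            read_recording(path)
        assert err.value.line == 3

    def test_unwritable_target_raises_oserror_with_path(self, tmp_path):
        rec = TriaxialRecording(np.zeros((3, 3)), 25.0, T0)
        target = tmp_path / "no" / "such" / "dir" / "x.csv"
        with pytest.raises(OSError) as err:
            write_recording(rec, target)
        assert "x.csv" in str(err.value)


class TestResample:
    def test_constant_signal_invariant(self):
        rec = TriaxialRecording(np.tile([0.0, 0.0, 1.0], (400, 1)), 100.0, T0)
        out = resample_uniform(rec, 25.0)
        assert out.sample_rate == 25.0
        np.testing.assert_allclose(out.samples, np.tile([0, 0, 1.0], (out.n_samples, 1)))
        assert out.samples[:, 2].mean() == pytest.approx(1.0)

    def test_sinusoid_matches_analytic(self):
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t)
        rec = TriaxialRecording(np.column_stack([x, 0 * t, 1 + 0 * t]), 100.0, T0)
        out = resample_uniform(rec, 25.0)
        t_new = np.arange(out.n_samples) / 25.0
        assert np.max(np.abs(out.samples[:, 0] - np.sin(2 * np.pi * t_new))) < 0.01

    def test_same_rate_identity_and_bad_rate(self):
        rec = TriaxialRecording(np.random.default_rng(0).normal(0, 1, (50, 3)),
                                25.0, T0)
        np.testing.assert_allclose(resample_uniform(rec, 25.0).samples,
                                   rec.samples, atol=1e-9)
        with pytest.raises(ValueError):
            resample_uniform(rec, 0.0)


class TestNonwearIntervals:
    @given(st.lists(st.tuples(st.integers(0, 200), st.integers(1, 60)),
                    max_size=8))
    def test_normalisation_sorted_and_disjoint(self, raw):
        ivs = [(T0 + pd.Timedelta(minutes=a), T0 + pd.Timedelta(minutes=a + d))
               for a, d in raw]
        nw = NonwearIntervals(ivs)
        for (a1, b1), (a2, b2) in zip(nw.intervals, nw.intervals[1:]):
            assert b1 < a2

    def test_mask_and_overlap(self):
        nw = NonwearIntervals([(T0 + pd.Timedelta(minutes=1),
                                T0 + pd.Timedelta(minutes=3))])
        mask = nw.mask_on_grid(T0, 300, 1.0)
        assert mask.sum() == 120
        assert nw.overlap_seconds(T0, T0 + pd.Timedelta(minutes=2)) == 60.0

    def test_diary_csv_round_trip(self, tmp_path):
        from thighlie.signal_io import read_nonwear_csv, write_nonwear_csv

        nw = NonwearIntervals(
            [(T0 + pd.Timedelta(hours=2), T0 + pd.Timedelta(hours=4)),
             (T0 + pd.Timedelta(hours=20), T0 + pd.Timedelta(hours=21))],
            source="diary",
        )
        path = tmp_path / "diary.csv"
        write_nonwear_csv(nw, path)
        back = read_nonwear_csv(path)
        assert back.source == "diary"
        assert back.intervals == nw.intervals

    def test_union_merges_sources(self):
        a = NonwearIntervals([(T0, T0 + pd.Timedelta(minutes=5))], "diary")
        b = NonwearIntervals([(T0 + pd.Timedelta(minutes=4),
                               T0 + pd.Timedelta(minutes=9))], "automatic")
        u = a.union(b)
        assert len(u.intervals) == 1
        assert u.intervals[0][1] - u.intervals[0][0] == pd.Timedelta(minutes=9)


class TestEpochSeries:
    def test_grid_helpers(self):
        s = EpochSeries(np.arange(10.0), T0, 1.0, "sdvm")
        assert s.index_at(T0 + pd.Timedelta(seconds=3.2)) == 3
        assert s.same_grid(s.with_values(np.zeros(10)))
        assert not s.same_grid(EpochSeries(np.arange(9.0), T0))

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            EpochSeries(np.array([]), T0)
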