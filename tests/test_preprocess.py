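"""Clock synchronisation, orientation corrections, non-wear and valid days."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import butter, sosfilt

from thighlie._utils import rotation_about
from thighlie.errors import ReferenceError_, SyncError
from thighlie.features import inclination
from thighlie.preprocess import (
    ClockMap,
    OrientationCorrection,
    align_recording,
    daily_thigh_correction,
    detect_nonwear,
    standing_reference_correction,
    synchronize,
    valid_days,
)
from thighlie.signal_io import NonwearIntervals, TriaxialRecording

from conftest import T0, static_recording


def _band_limited(rng, n, fs, cutoff=3.0):
    sos = butter(4, cutoff, fs=fs, output="sos")
    x = sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _noisy_pair(delay_samples=0, fs=25.0, minutes=20.0, seed=0):
    """Two recordings of one shared movement signal, B delayed by an integer
    number of samples on its stamped timeline."""
    rng = np.random.default_rng(seed)
    n = int(minutes * 60 * fs)
    pad = 4000
    base = 1.0 + 0.05 * _band_limited(rng, n + pad, fs)
    a = base[pad:]
    b = base[pad - delay_samples: pad - delay_samples + n]
    mk = lambda vm, plc: TriaxialRecording(
        np.column_stack([-vm, np.zeros(n), np.zeros(n)]), fs, T0, plc)
    return mk(a, "thigh"), mk(b, "back")


class TestSynchronize:
    def test_known_delay_recovered_within_one_sample(self):
        rec_a, rec_b = _noisy_pair(delay_samples=75)  # 3.00 s
        cmap = synchronize(rec_a, rec_b, chunk_length=60.0, max_lag=10.0)
        assert cmap.offset == pytest.approx(3.0, abs=1 / 25.0)
        assert abs(cmap.drift) < 1e-6

    def test_identity_offset_near_zero(self):
        rec_a, rec_b = _noisy_pair(delay_samples=0)
        cmap = synchronize(rec_a, rec_b, chunk_length=60.0, max_lag=10.0)
        assert abs(cmap.offset) <= 1 / 25.0

    def test_antisymmetric(self):
        rec_a, rec_b = _noisy_pair(delay_samples=40, seed=3)
        ab = synchronize(rec_a, rec_b, chunk_length=60.0, max_lag=10.0)
        ba = synchronize(rec_b, rec_a, chunk_length=60.0, max_lag=10.0)
        assert ab.offset == pytest.approx(-ba.offset, abs=1 / 25.0)

    def test_insufficient_overlap(self):
        rec_a, rec_b = _noisy_pair(minutes=5.0)
        with pytest.raises(SyncError):
            synchronize(rec_a, rec_b, chunk_length=60.0, max_lag=10.0)

    def test_flat_signal_low_confidence(self):
        n = 25 * 60 * 20
        rec = TriaxialRecording(np.tile([-1.0, 0, 0], (n, 1)), 25.0, T0)
        with pytest.raises(SyncError):
            synchronize(rec, rec, chunk_length=60.0, max_lag=10.0)

    def test_clockmap_roundtrip_and_inverse(self, tmp_path):
        cmap = ClockMap(offset=12.5, drift=3e-6, residual_mad=0.01, n_chunks=40)
        path = tmp_path / "cmap.json"
        cmap.to_json(path)
        back = ClockMap.from_json(path)
        assert back.offset == cmap.offset and back.drift == cmap.drift
        inv = cmap.inverse()
        t = np.array([0.0, 1000.0, 86000.0])
        np.testing.assert_allclose(inv.body_time(cmap.body_time(t)),
                                   cmap.stamped_on_b(inv.stamped_on_b(t)), atol=1e-9)
        with pytest.raises(ValueError):
            ClockMap(offset=0.0, drift=0.5)

    def test_align_recording_undoes_delay(self):
        rec_a, rec_b = _noisy_pair(delay_samples=50, seed=5)
        aligned = align_recording(rec_b, rec_a, ClockMap(offset=2.0))
        # interior samples must match the thigh signal exactly
        np.testing.assert_allclose(aligned.samples[100:-100, 0],
                                   rec_a.samples[100:-100, 0], atol=1e-9)


class TestStandingCorrection:
    def test_already_aligned_gives_identity(self, standing_rec):
        corr = standing_reference_correction(standing_rec, (5.0, 55.0))
        assert corr.angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_ten_degree_tilt_recovered_exactly(self):
        tilt = rotation_about([0.0, 1.0, 0.0], 10.0)
        direction = tilt @ np.array([-1.0, 0.0, 0.0])
        rec = static_recording(direction)
        corr = standing_reference_correction(rec, (5.0, 55.0))
        assert corr.angle_deg == pytest.approx(10.0, abs=1e-9)
        fixed = corr.apply(rec)
        assert inclination(fixed).values[10] == pytest.approx(0.0, abs=1e-6)

    def test_motion_in_interval_rejected(self):
        rng = np.random.default_rng(1)
        rec = static_recording([-1.0, 0, 0], noise_sd=0.3, rng=rng)
        with pytest.raises(ReferenceError_):
            standing_reference_correction(rec, (5.0, 55.0))

    def test_degenerate_magnitude_rejected(self):
        rec = static_recording([-0.3, 0.0, 0.0])
        with pytest.raises(ReferenceError_):
            standing_reference_correction(rec, (5.0, 55.0))

    def test_short_interval_rejected(self, standing_rec):
        with pytest.raises(ValueError):
            standing_reference_correction(standing_rec, (5.0, 8.0))

    def test_second_pass_is_identity(self):
        tilt = rotation_about([0.0, 0.3, 0.7], 7.0)
        rec = static_recording(tilt @ np.array([-1.0, 0.0, 0.0]))
        once = standing_reference_correction(rec, (5.0, 55.0)).apply(rec)
        again = standing_reference_correction(once, (5.0, 55.0))
        assert again.angle_deg < 1e-6

    def test_rotations_are_proper(self):
        with pytest.raises(ValueError):
            OrientationCorrection(np.diag([1.0, 1.0, -1.0]))  # improper
        with pytest.raises(ValueError):
            OrientationCorrection(np.eye(3) * 2.0)


class TestDailyThighCorrection:
    @staticmethod
    def _walking_day(mount_deg, seed=0, walk_min=10):
        from thighlie.synthetic import generate_day

        sched = [("STAND", 1.0), ("WALK", float(walk_min)), ("SIT", 60.0),
                 ("WALK", 3.0), ("SIT", 45.0)]
        return generate_day(sched, seed=seed, mount_tilt_thigh=mount_deg)

    def test_mount_tilt_recovered(self):
        day = self._walking_day(8.0, seed=4)
        corr = daily_thigh_correction(day.thigh)
        assert corr.flag is None
        assert corr.angle_deg == pytest.approx(8.0, abs=2.0)

    def test_no_walking_returns_flagged_identity(self):
        from thighlie.synthetic import generate_day

        day = generate_day([("STAND", 2.0), ("SIT", 90.0)], seed=1)
        corr = daily_thigh_correction(day.thigh)
        assert corr.flag == "no-walking"
        np.testing.assert_array_equal(corr.rotation, np.eye(3))

    def test_perfect_mount_near_identity(self):
        day = self._walking_day(0.0, seed=6)
        corr = daily_thigh_correction(day.thigh)
        assert corr.angle_deg < 3.0  # walking posture itself tilts ~2 deg


class TestNonwear:
    @staticmethod
    def _rec_with_still_block(pre_h=2.0, still_h=3.0, post_h=2.0, fs=10.0):
        rng = np.random.default_rng(0)
        n_pre, n_still, n_post = (int(h * 3600 * fs) for h in (pre_h, still_h, post_h))
        active = lambda n: [0, 0, 1.0] + rng.normal(0, 0.02, (n, 3))
        block = np.vstack([active(n_pre), np.tile([0, 0, 1.0], (n_still, 1)),
                           active(n_post)])
        return TriaxialRecording(block, fs, T0)

    def test_still_block_detected_with_edge_tolerance(self):
        rec = self._rec_with_still_block()
        nw = detect_nonwear(rec, min_duration=120.0, sd_threshold=0.003)
        assert len(nw.intervals) == 1
        a, b = nw.intervals[0]
        assert abs((a - (T0 + pd.Timedelta(hours=2))).total_seconds()) <= 120
        assert abs((b - (T0 + pd.Timedelta(hours=5))).total_seconds()) <= 120

    def test_active_day_empty(self):
        rec = self._rec_with_still_block(still_h=0.01)
        assert detect_nonwear(rec).intervals == []

    def test_below_min_duration_ignored(self):
        rec = self._rec_with_still_block(pre_h=1.0, still_h=0.75, post_h=1.0)
        assert detect_nonwear(rec, min_duration=120.0).intervals == []


class TestValidDays:
    @staticmethod
    def _day_pair(wear_h_thigh, wear_h_back):
        # 1 Hz stand-in recordings spanning one calendar day
        n = 24 * 3600
        mk = lambda plc: TriaxialRecording(
            np.tile([-1.0, 0, 0], (n, 1)), 1.0, T0, plc)
        nw = lambda wear_h: NonwearIntervals(
            [(T0 + pd.Timedelta(hours=wear_h), T0 + pd.Timedelta(hours=24))])
        return mk("thigh"), mk("back"), nw(wear_h_thigh), nw(wear_h_back)

    def test_nine_hours_both_included(self):
        assert valid_days(*self._day_pair(9, 9)) == [T0.date()]

    def test_six_hours_back_excluded(self):
        assert valid_days(*self._day_pair(9, 6)) == []

    def test_exactly_eight_hours_excluded(self):
        assert valid_days(*self._day_pair(8, 9)) == []
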