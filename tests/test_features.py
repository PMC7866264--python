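"""Filtering, SDVM and the three angle families against analytic oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thighlie.features import (
    compute_features,
    inclination,
    lowpass,
    rebase_rotation,
    rotation_angle,
    roll_azimuth,
    sagittal_angle,
    sdvm,
)
from thighlie.signal_io import TriaxialRecording

from conftest import T0, static_recording


def _sine_rec(freq, fs=25.0, duration=60.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return TriaxialRecording(np.column_stack([x, 0 * t, 1 + 0 * t]), fs, T0), t


class TestLowpass:
    def test_dc_passband_identity(self):
        rec = static_recording([0.0, 0.0, 1.0])
        np.testing.assert_allclose(lowpass(rec, 5.0).samples, rec.samples, atol=1e-9)

    def test_stopband_attenuation(self):
        rec, _ = _sine_rec(10.0)
        out = lowpass(rec, 5.0)
        # ignore filter edge transients
        mid = out.samples[200:-200, 0]
        assert np.abs(mid).max() < 0.1

    def test_passband_amplitude_preserved(self):
        rec, _ = _sine_rec(0.5)
        mid = lowpass(rec, 5.0).samples[200:-200, 0]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.02)

    def test_cutoff_must_be_below_nyquist(self):
        rec = static_recording([0, 0, 1.0])
        with pytest.raises(ValueError):
            lowpass(rec, 12.5)


class TestSdvm:
    def test_constant_signal_is_zero(self):
        rec = static_recording([0.0, 0.0, 1.0])
        assert np.all(sdvm(rec).values == 0.0)

    def test_two_point_alternation_closed_form(self):
        n = 10 * 50
        vm = np.where(np.arange(n) % 2 == 0, 0.99, 1.01)
        rec = TriaxialRecording(np.column_stack([0 * vm, 0 * vm, vm]), 50.0, T0)
        vals = sdvm(rec, window=2.0).values
        # interior epochs have complete, balanced windows
        np.testing.assert_allclose(vals[1:-1], 0.01, atol=1e-12)
        np.testing.assert_allclose(vals, 0.01, atol=1e-4)

    def test_white_noise_matches_sampling_distribution(self):
        rng = np.random.default_rng(11)
        vm = 1.0 + rng.normal(0, 0.02, 120 * 50)
        rec = TriaxialRecording(np.column_stack([0 * vm, 0 * vm, vm]), 50.0, T0)
        vals = sdvm(rec, window=2.0).values
        assert 0.015 < np.median(vals) < 0.025

    def test_window_validation(self):
        rec = static_recording([0, 0, 1.0])
        with pytest.raises(ValueError):
            sdvm(rec, window=0.5)

    @given(st.permutations([0, 1, 2]), st.tuples(*[st.sampled_from([-1.0, 1.0])] * 3))
    def test_invariant_under_axis_permutation_and_sign(self, perm, signs):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 0.05, (500, 3)) + [0, 0, 1.0]
        rec = TriaxialRecording(base, 25.0, T0)
        other = TriaxialRecording(base[:, perm] * np.asarray(signs), 25.0, T0)
        np.testing.assert_allclose(sdvm(rec).values, sdvm(other).values, atol=1e-12)


class TestAngles:
    @pytest.mark.parametrize(
        "direction, inc_deg",
        [
            ([-1.0, 0.0, 0.0], 0.0),      # standing: reading along -U
            ([0.0, 0.0, -1.0], 90.0),     # horizontal, W up
            ([-np.sqrt(0.5), 0.0, -np.sqrt(0.5)], 45.0),
        ],
    )
    def test_inclination_definition(self, direction, inc_deg):
        rec = static_recording(direction)
        assert inclination(rec).values[5] == pytest.approx(inc_deg, abs=1e-6)

    @pytest.mark.parametrize(
        "direction, theta_deg",
        [
            ([0.0, 0.0, 1.0], -90.0),   # supine back: W points down
            ([0.0, 0.0, -1.0], 90.0),   # stomach: W points up
        ],
    )
    def test_sagittal_sign_convention(self, direction, theta_deg):
        rec = static_recording(direction, placement="back")
        assert sagittal_angle(rec).values[5] == pytest.approx(theta_deg, abs=1e-6)

    def test_sitting_thigh_front_up(self):
        # horizontal thigh with the front (W) facing up
        rec = static_recording([0.0, 0.0, -1.0])
        assert sagittal_angle(rec).values[5] == pytest.approx(90.0, abs=1e-6)

    def test_low_gravity_epochs_are_missing(self):
        rec = static_recording([0.0, 0.0, 0.2])
        assert np.isnan(inclination(rec).values).all()
        assert np.isnan(sagittal_angle(rec).values).all()

    def test_brute_force_geometry_agreement(self):
        # independent vector geometry on random static orientations
        rng = np.random.default_rng(5)
        for _ in range(25):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            rec = static_recording(v, duration_s=10)
            up = -v
            inc_expect = np.degrees(np.arccos(np.clip(up[0], -1, 1)))
            th_expect = np.degrees(np.arcsin(np.clip(up[2], -1, 1)))
            assert inclination(rec).values[4] == pytest.approx(inc_expect, abs=0.1)
            assert sagittal_angle(rec).values[4] == pytest.approx(th_expect, abs=0.1)
            if np.hypot(up[1], up[2]) >= 0.2:
                phi_expect = np.degrees(np.arctan2(up[1], up[2]))
                assert roll_azimuth(rec).values[4] == pytest.approx(phi_expect, abs=0.1)


class TestRotation:
    @staticmethod
    def _roll_rec(phi_deg_per_epoch, inc=88.0, fs=25.0):
        phi = np.repeat(np.deg2rad(phi_deg_per_epoch), int(fs))
        inc_r = np.deg2rad(inc)
        up = np.column_stack(
            [np.full_like(phi, np.cos(inc_r)),
             np.sin(inc_r) * np.sin(phi),
             np.sin(inc_r) * np.cos(phi)]
        )
        return TriaxialRecording(-up, fs, T0)

    def test_constant_orientation_is_zero(self):
        rec = self._roll_rec(np.full(60, 30.0))
        rot = rotation_angle(rec)
        np.testing.assert_allclose(rot.values, 0.0, atol=1e-6)

    def test_rollover_reaches_ninety(self):
        phi = np.concatenate([np.zeros(30), np.linspace(0, 90, 10), np.full(30, 90.0)])
        rot = rotation_angle(self._roll_rec(phi))
        assert np.nanmax(np.abs(rot.values)) == pytest.approx(90.0, abs=2.0)

    def test_vertical_thigh_is_missing(self):
        rec = static_recording([-1.0, 0.0, 0.0])
        assert np.isnan(rotation_angle(rec).values).all()

    def test_invariant_to_joint_constant_offset(self):
        phi = np.concatenate([np.zeros(20), np.full(40, 75.0)])
        r1 = rotation_angle(self._roll_rec(phi)).values
        r2 = rotation_angle(self._roll_rec(phi + 40.0)).values
        np.testing.assert_allclose(r1, r2, atol=1e-6)

    def test_rebase_uses_circular_median(self):
        phi = np.array([179.0, -179.0, 178.0, -178.0, 179.5] + [90.0] * 5)
        rebased = rebase_rotation(phi, ref_epochs=5)
        # reference sits near the +-180 seam; the 90 deg samples end up ~90 off
        assert np.abs(np.abs(rebased[5:]) - 90.0).max() < 3.0


def test_compute_features_bundles_shared_grid():
    rng = np.random.default_rng(2)
    rec = TriaxialRecording(rng.normal(0, 0.01, (1500, 3)) + [0, 0, 1.0], 25.0, T0)
    fs = compute_features(rec)
    assert len(fs) == 60
    assert fs.sdvm.same_grid(fs.inc) and fs.inc.same_grid(fs.roll)
    frame = fs.to_frame()
    assert list(frame.columns) == ["time", "sdvm", "inc", "theta", "rot"]
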