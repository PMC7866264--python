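"""Movement and orientation features on the 1 s epoch grid.

All features are computed from a 5 Hz low-pass filtered signal so that the
per-epoch gravity estimate and the movement-intensity measure share one
filter chain:

* ``sdvm`` — SD of the vector magnitude over a centered 2 s window, in g;
* ``inclination`` — angle between the segment's longitudinal +U axis and the
  upward vertical (0° when standing, 90° when the segment is horizontal);
* ``sagittal_angle`` — signed angle of the sagittal W axis above (+) or
  below (−) the horizontal plane, θ = asin(component of the upward vertical
  along W);
* ``rotation_angle`` — roll about U, φ = atan2(g_V, g_W) of the projection of
  the upward vertical onto the V–W plane, reported relative to the circular
  median of the first seconds of the interval of interest.

A motionless sensor reads a unit vector along gravity (down), so the upward
vertical in the sensor frame is the negative of the per-epoch mean
acceleration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from ._utils import (
    circular_median_deg,
    epoch_window_mean,
    epoch_window_sd,
    wrap_deg,
)
from .signal_io import EpochSeries, TriaxialRecording

#: gravity estimates with mean-vector magnitude below this are unusable
MIN_GRAVITY_G = 0.5
#: roll is ill-defined when the V–W projection of the vertical is this small
MIN_ROLL_PROJECTION_G = 0.2


def lowpass(rec: TriaxialRecording, cutoff: float = 5.0, order: int = 4) -> TriaxialRecording:
    """Zero-phase Butterworth low-pass per axis (forward-backward)."""
    if not 0 < cutoff < rec.sample_rate / 2:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist={rec.sample_rate / 2} Hz), got {cutoff}"
        )
    sos = butter(order, cutoff, btype="low", fs=rec.sample_rate, output="sos")
    return replace(rec, samples=sosfiltfilt(sos, rec.samples, axis=0))


def sdvm(rec_filtered: TriaxialRecording, window: float = 2.0) -> EpochSeries:
    """Per-epoch SD of the vector magnitude over a centered window, in g."""
    if window < 1.0:
        raise ValueError("window must be at least 1 s")
    if window * rec_filtered.sample_rate < 2:
        raise ValueError("window spans fewer than 2 samples")
    vm = rec_filtered.vector_magnitude()
    sd = epoch_window_sd(vm, rec_filtered.sample_rate, window_s=window)
    return EpochSeries(sd, rec_filtered.start_time, 1.0, "sdvm")


def epoch_gravity(rec_filtered: TriaxialRecording, window: float = 2.0) -> np.ndarray:
    """Per-epoch mean acceleration vector (M, 3) over a centered window."""
    return epoch_window_mean(rec_filtered.samples, rec_filtered.sample_rate, window_s=window)


def _upward(gravity: np.ndarray):
    """Unit upward vertical per epoch and the mean-vector magnitude."""
    mag = np.linalg.norm(gravity, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        up = -gravity / mag[:, None]
    return up, mag


def inclination(rec_filtered: TriaxialRecording, window: float = 2.0) -> EpochSeries:
    """Angle (deg) between +U and the upward vertical; NaN when the mean
    vector magnitude is below 0.5 g."""
    up, mag = _upward(epoch_gravity(rec_filtered, window))
    inc = np.degrees(np.arccos(np.clip(up[:, 0], -1.0, 1.0)))
    inc[mag < MIN_GRAVITY_G] = np.nan
    return EpochSeries(inc, rec_filtered.start_time, 1.0, "inclination")


def sagittal_angle(rec_filtered: TriaxialRecording, window: float = 2.0) -> EpochSeries:
    """Signed angle (deg) of the W axis above the horizontal plane."""
    up, mag = _upward(epoch_gravity(rec_filtered, window))
    theta = np.degrees(np.arcsin(np.clip(up[:, 2], -1.0, 1.0)))
    theta[mag < MIN_GRAVITY_G] = np.nan
    return EpochSeries(theta, rec_filtered.start_time, 1.0, "sagittal_angle")


def roll_azimuth(rec_filtered: TriaxialRecording, window: float = 2.0) -> EpochSeries:
    """Absolute roll azimuth φ = atan2(up_V, up_W) in degrees.

    NaN where the projection of the upward vertical onto the V–W plane is
    below 0.2 g (segment near vertical, roll ill-defined).  Downstream code
    re-references this per sedentary bout; see :func:`rebase_rotation`.
    """
    g = epoch_gravity(rec_filtered, window)
    up_g = -g  # in g units, not normalised: the guard is on physical magnitude
    proj = np.hypot(up_g[:, 1], up_g[:, 2])
    phi = np.degrees(np.arctan2(up_g[:, 1], up_g[:, 2]))
    phi[proj < MIN_ROLL_PROJECTION_G] = np.nan
    return EpochSeries(phi, rec_filtered.start_time, 1.0, "rotation_angle")


def rebase_rotation(phi: np.ndarray, ref_epochs: int = 10) -> np.ndarray:
    """Rotation relative to the circular median of the first `ref_epochs`
    values, wrapped to [-180, 180)."""
    phi = np.asarray(phi, dtype=float)
    ref = circular_median_deg(phi[: max(ref_epochs, 1)])
    out = wrap_deg(phi - ref)
    out[~np.isfinite(phi)] = np.nan
    return out


def rotation_angle(rec_filtered: TriaxialRecording, ref_window: float = 10.0,
                   window: float = 2.0) -> EpochSeries:
    """Roll about U relative to the start of the recording slice.

    The reference orientation is the circular median of the roll azimuth over
    the first ``ref_window`` seconds; apply this to one sedentary bout at a
    time.
    """
    phi = roll_azimuth(rec_filtered, window)
    return phi.with_values(rebase_rotation(phi.values, int(round(ref_window))))


@dataclass
class FeatureSet:
    """Bundled per-second features on a shared grid.

    ``roll`` carries the absolute roll azimuth; rotation relative to a bout
    is derived from it with :func:`rebase_rotation`.
    """

    sdvm: EpochSeries
    inc: EpochSeries
    theta: EpochSeries
    roll: EpochSeries

    def __post_init__(self):
        for s in (self.inc, self.theta, self.roll):
            if not self.sdvm.same_grid(s):
                raise ValueError("feature series must share one epoch grid")

    def __len__(self) -> int:
        return len(self.sdvm)

    @property
    def start_time(self):
        return self.sdvm.start_time

    @property
    def epoch_length(self) -> float:
        return self.sdvm.epoch_length

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.sdvm.times(),
                "sdvm": self.sdvm.values,
                "inc": self.inc.values,
                "theta": self.theta.values,
                "rot": self.roll.values,
            }
        )


def compute_features(rec: TriaxialRecording, lp_hz: float = 5.0,
                     window_s: float = 2.0) -> FeatureSet:
    """Low-pass once and derive SDVM plus the three angle families."""
    filt = lowpass(rec, lp_hz)
    return FeatureSet(
        sdvm=sdvm(filt, window_s),
        inc=inclination(filt, window_s),
        theta=sagittal_angle(filt, window_s),
        roll=roll_azimuth(filt, window_s),
    )
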