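"""Two-sensor preparation: clock synchronisation, orientation correction
from reference postures, automatic non-wear detection and valid-day
selection.

Synchronisation estimates, per 10-minute chunk, the lag of the back sensor's
vector-magnitude signal relative to the thigh's by normalised
cross-correlation, then fits lag against time with a robust (Tukey bisquare)
linear regression.  The intercept is the clock offset at the thigh
recording's start and the slope is the relative clock drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.signal import butter, correlate, sosfiltfilt

from ._utils import epoch_window_mean, rotation_between, unit
from .errors import ReferenceError_, SyncError
from .signal_io import NonwearIntervals, TriaxialRecording, _as_utc

MAX_ABS_DRIFT = 0.01  # beyond this the clock map would not be monotone-sane


@dataclass
class ClockMap:
    """Affine map from the A (thigh) timeline to the B (back) clock.

    ``offset`` is B-clock minus A-clock at A's start; ``drift`` is seconds of
    divergence per second.  A body event at A-time ``t`` (seconds from A's
    start) is stamped ``t * (1 + drift) + offset`` on B's clock.
    """

    offset: float
    drift: float = 0.0
    residual_mad: float = 0.0
    n_chunks: int = 0

    def __post_init__(self):
        if abs(self.drift) >= MAX_ABS_DRIFT:
            raise ValueError("implausible drift; clock map must stay monotone")
        if self.residual_mad < 0:
            raise ValueError("residual_mad must be non-negative")

    def stamped_on_b(self, t_a):
        return np.asarray(t_a, float) * (1.0 + self.drift) + self.offset

    def body_time(self, t_b):
        return (np.asarray(t_b, float) - self.offset) / (1.0 + self.drift)

    def inverse(self) -> "ClockMap":
        return ClockMap(
            offset=-self.offset / (1.0 + self.drift),
            drift=-self.drift / (1.0 + self.drift),
            residual_mad=self.residual_mad,
            n_chunks=self.n_chunks,
        )

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "offset_s": self.offset,
                "drift": self.drift,
                "residual_mad_s": self.residual_mad,
                "n_chunks": self.n_chunks,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "ClockMap":
        try:
            data = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                data = json.load(fh)
        return cls(data["offset_s"], data["drift"], data.get("residual_mad_s", 0.0),
                   data.get("n_chunks", 0))


def synchronize(rec_a: TriaxialRecording, rec_b: TriaxialRecording,
                chunk_length: float = 600.0, max_lag: float = 120.0,
                min_peak_corr: float = 0.2) -> ClockMap:
    """Estimate the B-vs-A clock map from free-living signal content.

    Requires at least 10 chunks of overlap.  Chunks whose correlation peak is
    below ``min_peak_corr`` (or whose signal is flat) are dropped; if more
    than half are dropped a :class:`SyncError` is raised.
    """
    if rec_b.sample_rate != rec_a.sample_rate:
        from .signal_io import resample_uniform

        rec_b = resample_uniform(rec_b, rec_a.sample_rate)
    fs = rec_a.sample_rate
    tb0 = (rec_b.start_time - rec_a.start_time).total_seconds()

    ov_start = max(0.0, tb0 - max_lag)
    ov_end = min(rec_a.duration_s, tb0 + rec_b.duration_s + max_lag)
    if ov_end - ov_start < 10 * chunk_length:
        raise SyncError(
            f"insufficient overlap: {ov_end - ov_start:.0f} s < 10 x {chunk_length:.0f} s"
        )

    vm_a = rec_a.vector_magnitude()
    vm_b = rec_b.vector_magnitude()
    lagmax = int(round(max_lag * fs))
    clen = int(round(chunk_length * fs))

    rows = []  # (t_mid, lag_s, peak_corr)
    n_chunks = 0
    start = ov_start
    while start + chunk_length <= ov_end + 1e-9:
        i0 = int(round(start * fs))
        a_seg = vm_a[i0: i0 + clen]
        if len(a_seg) < clen:
            break
        n_chunks += 1
        # B samples covering [start - max_lag, start + chunk + max_lag] on B's clock
        j0 = int(np.ceil((start - max_lag - tb0) * fs - 1e-9))
        j1 = j0 + clen + 2 * lagmax
        j0c, j1c = max(j0, 0), min(j1, len(vm_b))
        b_seg = vm_b[j0c:j1c]
        start += chunk_length
        if len(b_seg) < clen + lagmax // 2:
            continue
        a_c = a_seg - a_seg.mean()
        b_c = b_seg - b_seg.mean()
        sd_a, sd_b = a_c.std(), b_c.std()
        if sd_a < 1e-7 or sd_b < 1e-7:
            continue
        xc = correlate(b_c, a_c, mode="valid", method="fft")
        m = int(np.argmax(xc))
        peak = xc[m] / (sd_a * sd_b * len(a_c))
        if peak < min_peak_corr:
            continue
        # sub-sample refinement by parabolic interpolation around the peak
        frac = 0.0
        if 0 < m < len(xc) - 1:
            denom = xc[m - 1] - 2 * xc[m] + xc[m + 1]
            if denom < 0:
                frac = float(np.clip(0.5 * (xc[m - 1] - xc[m + 1]) / denom, -0.5, 0.5))
        lag = (tb0 + j0c / fs + (m + frac) / fs) - (start - chunk_length)
        rows.append(((start - chunk_length) + 0.5 * chunk_length, lag, peak))

    if n_chunks == 0 or len(rows) < max(2, n_chunks // 2):
        raise SyncError(
            f"low-confidence synchronisation: only {len(rows)}/{n_chunks} usable chunks"
        )

    t = np.array([r[0] for r in rows])
    lag = np.array([r[1] for r in rows])
    X = sm.add_constant(t)
    fit = sm.RLM(lag, X, M=sm.robust.norms.TukeyBiweight()).fit()
    offset, drift = float(fit.params[0]), float(fit.params[1])
    resid = lag - (offset + drift * t)
    mad = float(np.median(np.abs(resid - np.median(resid))) * 1.4826)
    return ClockMap(offset=offset, drift=drift, residual_mad=mad, n_chunks=len(rows))


def align_recording(rec_b: TriaxialRecording, rec_a: TriaxialRecording,
                    cmap: ClockMap) -> TriaxialRecording:
    """Resample B onto A's grid using the clock map.

    Sample values outside B's span hold the edge value; the returned
    recording shares A's start time, rate and length but keeps B's placement.
    """
    tb0 = (rec_b.start_time - rec_a.start_time).total_seconds()
    t_a = rec_a.seconds()
    src = cmap.stamped_on_b(t_a) - tb0  # seconds on B's own sample axis
    tb = rec_b.seconds()
    out = np.column_stack([np.interp(src, tb, rec_b.samples[:, k]) for k in range(3)])
    return TriaxialRecording(out, rec_a.sample_rate, rec_a.start_time,
                             placement=rec_b.placement, sensor_id=rec_b.sensor_id)


# ---------------------------------------------------------------------------
# Orientation corrections
# ---------------------------------------------------------------------------

@dataclass
class OrientationCorrection:
    """Proper rotation mapping the sensor frame onto the segment frame."""

    rotation: np.ndarray
    source_interval: tuple | None = None
    placement: str = "thigh"
    flag: str | None = None

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    @property
    def angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def apply(self, rec: TriaxialRecording) -> TriaxialRecording:
        return replace(rec, samples=rec.samples @ self.rotation.T)


def standing_reference_correction(rec: TriaxialRecording,
                                  interval: tuple) -> OrientationCorrection:
    """Correction from a standing-still reference interval.

    The minimal rotation taking the interval's mean measured gravity
    direction onto the segment's −U axis (gravity points caudal when
    standing); yaw about the vertical cannot be observed from gravity alone
    and is left unchanged.  `interval` is a (start, end) pair of timestamps
    or of seconds relative to the recording start.
    """
    a, b = interval
    if not isinstance(a, (int, float)):
        a = (_as_utc(a) - rec.start_time).total_seconds()
        b = (_as_utc(b) - rec.start_time).total_seconds()
    if b - a < 5.0:
        raise ValueError("reference interval must span at least 5 s")
    seg = rec.slice_seconds(float(a), float(b))
    vm = seg.vector_magnitude()
    if float(vm.std()) > 0.1:
        raise ReferenceError_(
            f"reference interval contains motion (SD of VM = {vm.std():.3f} g > 0.1 g)"
        )
    mean_vec = seg.samples.mean(axis=0)
    mag = float(np.linalg.norm(mean_vec))
    if mag < 0.1:
        raise ReferenceError_("degenerate reference: near-zero mean acceleration")
    if not 0.9 <= float(vm.mean()) <= 1.1:
        raise ReferenceError_(
            f"reference interval mean magnitude {vm.mean():.3f} g outside [0.9, 1.1] g"
        )
    R = rotation_between(unit(mean_vec), np.array([-1.0, 0.0, 0.0]))
    return OrientationCorrection(R, source_interval=tuple(interval),
                                 placement=rec.placement)


def detect_walking(rec: TriaxialRecording, band=(1.0, 3.0),
                   power_rms_g: float = 0.05, max_inc_deg: float = 30.0) -> np.ndarray:
    """Boolean per-second mask of candidate walking epochs.

    An epoch is walking-like when the 1–3 Hz band RMS of the vector
    magnitude exceeds ``power_rms_g`` and the thigh inclination is below
    ``max_inc_deg``.
    """
    from .features import inclination, lowpass

    fs = rec.sample_rate
    vm = rec.vector_magnitude()
    sos = butter(3, band, btype="bandpass", fs=fs, output="sos")
    bp = sosfiltfilt(sos, vm)
    rms = np.sqrt(epoch_window_mean(bp * bp, fs, window_s=2.0))
    inc = inclination(lowpass(rec, 5.0)).values
    with np.errstate(invalid="ignore"):
        return (rms > power_rms_g) & (inc < max_inc_deg)


def daily_thigh_correction(rec: TriaxialRecording, min_walk_s: float = 60.0
                           ) -> OrientationCorrection:
    """Walking-based thigh mounting correction for one day of wear.

    Aligns the median gravity direction over detected walking epochs with
    −U.  If less than ``min_walk_s`` of walking is found the identity is
    returned with flag ``"no-walking"``.
    """
    walking = detect_walking(rec)
    if int(walking.sum()) < min_walk_s:
        return OrientationCorrection(np.eye(3), placement=rec.placement,
                                     flag="no-walking")
    g = epoch_window_mean(rec.samples, rec.sample_rate, window_s=2.0)
    med = np.median(g[walking], axis=0)
    if np.linalg.norm(med) < 0.1:
        return OrientationCorrection(np.eye(3), placement=rec.placement,
                                     flag="degenerate-walking")
    R = rotation_between(unit(med), np.array([-1.0, 0.0, 0.0]))
    return OrientationCorrection(R, placement=rec.placement)


# ---------------------------------------------------------------------------
# Non-wear and valid days
# ---------------------------------------------------------------------------

def detect_nonwear(rec: TriaxialRecording, min_duration: float = 120.0,
                   sd_threshold: float = 0.003) -> NonwearIntervals:
    """Automatic non-wear: per-minute SD below threshold on all three axes
    for at least ``min_duration`` consecutive minutes."""
    fs = rec.sample_rate
    spm = int(round(60 * fs))
    n_min = rec.n_samples // spm
    if n_min < 1 or n_min < min_duration:
        return NonwearIntervals([], source="automatic")
    x = rec.samples[: n_min * spm].reshape(n_min, spm, 3)
    quiet = (x.std(axis=1) < sd_threshold).all(axis=1)
    intervals = []
    i = 0
    while i < n_min:
        if quiet[i]:
            j = i
            while j < n_min and quiet[j]:
                j += 1
            if (j - i) >= min_duration:  # run length in minutes
                intervals.append(
                    (rec.start_time + pd.Timedelta(seconds=i * 60.0),
                     rec.start_time + pd.Timedelta(seconds=j * 60.0))
                )
            i = j
        else:
            i += 1
    return NonwearIntervals(intervals, source="automatic")


def valid_days(rec_thigh: TriaxialRecording, rec_back: TriaxialRecording,
               nonwear_thigh: NonwearIntervals | None = None,
               nonwear_back: NonwearIntervals | None = None,
               min_wear_h: float = 8.0) -> list:
    """Calendar days with strictly more than ``min_wear_h`` hours of wear on
    BOTH sensors (recorded time minus non-wear)."""
    nonwear_thigh = nonwear_thigh or NonwearIntervals([])
    nonwear_back = nonwear_back or NonwearIntervals([])
    def rec_end(rec):
        return rec.start_time + pd.Timedelta(seconds=rec.duration_s)

    days = []
    first = min(rec_thigh.start_time, rec_back.start_time).normalize()
    last = max(rec_end(rec_thigh), rec_end(rec_back)).normalize()
    day = first
    while day <= last:
        nxt = day + pd.Timedelta(days=1)
        ok = True
        for rec, nw in ((rec_thigh, nonwear_thigh), (rec_back, nonwear_back)):
            lo = max(rec.start_time, day)
            hi = min(rec_end(rec), nxt)
            covered = max((hi - lo).total_seconds(), 0.0)
            wear = covered - nw.overlap_seconds(day, nxt)
            if not wear > min_wear_h * 3600.0:
                ok = False
                break
        if ok:
            days.append(day.date())
        day = nxt
    return days
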