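"""Data model and CSV I/O for raw triaxial recordings and derived epoch series.

A recording holds uniformly sampled 3-axis acceleration in units of g in the
sensor frame: axis U longitudinal, axis V mediolateral, axis W sagittal (out
of the front of the thigh, out of the back posteriorly).  The sign convention
is the "gravity" one: a motionless sensor reads a unit vector pointing along
gravity, so standing upright gives approximately (-1, 0, 0) on (U, V, W)
after orientation correction.

The canonical interchange format is CSV with header ``time,ax,ay,az``,
ISO-8601 UTC timestamps and acceleration in g.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GapError, ParseError

PLACEMENTS = ("thigh", "back")

#: Labels used by per-epoch series of kind activity_class / lying_label.
ACTIVITY_LABELS = ("SED", "UPRIGHT", "NONWEAR", "MISSING")
LYING_LABELS = ("LIE", "SIT", "OTHER", "MISSING", "NONWEAR")

_CSV_COLUMNS = ("time", "ax", "ay", "az")


def _as_utc(ts) -> pd.Timestamp:
    t = pd.Timestamp(ts)
    if t.tzinfo is None:
        return t.tz_localize("UTC")
    return t.tz_convert("UTC")


@dataclass
class TriaxialRecording:
    """Uniformly sampled triaxial acceleration in g.

    Sample i is stamped ``start_time + i / sample_rate``.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: pd.Timestamp
    placement: str = "thigh"
    sensor_id: str = ""

    def __post_init__(self):
        self.samples = np.ascontiguousarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (N, 3) array")
        if self.samples.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if np.max(np.abs(self.samples)) > 16.0 + 1e-9:
            raise ValueError("sample magnitudes exceed 16 g")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}")
        self.start_time = _as_utc(self.start_time)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(
            np.arange(self.n_samples) / self.sample_rate, unit="s"
        )

    def seconds(self) -> np.ndarray:
        """Sample times in seconds relative to start_time."""
        return np.arange(self.n_samples) / self.sample_rate

    def vector_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.samples, axis=1)

    def slice_seconds(self, t0: float, t1: float) -> "TriaxialRecording":
        """Sub-recording covering [t0, t1) seconds relative to start."""
        i0 = max(int(np.ceil(t0 * self.sample_rate - 1e-9)), 0)
        i1 = min(int(np.ceil(t1 * self.sample_rate - 1e-9)), self.n_samples)
        if i1 <= i0:
            raise ValueError("empty slice")
        return replace(
            self,
            samples=self.samples[i0:i1].copy(),
            start_time=self.start_time + pd.Timedelta(seconds=i0 / self.sample_rate),
        )


@dataclass
class EpochSeries:
    """Per-epoch values on a left-aligned, half-open [t, t+epoch) grid."""

    values: np.ndarray
    start_time: pd.Timestamp
    epoch_length: float = 1.0
    kind: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not self.epoch_length > 0:
            raise ValueError("epoch_length must be positive")
        self.start_time = _as_utc(self.start_time)

    def __len__(self) -> int:
        return len(self.values)

    def times(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(
            np.arange(len(self)) * self.epoch_length, unit="s"
        )

    def same_grid(self, other: "EpochSeries") -> bool:
        return (
            len(self) == len(other)
            and self.epoch_length == other.epoch_length
            and self.start_time == other.start_time
        )

    def index_at(self, ts) -> int:
        """Epoch index containing timestamp ts (may be out of range)."""
        dt = (_as_utc(ts) - self.start_time).total_seconds()
        return int(np.floor(dt / self.epoch_length + 1e-9))

    def with_values(self, values) -> "EpochSeries":
        return EpochSeries(np.asarray(values), self.start_time, self.epoch_length, self.kind)

    def to_frame(self, name: str | None = None) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times(), name or self.kind or "value": self.values})


@dataclass
class NonwearIntervals:
    """Non-overlapping, time-ordered (start, end) periods of non-wear."""

    intervals: Sequence[tuple] = field(default_factory=list)
    source: str = "automatic"

    def __post_init__(self):
        ivs = sorted(
            ((_as_utc(a), _as_utc(b)) for a, b in self.intervals), key=lambda p: p[0]
        )
        merged: list[tuple] = []
        for a, b in ivs:
            if not a < b:
                raise ValueError("interval start must precede end")
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        self.intervals = merged

    def union(self, other: "NonwearIntervals") -> "NonwearIntervals":
        return NonwearIntervals(
            list(self.intervals) + list(other.intervals),
            source=self.source if self.source == other.source else "diary+automatic",
        )

    def mask_on_grid(self, start_time, n: int, epoch_length: float = 1.0) -> np.ndarray:
        """Boolean mask of epochs whose midpoint falls inside any interval."""
        start_time = _as_utc(start_time)
        mids = np.arange(n) * epoch_length + 0.5 * epoch_length
        mask = np.zeros(n, dtype=bool)
        for a, b in self.intervals:
            ta = (a - start_time).total_seconds()
            tb = (b - start_time).total_seconds()
            mask |= (mids >= ta) & (mids < tb)
        return mask

    def overlap_seconds(self, a, b) -> float:
        """Total non-wear seconds inside window [a, b)."""
        a, b = _as_utc(a), _as_utc(b)
        total = 0.0
        for s, e in self.intervals:
            lo, hi = max(s, a), min(e, b)
            if lo < hi:
                total += (hi - lo).total_seconds()
        return total


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def write_recording(rec: TriaxialRecording, path) -> None:
    """Write a recording as ``time,ax,ay,az`` CSV (ISO-8601 UTC, g)."""
    df = pd.DataFrame(rec.samples, columns=list(_CSV_COLUMNS[1:]))
    df.insert(0, "time", rec.times().strftime("%Y-%m-%dT%H:%M:%S.%f"))
    try:
        df.to_csv(path, index=False, float_format="%.6f")
    except OSError as exc:
        raise OSError(f"cannot write recording to {path}: {exc}") from exc


def read_recording(path, placement: str = "thigh", *, sensor_id: str = "",
                   allow_gaps: bool = False, gap_tolerance: float = 1.5,
                   columns=_CSV_COLUMNS) -> TriaxialRecording:
    """Read a ``time,ax,ay,az`` CSV into a :class:`TriaxialRecording`.

    Sampling must be uniform; inter-sample intervals larger than
    ``gap_tolerance`` times the nominal interval raise :class:`GapError`
    listing the gaps, unless ``allow_gaps`` is set, in which case samples are
    linearly interpolated onto the uniform grid.
    """
    tcol, *axcols = columns
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, OSError, UnicodeDecodeError) as exc:
        raise ParseError(str(exc), path=path) from exc
    missing = [c for c in (tcol, *axcols) if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing}", path=path)
    if len(df) < 1:
        raise ParseError("no samples", path=path)

    times = pd.to_datetime(df[tcol], errors="coerce", utc=True, format="ISO8601")
    vals = df[axcols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = times.isna().to_numpy() | ~np.isfinite(vals).all(axis=1)
    if bad.any():
        # +2: header line and 1-based numbering
        raise ParseError("malformed row", path=path, line=int(np.argmax(bad)) + 2)

    t = (times - times.iloc[0]).dt.total_seconds().to_numpy()
    if len(t) == 1:
        raise ParseError("a single sample does not define a sample rate", path=path)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ParseError("timestamps must be strictly increasing", path=path,
                         line=int(np.argmax(dt <= 0)) + 3)
    nominal = float(np.median(dt))
    sample_rate = 1.0 / nominal
    gaps_idx = np.nonzero(dt > gap_tolerance * nominal)[0]
    if len(gaps_idx) and not allow_gaps:
        gaps = [(times.iloc[i], times.iloc[i + 1]) for i in gaps_idx]
        raise GapError(gaps, path=path)
    if len(gaps_idx):
        grid = np.arange(int(round(t[-1] / nominal)) + 1) * nominal
        vals = np.column_stack([np.interp(grid, t, vals[:, k]) for k in range(3)])
    return TriaxialRecording(
        samples=vals,
        sample_rate=sample_rate,
        start_time=times.iloc[0],
        placement=placement,
        sensor_id=sensor_id,
    )


def resample_uniform(rec: TriaxialRecording, target_rate: float) -> TriaxialRecording:
    """Linear interpolation of a recording onto a new uniform grid.

    start_time is preserved; the grid covers the original time span.
    """
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if target_rate == rec.sample_rate:
        return replace(rec, samples=rec.samples.copy())
    t_old = rec.seconds()
    n_new = int(np.floor(t_old[-1] * target_rate + 1e-9)) + 1
    t_new = np.arange(n_new) / target_rate
    out = np.column_stack([np.interp(t_new, t_old, rec.samples[:, k]) for k in range(3)])
    return replace(rec, samples=out, sample_rate=float(target_rate))


def write_labels(series: EpochSeries, path) -> None:
    """Write an epoch label/value series as ``time,label`` CSV."""
    series.to_frame("label").assign(
        time=lambda d: d["time"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    ).to_csv(path, index=False)


def read_nonwear_csv(path) -> NonwearIntervals:
    """Read diary non-wear intervals from a ``start,end[,source]`` CSV."""
    df = pd.read_csv(path)
    missing = [c for c in ("start", "end") if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing}", path=path)
    source = str(df["source"].iloc[0]) if "source" in df.columns and len(df) else "diary"
    intervals = [
        (pd.Timestamp(a), pd.Timestamp(b))
        for a, b in zip(pd.to_datetime(df["start"], utc=True, format="ISO8601"),
                        pd.to_datetime(df["end"], utc=True, format="ISO8601"))
    ]
    return NonwearIntervals(intervals, source=source)


def write_nonwear_csv(nonwear: NonwearIntervals, path) -> None:
    pd.DataFrame(
        {
            "start": [a.strftime("%Y-%m-%dT%H:%M:%S") for a, _ in nonwear.intervals],
            "end": [b.strftime("%Y-%m-%dT%H:%M:%S") for _, b in nonwear.intervals],
            "source": nonwear.source,
        }
    ).to_csv(path, index=False)


def read_labels(path, kind: str = "lying_label") -> EpochSeries:
    df = pd.read_csv(path)
    times = pd.to_datetime(df["time"], utc=True, format="ISO8601")
    if len(df) < 2:
        epoch = 1.0
    else:
        epoch = float((times.iloc[1] - times.iloc[0]).total_seconds())
    return EpochSeries(df["label"].to_numpy(), times.iloc[0], epoch, kind)
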