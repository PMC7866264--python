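"""Single-sensor lying detection on sedentary bouts.

Algorithm A is the thigh-rotation criterion: a sedentary bout containing any
epoch whose rotation about the thigh's longitudinal axis exceeds the
threshold (default 65 deg, relative to the bout's initial orientation) is
classified as a lying bout; every other sedentary bout is sitting.

Algorithm B refines A with a decision tree evaluated per sedentary bout:

1. bouts shorter than MinLieT (default 20 min) -> SIT;
2. S = 75th percentile of the per-epoch SDVM in the bout;
   if S > SDVM_1 (default 0.01 g) -> SIT   (too much thigh movement for bed);
3. if S < SDVM_2 (default 0.004 g) -> LIE  (motionless: supported by a bed,
   no rotation required);
4. otherwise LIE iff the bout contains a rotation crossing sustained for at
   least 5 s; momentary crossings are ignored.

Bouts are labelled atomically: a sedentary bout is entirely LIE or SIT.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .features import FeatureSet, rebase_rotation
from .sedentary import Bout, summarize_bout
from .signal_io import EpochSeries


@dataclass
class LyingParams:
    """Thresholds of the lying decision tree (defaults are the validated
    operating point)."""

    rot_threshold: float = 65.0   # deg
    min_cross: float = 5.0        # s, Algorithm B only
    sdvm1: float = 0.01           # g, upper bout-movement limit
    sdvm2: float = 0.004          # g, stillness bypass
    min_lie: float = 20.0         # minutes
    sdvm_stat: str = "p75"
    rot_ref_s: float = 10.0       # bout-start reference window for rotation

    def __post_init__(self):
        # sdvm2 = 0 disables the stillness bypass (S < 0 never holds)
        if not 0 <= self.sdvm2 < self.sdvm1:
            raise ValueError("need 0 <= sdvm2 < sdvm1")
        if not 0 < self.rot_threshold < 180:
            raise ValueError("rot_threshold must lie in (0, 180) deg")
        if not self.min_lie >= 0:
            raise ValueError("min_lie must be non-negative")
        if self.sdvm_stat != "p75":
            raise ValueError("only the 75th-percentile bout statistic is supported")


def detect_rotations(rot, threshold: float = 65.0, min_duration: float = 0.0,
                     epoch_length: float = 1.0) -> list[tuple]:
    """Maximal epoch-index intervals with |rotation| above threshold.

    Intervals shorter than ``min_duration`` seconds are discarded;
    ``min_duration = 0`` keeps every crossing, reproducing the plain
    rotation criterion.
    """
    values = rot.values if isinstance(rot, EpochSeries) else np.asarray(rot, float)
    if isinstance(rot, EpochSeries):
        epoch_length = rot.epoch_length
    with np.errstate(invalid="ignore"):
        above = np.abs(values) > threshold
    above &= np.isfinite(values)
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return [(int(s), int(e)) for s, e in zip(starts, ends)
            if (e - s) * epoch_length >= min_duration]


def _bout_rotation(features: FeatureSet, bout: Bout, ref_s: float) -> np.ndarray:
    sl = bout.epoch_slice(features.roll)
    ref_epochs = int(round(ref_s / features.epoch_length))
    return rebase_rotation(features.roll.values[sl], ref_epochs)


def _relabel(bout: Bout, label: str, features: FeatureSet, ref_s: float) -> Bout:
    summary = summarize_bout(bout, features, int(round(ref_s / features.epoch_length)))
    return replace(bout, label=label, features=summary)


def algorithm_a(sed_bouts: list[Bout], features: FeatureSet,
                params: LyingParams | None = None) -> list[Bout]:
    """Rotation-only lying detection: any crossing marks the bout LIE."""
    params = params or LyingParams()
    out = []
    for b in sed_bouts:
        if b.label != "SED":
            continue
        rot = _bout_rotation(features, b, params.rot_ref_s)
        events = detect_rotations(rot, params.rot_threshold, 0.0,
                                  features.epoch_length)
        out.append(_relabel(b, "LIE" if events else "SIT", features, params.rot_ref_s))
    return out


def algorithm_b(sed_bouts: list[Bout], features: FeatureSet,
                params: LyingParams | None = None) -> list[Bout]:
    """Refined decision tree (duration, SDVM limits, sustained rotation)."""
    params = params or LyingParams()
    out = []
    for b in sed_bouts:
        if b.label != "SED":
            continue
        if b.duration_s < params.min_lie * 60.0:
            out.append(_relabel(b, "SIT", features, params.rot_ref_s))
            continue
        sl = b.epoch_slice(features.sdvm)
        sd = features.sdvm.values[sl]
        s = np.nanpercentile(sd, 75) if np.isfinite(sd).any() else np.nan
        if not np.isfinite(s) or s > params.sdvm1:
            out.append(_relabel(b, "SIT", features, params.rot_ref_s))
            continue
        if s < params.sdvm2:
            out.append(_relabel(b, "LIE", features, params.rot_ref_s))
            continue
        rot = _bout_rotation(features, b, params.rot_ref_s)
        events = detect_rotations(rot, params.rot_threshold, params.min_cross,
                                  features.epoch_length)
        out.append(_relabel(b, "LIE" if events else "SIT", features, params.rot_ref_s))
    return out


def bouts_to_series(bouts: list[Bout], classes: EpochSeries) -> EpochSeries:
    """Per-second lying labels from labelled bouts plus the activity series.

    SED epochs take the label of their bout; UPRIGHT -> OTHER; NONWEAR and
    MISSING pass through, so agreement statistics can exclude them.
    """
    out = np.full(len(classes), "OTHER", dtype="<U8")
    cls = np.asarray(classes.values, dtype="<U8")
    out[cls == "NONWEAR"] = "NONWEAR"
    out[cls == "MISSING"] = "MISSING"
    for b in bouts:
        if b.label in ("LIE", "SIT"):
            out[b.epoch_slice(classes)] = b.label
    return EpochSeries(out, classes.start_time, classes.epoch_length, "lying_label")


def lying_summary(bouts: list[Bout], valid_days: list | None = None) -> pd.DataFrame:
    """Total LIE minutes per calendar day (0.1 min precision).

    Bouts spanning midnight are split between days.  When ``valid_days`` is
    given only those days are reported (with explicit zeros); otherwise all
    days touched by any bout appear.
    """
    seconds: dict[datetime.date, float] = {}
    for b in bouts:
        if b.label != "LIE":
            continue
        t = b.start
        while t < b.end:
            day_end = (t.normalize() + pd.Timedelta(days=1))
            chunk_end = min(day_end, b.end)
            seconds[t.date()] = seconds.get(t.date(), 0.0) + (chunk_end - t).total_seconds()
            t = chunk_end
    if valid_days is not None:
        days = sorted(valid_days)
    else:
        days = sorted(seconds)
    rows = [{"date": d, "lying_min": round(seconds.get(d, 0.0) / 60.0, 1)} for d in days]
    return pd.DataFrame(rows, columns=["date", "lying_min"])


def series_summary(series: EpochSeries, valid_days: list | None = None) -> pd.DataFrame:
    """Per-day LIE minutes from a per-second label series."""
    lab = np.asarray(series.values, dtype="<U8")
    times = series.times()
    df = pd.DataFrame({"date": times.date, "lie": (lab == "LIE").astype(float)})
    per_day = df.groupby("date")["lie"].sum() * series.epoch_length / 60.0
    if valid_days is not None:
        per_day = per_day.reindex(sorted(valid_days), fill_value=0.0)
    return per_day.round(1).rename("lying_min").reset_index()
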