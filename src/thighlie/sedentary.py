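"""Per-second activity classification and sedentary-bout extraction.

Only the split the lying algorithms need is made: SED (sitting-or-lying:
thigh off-vertical and little movement), UPRIGHT (everything else while
worn) and NONWEAR.  Short interruptions of a sedentary run are absorbed and
very short bouts are merged into their longer neighbour, so that a posture
transition does not fragment a bout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureSet, rebase_rotation
from .signal_io import EpochSeries, NonwearIntervals


@dataclass
class Bout:
    """Contiguous interval with one activity/posture label."""

    start: pd.Timestamp
    end: pd.Timestamp
    label: str
    features: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError("bout end must be after start")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()

    def epoch_slice(self, grid: EpochSeries) -> slice:
        i0 = max(grid.index_at(self.start), 0)
        i1 = min(grid.index_at(self.end - pd.Timedelta(seconds=1e-6)) + 1, len(grid))
        return slice(i0, i1)


def classify_activity(features: FeatureSet, nonwear: NonwearIntervals | None = None,
                      inc_threshold: float = 45.0,
                      sdvm_threshold: float = 0.1) -> EpochSeries:
    """SED / UPRIGHT / NONWEAR / MISSING per second.

    SED requires thigh inclination above ``inc_threshold`` (thigh
    off-vertical) and SDVM below ``sdvm_threshold``; non-wear intervals take
    precedence and epochs with unusable features are MISSING.
    """
    inc = features.inc.values
    sd = features.sdvm.values
    out = np.full(len(features), "UPRIGHT", dtype="<U8")
    with np.errstate(invalid="ignore"):
        out[(inc > inc_threshold) & (sd < sdvm_threshold)] = "SED"
    out[~(np.isfinite(inc) & np.isfinite(sd))] = "MISSING"
    if nonwear is not None:
        mask = nonwear.mask_on_grid(features.start_time, len(features),
                                    features.epoch_length)
        out[mask] = "NONWEAR"
    return EpochSeries(out, features.start_time, features.epoch_length,
                       "activity_class")


def _runs(labels: np.ndarray) -> list[list]:
    """Run-length encoding as mutable [label, start, length] triples."""
    edges = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [len(labels)]])
    return [[labels[s], int(s), int(e - s)] for s, e in zip(starts, ends)]


def extract_bouts(classes: EpochSeries, min_bout: float = 5.0,
                  bridge_gap: float = 10.0) -> list[Bout]:
    """Turn a label series into time-ordered, non-overlapping bouts.

    Interruptions of a SED run by at most ``bridge_gap`` seconds of any other
    label are absorbed into the sedentary bout; afterwards bouts shorter
    than ``min_bout`` seconds are merged into their longer neighbour.  Total
    duration is conserved and the operation is idempotent.
    """
    labels = np.asarray(classes.values, dtype="<U8")
    if len(labels) == 0:
        return []
    epoch = classes.epoch_length
    bridge_n = int(np.floor(bridge_gap / epoch + 1e-9))
    min_n = int(np.ceil(min_bout / epoch - 1e-9))

    # bridge and merge alternately until nothing changes, so the result is a
    # fixpoint and re-running on its own output is a no-op
    runs = _runs(labels)
    while True:
        before = [tuple(r) for r in runs]
        runs = _bridge_gaps(runs, bridge_n)
        runs = _merge_short(runs, min_n)
        if [tuple(r) for r in runs] == before:
            break

    bouts = []
    for lab, s, n in runs:
        t0 = classes.start_time + pd.Timedelta(seconds=s * epoch)
        t1 = classes.start_time + pd.Timedelta(seconds=(s + n) * epoch)
        bouts.append(Bout(t0, t1, str(lab)))
    return bouts


def _bridge_gaps(runs: list[list], bridge_n: int) -> list[list]:
    """Relabel maximal non-SED gaps of total length <= bridge_n that are
    flanked by SED on both sides."""
    i = 0
    while i < len(runs):
        if runs[i][0] == "SED":
            i += 1
            continue
        j = i
        while j < len(runs) and runs[j][0] != "SED":
            j += 1
        total = sum(r[2] for r in runs[i:j])
        if (0 < i and j < len(runs) and total <= bridge_n):
            for r in runs[i:j]:
                r[0] = "SED"
        i = j
    return _merge_adjacent(runs)


def _merge_short(runs: list[list], min_n: int) -> list[list]:
    """Merge runs shorter than min_n into their longer neighbour."""
    while len(runs) > 1:
        lengths = [r[2] for r in runs]
        i = int(np.argmin(lengths))
        if lengths[i] >= min_n:
            break
        if i == 0:
            tgt = 1
        elif i == len(runs) - 1:
            tgt = i - 1
        else:
            tgt = i - 1 if runs[i - 1][2] >= runs[i + 1][2] else i + 1
        runs[i][0] = runs[tgt][0]
        runs = _merge_adjacent(runs)
    return runs


def _merge_adjacent(runs: list[list]) -> list[list]:
    out: list[list] = []
    for r in runs:
        if out and out[-1][0] == r[0]:
            out[-1][2] += r[2]
        else:
            out.append(list(r))
    return out


def summarize_bout(bout: Bout, features: FeatureSet,
                   rot_ref_epochs: int = 10) -> dict:
    """Duration, 75th-percentile SDVM and maximum |rotation| of one bout."""
    sl = bout.epoch_slice(features.sdvm)
    sd = features.sdvm.values[sl]
    rot = rebase_rotation(features.roll.values[sl], rot_ref_epochs)
    return {
        "duration_s": bout.duration_s,
        "sdvm_p75": float(np.nanpercentile(sd, 75)) if np.isfinite(sd).any() else np.nan,
        "rot_max": float(np.nanmax(np.abs(rot))) if np.isfinite(rot).any() else np.nan,
    }


def bouts_to_frame(bouts: list[Bout]) -> pd.DataFrame:
    rows = []
    for b in bouts:
        rows.append(
            {
                "start": b.start.strftime("%Y-%m-%dT%H:%M:%S"),
                "end": b.end.strftime("%Y-%m-%dT%H:%M:%S"),
                "label": b.label,
                "duration_s": b.duration_s,
                "sdvm_p75": b.features.get("sdvm_p75", np.nan),
                "rot_max": b.features.get("rot_max", np.nan),
            }
        )
    return pd.DataFrame(rows, columns=["start", "end", "label", "duration_s",
                                       "sdvm_p75", "rot_max"])
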