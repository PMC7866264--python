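"""Agreement statistics between a lying classifier and the reference.

Per-second confusion counts with sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP) and accuracy = (TP+TN)/(TP+TN+FP+FN); per-day and per-participant
lying-time differences; and Bland-Altman 95% limits of agreement,
mean difference +/- 1.96 x SD of the differences (SD with the n-1
denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .signal_io import EpochSeries

_EXCLUDED = ("NONWEAR", "MISSING")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def confusion(pred: EpochSeries, ref: EpochSeries,
              positive: str = "LIE") -> ConfusionCounts:
    """Per-epoch confusion counts; epochs where either side is NONWEAR or
    MISSING are excluded.  The two series must share one grid."""
    if not pred.same_grid(ref):
        raise AlignmentError("prediction and reference grids differ")
    p = np.asarray(pred.values, dtype="<U8")
    r = np.asarray(ref.values, dtype="<U8")
    keep = ~(np.isin(p, _EXCLUDED) | np.isin(r, _EXCLUDED))
    pl = p[keep] == positive
    rl = r[keep] == positive
    return ConfusionCounts(
        tp=int(np.sum(pl & rl)),
        fp=int(np.sum(pl & ~rl)),
        tn=int(np.sum(~pl & ~rl)),
        fn=int(np.sum(~pl & rl)),
    )


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy); NaN where undefined."""
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else float("nan")
    acc = (c.tp + c.tn) / c.total if c.total > 0 else float("nan")
    return sens, spec, acc


def daily_differences(pred_minutes: pd.DataFrame,
                      ref_minutes: pd.DataFrame) -> pd.DataFrame:
    """Per (subject, date) difference pred - ref in minutes.

    Both tables need columns subject, date, lying_min.  Days present on one
    side only are excluded with a warning.
    """
    merged = pred_minutes.merge(ref_minutes, on=["subject", "date"],
                                suffixes=("_pred", "_ref"), how="outer",
                                indicator=True)
    dropped = merged["_merge"] != "both"
    if dropped.any():
        warnings.warn(f"excluded {int(dropped.sum())} day(s) present on one side only")
    keep = merged.loc[~dropped].copy()
    keep["diff_min"] = keep["lying_min_pred"] - keep["lying_min_ref"]
    return keep[["subject", "date", "diff_min"]].reset_index(drop=True)


def participant_averages(daily: pd.DataFrame) -> pd.DataFrame:
    """Mean daily difference per subject."""
    return (daily.groupby("subject")["diff_min"].mean()
            .rename("mean_diff_min").reset_index())


@dataclass
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mean_diff_min": self.mean_diff,
            "sd_diff_min": self.sd_diff,
            "loa_low_min": self.loa_low,
            "loa_high_min": self.loa_high,
            "n": self.n,
        }


def bland_altman(diffs) -> BlandAltman:
    """Mean, SD (n-1) and 95% limits of agreement of the differences."""
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 2:
        raise ValueError("Bland-Altman needs at least 2 differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd, int(d.size))


def bland_altman_plot(pred_minutes, ref_minutes, ax=None, label: str = ""):
    """Classic agreement plot: mean of the two methods on x, difference on y,
    with the bias and the 95% limits as horizontal lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pred = np.asarray(pred_minutes, float)
    ref = np.asarray(ref_minutes, float)
    ba = bland_altman(pred - ref)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((pred + ref) / 2.0, pred - ref, s=12, alpha=0.7)
    for y, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of methods (min/day)")
    ax.set_ylabel("difference (min/day)")
    if label:
        ax.set_title(label)
    return ax


@dataclass
class AgreementReport:
    """Bundle of per-second metrics and lying-time agreement for one
    algorithm against the reference."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    daily: pd.DataFrame = field(repr=False, default=None)
    day_level: BlandAltman | None = None
    participant_level: BlandAltman | None = None
    per_participant_metrics: pd.DataFrame | None = field(repr=False, default=None)

    def to_dict(self) -> dict:
        out = {
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                       "tn": self.counts.tn, "fn": self.counts.fn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }
        if self.day_level is not None:
            out["day_level"] = self.day_level.to_dict()
        if self.participant_level is not None:
            out["participant_level"] = self.participant_level.to_dict()
        if self.per_participant_metrics is not None:
            out["per_participant"] = {
                "sensitivity": _stats(self.per_participant_metrics["sensitivity"]),
                "specificity": _stats(self.per_participant_metrics["specificity"]),
                "accuracy": _stats(self.per_participant_metrics["accuracy"]),
            }
        return out


def _stats(series) -> dict:
    x = np.asarray(series, float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return {"mean": float("nan"), "sd": float("nan"),
                "min": float("nan"), "max": float("nan")}
    return {"mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
            "min": float(x.min()), "max": float(x.max())}


def build_report(counts_by_subject: dict, daily: pd.DataFrame) -> AgreementReport:
    """Assemble the full agreement report from per-subject confusion counts
    and the per-day difference table."""
    total = ConfusionCounts()
    rows = []
    for subj, c in counts_by_subject.items():
        total = total + c
        sens, spec, acc = metrics(c)
        rows.append({"subject": subj, "sensitivity": sens,
                     "specificity": spec, "accuracy": acc})
    sens, spec, acc = metrics(total)
    day_ba = bland_altman(daily["diff_min"]) if len(daily) >= 2 else None
    part = participant_averages(daily)
    part_ba = bland_altman(part["mean_diff_min"]) if len(part) >= 2 else None
    return AgreementReport(
        counts=total, sensitivity=sens, specificity=spec, accuracy=acc,
        daily=daily, day_level=day_ba, participant_level=part_ba,
        per_participant_metrics=pd.DataFrame(rows),
    )
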