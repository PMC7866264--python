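"""End-to-end processing of a thigh + back day and cohort-level validation.

Per day: synchronise the two clocks, map the back recording onto the thigh
timeline, correct orientations (standing reference, then walking-based
daily thigh correction), detect non-wear, classify sedentary time, label
lying by the dual-sensor reference and by Algorithms A and B, and summarise
lying minutes.  The cohort runner aggregates per-second agreement and
Bland-Altman lying-time statistics across subjects and valid days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import RunConfig
from .errors import ThighlieError
from .evaluation import (
    AgreementReport,
    build_report,
    confusion,
    daily_differences,
)
from .features import FeatureSet, compute_features
from .lying import algorithm_a, algorithm_b, bouts_to_series, series_summary
from .preprocess import (
    ClockMap,
    align_recording,
    daily_thigh_correction,
    detect_nonwear,
    standing_reference_correction,
    synchronize,
    valid_days,
)
from .reference_method import reference_labels
from .sedentary import classify_activity, extract_bouts
from .signal_io import EpochSeries, NonwearIntervals
from .synthetic import SyntheticDay, generate_cohort


@dataclass
class PreparedDay:
    """Everything the detectors and the evaluation need for one day."""

    subject: str
    date: pd.Timestamp
    clockmap: ClockMap
    features_thigh: FeatureSet
    features_back: FeatureSet
    classes: EpochSeries
    sed_bouts: list
    ref_labels: EpochSeries
    valid_dates: list
    nonwear: NonwearIntervals
    flags: list = field(default_factory=list)


def prepare_day(day: SyntheticDay, cfg: RunConfig | None = None) -> PreparedDay:
    """Synchronise, correct, featurise and reference-label one day."""
    cfg = cfg or RunConfig()
    flags = []

    cmap = synchronize(day.thigh, day.back,
                       chunk_length=cfg["sync"]["chunk_s"],
                       max_lag=cfg["sync"]["max_lag_s"])
    back = align_recording(day.back, day.thigh, cmap)
    thigh = day.thigh

    if day.standing_interval is not None:
        thigh = standing_reference_correction(thigh, day.standing_interval).apply(thigh)
        back = standing_reference_correction(back, day.standing_interval).apply(back)
    walk_corr = daily_thigh_correction(thigh)
    if walk_corr.flag:
        flags.append(walk_corr.flag)
    else:
        thigh = walk_corr.apply(thigh)

    nw = detect_nonwear(thigh, cfg["nonwear"]["min_min"], cfg["nonwear"]["sd_g"])
    nw_back = detect_nonwear(back, cfg["nonwear"]["min_min"], cfg["nonwear"]["sd_g"])
    nw = nw.union(day.diary_nonwear)
    nw_back = nw_back.union(day.diary_nonwear)

    ft = compute_features(thigh, cfg["features"]["lp_hz"], cfg["features"]["window_s"])
    fb = compute_features(back, cfg["features"]["lp_hz"], cfg["features"]["window_s"])

    classes = classify_activity(ft, nw, cfg["sed"]["inc_deg"], cfg["sed"]["sdvm_g"])
    bouts = extract_bouts(classes, cfg["sed"]["min_bout_s"], cfg["sed"]["bridge_s"])
    sed = [b for b in bouts if b.label == "SED"]
    ref = reference_labels(sed, ft, fb, cfg["reference"]["inc_back_deg"])
    vdays = valid_days(thigh, back, nw, nw_back, cfg["validday"]["min_wear_h"])

    return PreparedDay(day.subject, day.date, cmap, ft, fb, classes, sed, ref,
                       vdays, nw, flags)


@dataclass
class DayResult:
    prepared: PreparedDay
    pred_a: EpochSeries
    pred_b: EpochSeries
    bouts_a: list
    bouts_b: list


def detect_day(prep: PreparedDay, cfg: RunConfig | None = None) -> DayResult:
    """Run both lying algorithms on a prepared day."""
    cfg = cfg or RunConfig()
    params = cfg.lying_params()
    ba = algorithm_a(prep.sed_bouts, prep.features_thigh, params)
    bb = algorithm_b(prep.sed_bouts, prep.features_thigh, params)
    return DayResult(
        prepared=prep,
        pred_a=bouts_to_series(ba, prep.classes),
        pred_b=bouts_to_series(bb, prep.classes),
        bouts_a=ba,
        bouts_b=bb,
    )


def process_day(day: SyntheticDay, cfg: RunConfig | None = None) -> DayResult:
    cfg = cfg or RunConfig()
    return detect_day(prepare_day(day, cfg), cfg)


def _daily_minutes(series: EpochSeries, subject: str, dates: list) -> pd.DataFrame:
    df = series_summary(series, dates)
    df.insert(0, "subject", subject)
    return df


def run_validate(cfg: RunConfig | None = None, days: list | None = None,
                 n_subjects: int = 5, days_per_subject: int = 7,
                 seed: int = 42) -> dict:
    """Full validation: simulate (unless days are given), detect with both
    algorithms, compare with the reference, and aggregate.

    Returns a dict with an :class:`AgreementReport` per algorithm, the
    per-day lying-minute table and the resolved configuration.
    """
    cfg = cfg or RunConfig()
    if days is None:
        days = generate_cohort(n_subjects, days_per_subject, master_seed=seed,
                               sample_rate=cfg["sample_rate_hz"])

    counts = {"A": {}, "B": {}}
    minute_rows = {"A": [], "B": [], "ref": []}
    failures = []
    for day in days:
        try:
            res = process_day(day, cfg)
        except ThighlieError as exc:
            failures.append({"subject": day.subject, "date": str(day.date),
                             "stage": type(exc).__name__, "error": str(exc)})
            continue
        prep = res.prepared
        if not prep.valid_dates:
            continue
        for algo, pred in (("A", res.pred_a), ("B", res.pred_b)):
            c = confusion(pred, prep.ref_labels)
            counts[algo][prep.subject] = counts[algo].get(prep.subject, None) + c \
                if prep.subject in counts[algo] else c
            minute_rows[algo].append(_daily_minutes(pred, prep.subject, prep.valid_dates))
        minute_rows["ref"].append(
            _daily_minutes(prep.ref_labels, prep.subject, prep.valid_dates))

    ref_tbl = pd.concat(minute_rows["ref"], ignore_index=True) if minute_rows["ref"] \
        else pd.DataFrame(columns=["subject", "date", "lying_min"])
    reports: dict[str, AgreementReport] = {}
    for algo in ("A", "B"):
        tbl = pd.concat(minute_rows[algo], ignore_index=True) if minute_rows[algo] \
            else pd.DataFrame(columns=["subject", "date", "lying_min"])
        daily = daily_differences(tbl, ref_tbl)
        reports[algo] = build_report(counts[algo], daily)
        reports[algo].daily = daily

    return {
        "reports": reports,
        "reference_minutes": ref_tbl,
        "config": cfg.resolved(),
        "n_days_processed": len(days) - len(failures),
        "failures": failures,
    }


def report_to_json(result: dict) -> dict:
    """JSON-serialisable view of a run_validate result."""
    out = {
        "config": result["config"],
        "n_days_processed": result["n_days_processed"],
        "failures": result["failures"],
        "algorithms": {k: v.to_dict() for k, v in result["reports"].items()},
    }
    return out
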