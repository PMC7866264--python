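"""Shared fixtures: small constructed recordings and one session-scoped
synthetic validation cohort that heavier tests reuse."""

from __future__ import annotations

import time
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from thighlie.config import RunConfig
from thighlie.lying import series_summary
from thighlie.pipeline import detect_day, prepare_day
from thighlie.signal_io import TriaxialRecording
from thighlie.synthetic import generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

T0 = pd.Timestamp("2024-01-01", tz="UTC")


def static_recording(direction, duration_s=60.0, fs=25.0, placement="thigh",
                     start=T0, noise_sd=0.0, rng=None):
    """Motionless recording reading `direction` (a gravity-frame vector)."""
    n = int(duration_s * fs)
    d = np.asarray(direction, float)
    samples = np.tile(d, (n, 1))
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        samples = samples + rng.normal(0, noise_sd, samples.shape)
    return TriaxialRecording(samples, fs, start, placement)


@pytest.fixture
def standing_rec():
    # upright: static reading points along gravity, i.e. along -U
    return static_recording([-1.0, 0.0, 0.0])


@pytest.fixture(scope="session")
def cohort():
    """Default validation cohort (5 subjects x 7 days), fully processed.

    Raw recordings are released after processing; only per-second series,
    bout lists and per-day lying-minute tables are retained.
    """
    cfg = RunConfig()
    t_gen = t_prep = t_detect = 0.0
    days_out = []
    t0 = time.monotonic()
    days = generate_cohort(5, 7, master_seed=42)
    t_gen = time.monotonic() - t0
    for day in days:
        t0 = time.monotonic()
        prep = prepare_day(day, cfg)
        t_prep += time.monotonic() - t0
        t0 = time.monotonic()
        res = detect_day(prep, cfg)
        t_detect += time.monotonic() - t0
        days_out.append(
            SimpleNamespace(
                subject=day.subject,
                date=day.date,
                truth_lying=day.truth_lying,
                truth_activity=day.truth_activity,
                injected_offset=day.clock_offset,
                injected_drift=day.drift,
                clockmap=prep.clockmap,
                ref_labels=prep.ref_labels,
                valid_dates=prep.valid_dates,
                pred_a=res.pred_a,
                pred_b=res.pred_b,
                bouts_a=res.bouts_a,
                bouts_b=res.bouts_b,
                sed_bouts=prep.sed_bouts,
                minutes_a=series_summary(res.pred_a, prep.valid_dates),
                minutes_b=series_summary(res.pred_b, prep.valid_dates),
                minutes_ref=series_summary(prep.ref_labels, prep.valid_dates),
            )
        )
        # drop the raw samples (tens of MB per day) before the next one
        day.thigh = day.back = None
    return SimpleNamespace(days=days_out, cfg=cfg, t_generate=t_gen,
                           t_prepare=t_prep, t_detect=t_detect)
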