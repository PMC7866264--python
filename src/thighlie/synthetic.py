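"""Synthetic free-living days for a thigh + back sensor pair.

A day is a schedule of posture states.  Each state fixes the gravity
direction in both sensor frames — parametrised by the segment inclination
(angle of the longitudinal axis to the vertical) and a roll azimuth about
the longitudinal axis — plus a state-specific movement noise level in g.
Lying states with a rollover rate toggle the roll between the base
orientation and a side-lying excursion through smooth 5–15 s ramps; the
first excursion of a block is placed deterministically so that every finite
block exhibits the state's defining behaviour.  Walking adds a ~2 Hz
vertical oscillation of 0.3 g with slowly wandering cadence.

Movement noise is band-limited below the 5 Hz analysis filter, so its
per-window SD maps directly onto the SDVM thresholds under test; half of
the noise variance is shared between the two sensors (trunk and thigh move
together), which is what makes free-living cross-correlation
synchronisation possible.  The back recording is stamped on its own clock,
offset and drifting relative to the thigh's as requested.

Ground-truth labels are per second on the thigh timeline and are therefore
invariant to the injected clock errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt

from ._utils import rotation_about
from .signal_io import EpochSeries, NonwearIntervals, TriaxialRecording, _as_utc

NOISE_SHAPING_HZ = 3.5  # movement-noise bandwidth; below the 5 Hz LP filter


@dataclass(frozen=True)
class PostureState:
    """Orientation and movement parameters of one posture state.

    Angles are degrees.  ``*_inc`` is the segment inclination to the
    vertical, ``*_phi`` the roll azimuth (0 = sagittal axis W facing up for
    a horizontal segment).  ``truth`` is the per-second ground-truth lying
    label the state carries.
    """

    name: str
    thigh_inc: float
    thigh_phi: float
    back_inc: float
    back_phi: float
    motion_sd: float
    truth: str  # LIE | SIT | OTHER | NONWEAR
    rollover_rate: float = 0.0      # excursions/h about the long axis
    roll_amp: tuple = (60.0, 110.0)  # sampled excursion amplitude, deg
    first_roll_s: float | None = None
    first_roll_amp: float = 75.0
    roll_both: bool = True          # whole-body roll (back follows thigh)
    gait_amp: float = 0.0           # g, vertical oscillation
    gait_hz: float = 2.0


STATES: dict[str, PostureState] = {
    s.name: s
    for s in [
        PostureState("STAND", 2, 0, 5, 0, 0.005, "OTHER"),
        PostureState("WALK", 2, 0, 6, 0, 0.05, "OTHER", gait_amp=0.3),
        PostureState("SIT", 80, 0, 12, 0, 0.007, "SIT"),
        PostureState("SIT_CROSSED", 80, 0, 15, 0, 0.015, "SIT",
                     rollover_rate=4.0, roll_amp=(70.0, 85.0),
                     first_roll_s=60.0, roll_both=False),
        PostureState("SIT_LEAN_FWD", 80, 0, 55, 0, 0.007, "SIT"),
        PostureState("SIT_LEAN_SIDE", 80, 60, 55, 20, 0.007, "SIT"),
        PostureState("LIE_SUPINE_ROT", 88, 0, 88, 180, 0.005, "LIE",
                     rollover_rate=1.5, first_roll_s=1200.0),
        PostureState("LIE_SIDE", 88, 70, 88, 105, 0.003, "LIE"),
        PostureState("LIE_STOMACH", 88, 180, 88, 0, 0.003, "LIE"),
        PostureState("LIE_STILL", 88, 30, 88, 150, 0.002, "LIE"),
        PostureState("NONWEAR", 45, 0, 45, 0, 0.0, "NONWEAR"),
    ]
}


@dataclass(frozen=True)
class ScheduleEntry:
    state: str
    minutes: float

    def __post_init__(self):
        if self.state not in STATES:
            raise ValueError(f"unknown posture state {self.state!r}")
        if not self.minutes > 0:
            raise ValueError("duration must be positive")


@dataclass
class SyntheticDay:
    """One generated day: paired recordings plus second-level ground truth."""

    thigh: TriaxialRecording
    back: TriaxialRecording
    truth_lying: EpochSeries
    truth_activity: EpochSeries
    seed: int
    clock_offset: float = 0.0
    drift: float = 0.0
    standing_interval: tuple | None = None
    diary_nonwear: NonwearIntervals = field(default_factory=lambda: NonwearIntervals([], "diary"))
    subject: str = "S00"
    date: pd.Timestamp | None = None
    mount_tilt_thigh: float = 0.0
    mount_tilt_back: float = 0.0
    schedule: list = field(default_factory=list)


@dataclass
class ScenarioMix:
    """Free-living scenario: the distribution daily schedules are drawn from."""

    night_h: tuple = (6.5, 8.0)
    p_crossed: float = 1.0
    p_still: float = 1.0
    p_side: float = 1.0
    p_stomach: float = 0.2
    nonwear_every: int = 3  # every k-th day gets a 150 min off-body block
    day_minutes: float = 1440.0


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------

def _shaped_noise(rng: np.random.Generator, n: int, ncols: int, fs: float,
                  cutoff: float = NOISE_SHAPING_HZ) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited below `cutoff` Hz."""
    w = rng.standard_normal((n, ncols))
    if n < 60 or cutoff >= fs / 2:
        return w
    sos = butter(4, cutoff, fs=fs, output="sos")
    f = sosfilt(sos, w, axis=0)  # causal: phase is irrelevant for noise
    sd = f.std(axis=0)
    sd[sd == 0] = 1.0
    f /= sd
    return f


def _slow_wander(rng: np.random.Generator, n: int, ncols: int, fs: float) -> np.ndarray:
    """Unit-SD very-low-frequency wander (postural sway, cadence drift).

    Generated on a coarse 1 Hz grid and interpolated, which is exact enough
    for a signal band-limited far below 1 Hz.
    """
    coarse_fs = 1.0
    n_c = max(int(np.ceil(n / fs * coarse_fs)) + 2, 8)
    w = _shaped_noise(rng, n_c, ncols, coarse_fs, cutoff=0.1)
    t_c = np.arange(n_c) / coarse_fs
    t = np.arange(n) / fs
    out = np.empty((n, ncols))
    for k in range(ncols):
        out[:, k] = np.interp(t, t_c, w[:, k])
    return out


def _roll_delta(rng: np.random.Generator, n_seg: int, fs: float,
                st: PostureState) -> np.ndarray:
    """Roll-excursion profile (deg added to the base azimuth) for one block."""
    delta = np.zeros(n_seg)
    if st.rollover_rate <= 0 or n_seg < int(90 * fs):
        return delta
    seg_s = n_seg / fs
    events = []  # (time_s, target_deg, ramp_s)
    t = st.first_roll_s if st.first_roll_s is not None else max(
        60.0, rng.exponential(3600.0 / st.rollover_rate))
    rolled = False
    first = True
    while t < seg_s - 30.0:
        if not rolled:
            amp = st.first_roll_amp if first else float(rng.uniform(*st.roll_amp))
            target = amp * (1.0 if rng.random() < 0.5 else -1.0)
            first = False
        else:
            target = 0.0
        ramp = 8.0 if first else float(rng.uniform(5.0, 15.0))
        events.append((t, target, ramp))
        rolled = not rolled
        t += max(60.0, rng.exponential(3600.0 / st.rollover_rate))
    cur = 0.0
    pos = 0
    for t_ev, target, ramp in events:
        i0 = int(t_ev * fs)
        i1 = min(int((t_ev + ramp) * fs), n_seg)
        delta[pos:i0] = cur
        if i1 > i0:
            delta[i0:i1] = np.linspace(cur, target, i1 - i0)
        cur = target
        pos = i1
    delta[pos:] = cur
    return delta


def _smooth_transitions(arrays: list[np.ndarray], boundaries: list[int],
                        fs: float, transition_s: float = 2.0) -> None:
    half = int(round(transition_s * fs / 2))
    n = arrays[0].shape[0]
    for ib in boundaries:
        lo, hi = max(ib - half, 0), min(ib + half, n - 1)
        if hi - lo < 2:
            continue
        for arr in arrays:
            arr[lo:hi] = np.linspace(arr[lo], arr[hi], hi - lo)


def _direction(inc_deg: np.ndarray, phi_deg: np.ndarray) -> np.ndarray:
    """Upward-vertical unit vector in the segment frame from (inc, phi)."""
    inc = np.deg2rad(inc_deg)
    phi = np.deg2rad(phi_deg)
    s = np.sin(inc)
    return np.column_stack([np.cos(inc), s * np.sin(phi), s * np.cos(phi)])


def _mount_rotation(rng: np.random.Generator, tilt_deg: float) -> np.ndarray:
    if tilt_deg == 0:
        return np.eye(3)
    az = rng.uniform(0, 2 * np.pi)
    axis = np.array([0.0, np.cos(az), np.sin(az)])  # tilt axis in the V-W plane
    return rotation_about(axis, tilt_deg)


def generate_day(schedule: list[ScheduleEntry], sample_rate: float = 25.0,
                 seed: int = 0, clock_offset: float = 0.0, drift: float = 0.0,
                 date="2024-01-01", subject: str = "S00",
                 mount_tilt_thigh: float = 0.0, mount_tilt_back: float = 0.0,
                 noise_share: float = 0.5, jitter_deg: float = 0.7) -> SyntheticDay:
    """Generate one day of paired recordings with ground truth.

    ``clock_offset``/``drift`` displace the back sensor's clock relative to
    the thigh's (a body event at thigh-time t is stamped
    ``t*(1+drift)+clock_offset`` on the back recording).  The same seed
    reproduces the identical day.
    """
    schedule = [e if isinstance(e, ScheduleEntry) else ScheduleEntry(*e) for e in schedule]
    if not schedule:
        raise ValueError("schedule is empty")
    fs = float(sample_rate)
    start = _as_utc(date)
    durations = np.array([e.minutes * 60.0 for e in schedule])
    if durations.sum() > 36 * 3600:
        raise ValueError("schedule exceeds 36 h")
    lengths = np.diff(np.round(np.concatenate([[0.0], np.cumsum(durations)]) * fs)
                      ).astype(int)
    n = int(lengths.sum())
    boundaries = list(np.cumsum(lengths)[:-1])

    rng = np.random.default_rng(seed)
    r_events, r_common, r_thigh, r_back, r_jit, r_misc = rng.spawn(6)

    states = [STATES[e.state] for e in schedule]
    thigh_inc = np.repeat([s.thigh_inc for s in states], lengths).astype(float)
    thigh_phi = np.repeat([s.thigh_phi for s in states], lengths).astype(float)
    back_inc = np.repeat([s.back_inc for s in states], lengths).astype(float)
    back_phi = np.repeat([s.back_phi for s in states], lengths).astype(float)
    sd = np.repeat([s.motion_sd for s in states], lengths).astype(float)
    gait = np.repeat([s.gait_amp for s in states], lengths).astype(float)

    pos = 0
    for st, ln in zip(states, lengths):
        if st.rollover_rate > 0:
            delta = _roll_delta(r_events, ln, fs, st)
            thigh_phi[pos:pos + ln] += delta
            if st.roll_both:
                back_phi[pos:pos + ln] -= delta  # same physical roll, mirrored frame
        pos += ln

    _smooth_transitions([thigh_inc, thigh_phi, back_inc, back_phi, sd, gait],
                        boundaries, fs)

    # slow postural wander on the orientation angles
    jit = _slow_wander(r_jit, n, 5, fs) * jitter_deg
    worn = sd > 0  # keep the off-body block perfectly still
    thigh_inc += jit[:, 0] * worn
    thigh_phi += jit[:, 1] * worn
    back_inc += jit[:, 2] * worn
    back_phi += jit[:, 3] * worn

    # gait oscillation with wandering cadence, shared body-time phase
    t_grid = np.arange(n) / fs
    cadence = 2.0 + 0.15 * jit[:, 4] / max(jitter_deg, 1e-9)
    phase = 2 * np.pi * np.cumsum(cadence) / fs
    osc = gait * np.sin(phase)

    # shared movement rides on the vertical (trunk and thigh bounce
    # together), so both sensors carry an identical vector-magnitude
    # signature of it regardless of their orientations
    w_c, w_i = np.sqrt(noise_share), np.sqrt(1.0 - noise_share)
    common = w_c * sd * _shaped_noise(r_common, n, 1, fs)[:, 0]
    vertical = 1.0 + osc + common

    v_thigh = _direction(thigh_inc, thigh_phi)
    a_thigh = -vertical[:, None] * v_thigh
    a_thigh += (w_i * sd)[:, None] * _shaped_noise(r_thigh, n, 3, fs)
    a_thigh = a_thigh @ _mount_rotation(r_misc, mount_tilt_thigh).T

    # back: deterministic part + shared noise evaluated at body time, then
    # resampled onto the back sensor's own (offset, drifting) clock
    v_back = _direction(back_inc, back_phi)
    a_back_body = -vertical[:, None] * v_back
    t_body = np.clip((t_grid - clock_offset) / (1.0 + drift), 0.0, t_grid[-1])
    a_back = np.empty_like(a_back_body)
    for k in range(3):
        a_back[:, k] = np.interp(t_body, t_grid, a_back_body[:, k])
    sd_b = np.interp(t_body, t_grid, sd)
    a_back += (w_i * sd_b)[:, None] * _shaped_noise(r_back, n, 3, fs)
    a_back = a_back @ _mount_rotation(r_misc, mount_tilt_back).T

    thigh = TriaxialRecording(a_thigh, fs, start, "thigh", f"{subject}-thigh")
    back = TriaxialRecording(a_back, fs, start, "back", f"{subject}-back")

    # per-second ground truth on the thigh timeline
    m = int(n // fs)
    mids = (np.arange(m) + 0.5)
    seg_ends = np.cumsum(lengths) / fs
    seg_idx = np.searchsorted(seg_ends, mids, side="right").clip(max=len(states) - 1)
    truth = np.array([states[i].truth for i in seg_idx], dtype="<U8")
    lying = truth.copy()
    lying[truth == "OTHER"] = "OTHER"
    activity = np.full(m, "UPRIGHT", dtype="<U8")
    activity[(truth == "SIT") | (truth == "LIE")] = "SED"
    activity[truth == "NONWEAR"] = "NONWEAR"

    standing = None
    if schedule[0].state == "STAND" and schedule[0].minutes * 60 >= 20:
        end_s = min(50.0, schedule[0].minutes * 60 - 2.0)
        standing = (start + pd.Timedelta(seconds=5.0),
                    start + pd.Timedelta(seconds=end_s))

    diary = NonwearIntervals(
        [(start + pd.Timedelta(seconds=float(seg_ends[i] - lengths[i] / fs)),
          start + pd.Timedelta(seconds=float(seg_ends[i])))
         for i, st in enumerate(states) if st.name == "NONWEAR"],
        source="diary",
    )

    return SyntheticDay(
        thigh=thigh, back=back,
        truth_lying=EpochSeries(lying, start, 1.0, "lying_label"),
        truth_activity=EpochSeries(activity, start, 1.0, "activity_class"),
        seed=int(seed) if np.isscalar(seed) and not hasattr(seed, "spawn") else -1,
        clock_offset=clock_offset, drift=drift, standing_interval=standing,
        diary_nonwear=diary, subject=subject, date=start,
        mount_tilt_thigh=mount_tilt_thigh, mount_tilt_back=mount_tilt_back,
        schedule=schedule,
    )


# ---------------------------------------------------------------------------
# schedules and cohorts
# ---------------------------------------------------------------------------

def default_day_schedule(rng: np.random.Generator, mix: ScenarioMix | None = None,
                         include_nonwear: bool = False) -> list[ScheduleEntry]:
    """Draw one realistic day: a night lying block, daytime sitting blocks
    separated by standing/walking, plus the algorithm-contrast blocks
    (crossed-leg sitting, motionless lying, side-lying without turning)."""
    mix = mix or ScenarioMix()
    entries: list[ScheduleEntry] = []

    def add(state, minutes):
        if minutes > 0:
            entries.append(ScheduleEntry(state, float(minutes)))

    # standing/walking breaks separate every pair of sedentary blocks, so
    # each block forms its own sedentary bout (people stand up in between)
    add("STAND", 1.0)
    night = rng.uniform(*mix.night_h) * 60.0
    add("LIE_SUPINE_ROT", night)
    add("WALK", 5)
    add("SIT", rng.uniform(70, 110))
    add("STAND", 2)
    add("SIT_LEAN_FWD", 15)
    add("WALK", 3)
    add("SIT", rng.uniform(60, 90))
    if rng.random() < mix.p_crossed:
        add("STAND", 2)
        add("SIT_CROSSED", 30)
    add("WALK", 3)
    if include_nonwear:
        add("NONWEAR", 150)
        add("WALK", 3)
    add("SIT", rng.uniform(45, 80))
    if rng.random() < mix.p_still:
        add("STAND", 2)
        add("LIE_STILL", 30)
    add("STAND", 2)
    add("SIT_LEAN_SIDE", 15)
    add("WALK", 5)
    if rng.random() < mix.p_stomach:
        add("LIE_STOMACH", 20)
        add("STAND", 2)
    add("SIT", rng.uniform(60, 90))
    if rng.random() < mix.p_side:
        add("WALK", 2)
        add("LIE_SIDE", 30)
    add("WALK", 3)
    remaining = mix.day_minutes - sum(e.minutes for e in entries)
    while remaining > 45:
        add("STAND", 2)
        block = float(min(rng.uniform(60, 100), remaining - 22))
        add("SIT", block)
        remaining = mix.day_minutes - sum(e.minutes for e in entries)
    if remaining >= 3:
        add("STAND", 1)
        add("SIT", remaining - 1)
    elif remaining > 0:
        add("STAND", remaining)
    return entries


def generate_cohort(n_subjects: int = 5, days_per_subject: int = 7,
                    master_seed: int = 42, mix: ScenarioMix | None = None,
                    sample_rate: float = 25.0) -> list[SyntheticDay]:
    """Reproducible cohort of synthetic days.

    Per subject: a clock offset of 0.5–30 s, a drift of 0–5e-6 s/s and
    mounting tilts of 0–6 deg are drawn once; each day gets its own schedule
    and noise seed, all derived from ``master_seed``.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    mix = mix or ScenarioMix()
    days: list[SyntheticDay] = []
    for s, child in enumerate(np.random.SeedSequence(master_seed).spawn(n_subjects)):
        rng = np.random.default_rng(child)
        offset = float(rng.uniform(0.5, 30.0))
        drift = float(rng.uniform(0.0, 5e-6))
        tilt_t = float(rng.uniform(0.0, 6.0))
        tilt_b = float(rng.uniform(0.0, 6.0))
        for d in range(days_per_subject):
            schedule = default_day_schedule(
                rng, mix, include_nonwear=(d % mix.nonwear_every == 0))
            day_seed = int(rng.integers(2 ** 31))
            day = generate_day(
                schedule, sample_rate=sample_rate, seed=day_seed,
                clock_offset=offset, drift=drift,
                date=pd.Timestamp("2024-01-01", tz="UTC") + pd.Timedelta(days=d),
                subject=f"S{s:02d}", mount_tilt_thigh=tilt_t, mount_tilt_back=tilt_b,
            )
            days.append(day)
    return days


def write_day(day: SyntheticDay, outdir) -> dict:
    """Write thigh/back/truth CSVs plus a manifest; returns the manifest."""
    import json
    import os

    from .signal_io import write_labels, write_recording

    os.makedirs(outdir, exist_ok=True)
    tag = f"{day.subject}_{day.date.strftime('%Y%m%d')}"
    paths = {
        "thigh": os.path.join(outdir, f"{tag}_thigh.csv"),
        "back": os.path.join(outdir, f"{tag}_back.csv"),
        "truth": os.path.join(outdir, f"{tag}_truth.csv"),
    }
    write_recording(day.thigh, paths["thigh"])
    write_recording(day.back, paths["back"])
    write_labels(day.truth_lying, paths["truth"])
    manifest = {
        "subject": day.subject,
        "date": day.date.isoformat(),
        "seed": day.seed,
        "clock_offset_s": day.clock_offset,
        "drift": day.drift,
        "standing_interval": [str(t) for t in day.standing_interval]
        if day.standing_interval else None,
        "files": paths,
    }
    with open(os.path.join(outdir, f"{tag}_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
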