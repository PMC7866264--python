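# Methods

This note documents the conventions, models and numerical choices behind
`thighlie`: what exactly is computed, which parameters matter and why they
have the defaults they do, what the synthetic generator does and does not
emulate, and the known limitations.

## Sensor frames and the sign convention

Each recording is an (N, 3) array of acceleration in g in the sensor frame
(U, V, W): U longitudinal (cranial when standing, after orientation
correction), V mediolateral, W sagittal — out of the front of the thigh,
out of the back posteriorly.

We use the *gravity* sign convention: a motionless sensor reads a unit
vector pointing **along gravity** (down). Standing upright therefore reads
≈ (−1, 0, 0), and the upward vertical in the sensor frame is the negative
of the (low-pass filtered, window-averaged) acceleration. All angle
definitions follow from this:

* **Inclination** INC = ∠(+U, upward vertical); 0° standing, 90° when the
  segment is horizontal. Undefined (missing) when the mean vector magnitude
  in an epoch is below 0.5 g.
* **Sagittal angle** θ = asin(upward vertical · W), in degrees: the signed
  elevation of the sagittal axis above the horizontal plane. Supine lying
  gives θ_back = −90° (the back's W points down), prone lying +90°; a
  sitting thigh with the knee forward has θ_thigh near +90°.
* **Thigh roll azimuth** φ = atan2(up_V, up_W): rotation of the upward
  vertical in the V–W plane. Missing when the projection of the vertical
  onto V–W is below 0.2 g (thigh near vertical — roll is ill-defined while
  standing). The *rotation angle* reported for a sedentary bout is
  φ(t) minus the circular median of φ over the bout's first 10 s, wrapped
  to [−180°, 180°). The start-of-bout posture is the natural reference and
  the circular median resists transient motion; the reference window is
  configurable (`lying.rot_ref_s`).

If a deployment's devices use the opposite (reaction-force) convention,
negate the samples on ingest.

## Filter chain and epoch grid

Everything downstream lives on a 1 s, left-aligned, half-open epoch grid.
Features come from one shared chain: a zero-phase 4th-order Butterworth
low-pass at 5 Hz (`features.lp_hz`), then per-epoch statistics over a 2 s
window centred on the epoch (`features.window_s`):

* **SDVM** — the SD (population form) of the vector magnitude over the
  window, in g. The 2 s window is a pragmatic choice: long enough for a
  stable SD at 25 Hz (50 samples), short enough to localise movement to the
  second.
* Angles are computed from the windowed mean acceleration vector, so the
  gravity estimate and SDVM share one filter chain.

The default sample rate for generated data is 25 Hz (configurable); any
uniform 25–100 Hz input works, and `resample_uniform` harmonises mixed
rates by linear interpolation.

## Two-sensor preparation

* **Clock synchronisation.** The back sensor's clock is modelled as an
  affine map of the thigh's (offset + drift). Per 10-minute chunk
  (`sync.chunk_s`) the lag of the back vector-magnitude signal is found by
  normalised cross-correlation within ±120 s (`sync.max_lag_s`), with
  3-point parabolic sub-sample refinement; chunks with a peak correlation
  below 0.2 or with flat signal are dropped (more than half dropped →
  low-confidence error, the day is unusable). The (time, lag) pairs are fit
  with a robust linear regression (Tukey bisquare, via statsmodels RLM):
  intercept = offset at the thigh recording's start, slope = drift. Free
  living provides the needed shared signal content — walking bouts and the
  common component of body movement.
* **Orientation corrections.** From a ≥ 5 s standing-still interval (mean
  vector magnitude within 0.9–1.1 g, SD of VM ≤ 0.1 g), the minimal
  rotation taking the mean gravity direction onto −U. Gravity observes only
  tilt: yaw about the vertical is unidentifiable from a static posture and
  is left unchanged — a documented limitation, acceptable because all
  downstream criteria depend on inclination and on *relative* roll. The
  thigh additionally gets a daily walking-based correction: epochs whose
  1–3 Hz band RMS of VM exceeds 0.05 g with inclination < 30° are walking
  candidates; given ≥ 60 s of them, the median walking gravity direction is
  mapped onto −U, else the identity is returned flagged `no-walking`. Full
  gain/offset autocalibration is *not* implemented; inputs are assumed
  calibrated (the generator produces calibrated signals).
* **Non-wear.** Per-minute SD below 0.003 g on all three axes sustained for
  ≥ 120 min, merged with diary intervals. The 0.003 g level sits below the
  movement of a worn sensor in any posture here modelled except motionless
  lying (0.002 g); the 120 min duration is what separates the two — a still
  nap is shorter, a removed sensor stays still longer. This ambiguity is
  real and resolved purely by duration; deployments with long motionless
  sleep and no diary should expect misclassification at this boundary.
* **Valid days.** A calendar day enters the analysis only with strictly
  more than 8 h of wear on *both* sensors.

## Sedentary bouts

Per second: NONWEAR inside a non-wear interval; else SED when thigh
inclination > 45° and SDVM < 0.1 g; else UPRIGHT. This is deliberately the
minimal split the lying detectors need — no walking/running/stair/cycle
taxonomy — with both thresholds configurable (`sed.inc_deg`, `sed.sdvm_g`).

Runs of equal labels become bouts. Interruptions of sedentary time totalling
≤ 10 s (`sed.bridge_s`) flanked by SED are absorbed, then bouts shorter than
5 s are merged into the longer neighbour; the two steps alternate to a
fixpoint, making extraction idempotent and duration-conserving. The bridge
width matters: how aggressively sporadic activity inside a sedentary bout is
filtered changes how much of a day one bout can span, and with it the lying
totals — which is why it is an exposed, logged parameter rather than a
constant.

## The lying detectors

Both label whole sedentary bouts atomically (LIE or SIT).

**Algorithm A**: LIE iff any epoch's |rotation| > 65° (`lying.rot_deg`).

**Algorithm B**, per bout, in order: (i) duration < 20 min
(`lying.min_lie_min`) → SIT; (ii) S = 75th percentile of per-epoch SDVM;
S > 0.01 g (`lying.sdvm1_g`) → SIT; (iii) S < 0.004 g (`lying.sdvm2_g`) →
LIE; (iv) else LIE iff a rotation event lasts ≥ 5 s (`lying.min_cross_s`).

Design choices made here, where the tree's exact topology was open:

* The order duration → SDVM₁ → SDVM₂ → rotation makes SDVM₁ a hard veto
  (crossed-leg sitting cannot be rescued by its rotation) and SDVM₂ a
  rotation bypass (motionless lying needs no rollover), matching each
  criterion's motivation. The order is fixed, not configurable.
* The bout statistic is the 75th percentile of per-epoch SDVM for *both*
  SDVM₁ and SDVM₂; the upper-limit criterion names that percentile, reusing
  it for the stillness bypass is this package's choice.
* MinLieT applies to every LIE classification, including the SDVM₂ branch.
* Rotation events are per-epoch threshold crossings of the re-referenced
  roll series; with `min_cross = 0` every crossing counts, which together
  with `min_lie = 0`, `sdvm1 = ∞`, `sdvm2 = 0` reduces Algorithm B exactly
  to Algorithm A (a tested identity).

## Reference method

Within sedentary bouts: LIE where INC_back > 45° (`reference.inc_back_deg`),
else SIT; OTHER outside; MISSING where back features are unusable. Two
per-epoch reclassifications then run in order:

1. θ_back > 0 **and** θ_thigh > 45° → SIT (forward lean: the trunk pitches
   forward past horizontal while the thigh stays in the sitting attitude);
2. |INC_back − θ_back| < 10 **and** INC_back < 65° **and** θ_back < 65°
   → SIT (sideways-lean geometry).

Both only ever convert LIE → SIT, so lying time is non-increasing through
the chain — a tested invariant. The θ_back < 65° clause is applied literally
on the signed angle (for negative θ_back it is vacuous; the other clauses
bind). Whether the original procedure applied these per epoch or per bout
majority is unknowable from its description; per-epoch is implemented, with
bouts re-segmented afterwards.

## Agreement statistics

Per-second confusion counts exclude epochs that are NONWEAR or MISSING on
either side and are restricted to valid days. Sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), accuracy = (TP+TN)/total; undefined ratios are
NaN, not errors. Daily lying minutes (bouts split at midnight, 0.1 min
precision) give per-day differences and per-participant means;
Bland–Altman limits are mean ± 1.96 × SD with the n−1 SD denominator.
Reports provide both pooled and per-participant (mean/SD/min/max) metrics.

## The synthetic generator

`thighlie.synthetic` emulates free-living days as schedules of posture
states, each state a (thigh, back) gravity orientation plus a movement-noise
level: standing, walking, plain/crossed-leg/forward-lean/side-lean sitting,
supine lying with rollovers, side/prone/motionless lying, and non-wear.
Orientation parameters live in one table (`STATES`) so edge-case suites
(e.g. half-lying recliner postures) can be generated by variation.

Key mechanisms and the reasons behind them:

* **Noise model.** Movement noise is Gaussian, band-limited below 3.5 Hz —
  inside the 5 Hz analysis band — so a state's noise SD maps essentially
  one-to-one onto the SDVM the pipeline measures, which is what the SDVM
  thresholds are tested against. Half of the noise variance is a scalar
  *vertical* component shared by both sensors (trunk and thigh accelerate
  together), giving the cross-correlation synchroniser a broadband shared
  signal; the other half is independent per sensor.
* **State noise levels** (g): motionless lying 0.002 < SDVM₂; side/prone
  lying 0.003 < SDVM₂; supine-with-rollovers 0.005 (between the two
  thresholds — must be caught by rotation); sitting 0.007; crossed-leg
  sitting 0.015 > SDVM₁; walking 0.05 plus a 0.3 g ≈ 2 Hz vertical
  oscillation with wandering cadence. These place every branch of both
  algorithms on the map: the A-vs-B contrast scenarios are guaranteed, not
  incidental.
* **Rollovers.** In rotating lying states the roll toggles between the base
  orientation and a side excursion through smooth 5–15 s ramps at ~1.5
  events/h (a free parameter — nightly rollover frequency is not an
  established constant). The first excursion of each block is placed
  deterministically (20 min into a night, 60 s into a crossed-leg block) at
  75°, so a finite block always exhibits its defining behaviour; later
  events draw amplitudes of 60–110° (70–85° for leg crossing) at random.
* **Transitions** between states are 2 s linear orientation blends; truth
  labels switch at the scheduled boundary, so evaluation against truth
  excludes ±2 s around transitions.
* **Clock errors** offset and drift displace the back recording's stamped
  timeline; ground truth lives on the thigh timeline and is invariant to
  them. Mounting errors are small random tilts (default ≤ 6°, no yaw) the
  corrections must undo.
* **Cohorts.** The default day: a 6.5–8 h night with rollovers, sitting
  blocks separated by standing/walking breaks, one crossed-leg (30 min),
  one motionless-lying (30 min), one side-lying (30 min) block daily, a
  prone block with probability 0.2, and a 150 min non-wear block every
  third day. Short breaks between sedentary blocks mirror real behaviour
  (people stand up between activities) and keep blocks as separate bouts.
  Lying occupies ~35–37 % of worn time, the prevalence typical of adult
  free-living cohorts. All randomness derives from one master seed via
  spawned generator streams (subject → day → noise), so cohorts are exactly
  reproducible.

**What passing tests do and do not show.** The generator's movement is
band-limited Gaussian noise around piecewise-constant gravity — it contains
no gait harmonics beyond a single oscillation, no postural micro-adjustment
bursts, no bed-sharing artefacts, no device gain/offset miscalibration, no
temperature drift, and its posture states are cleanly separated in angle
space. Perfect reference recovery and near-perfect Algorithm-B agreement on
synthetic cohorts therefore validate the *logic and wiring* of the chain
(thresholds, equations, bout handling, synchronisation, statistics), not
field performance on real recordings, where boundary postures ("half
lying") genuinely blur the sitting/lying definition.

## Numerical details

* Windowed statistics use cumulative sums with edge-clipped windows; the
  window SD uses the population (n) denominator, Bland–Altman the sample
  (n−1) denominator.
* Circular medians minimise summed absolute wrapped deviation over the
  sample angles (O(n²), only ever on ≤ 10-epoch windows; ties take the
  first minimiser).
* Rotation matrices are built by Rodrigues' formula; the minimal-rotation
  construction handles the antiparallel case by an arbitrary perpendicular
  axis.
* NaN propagates as the missing marker throughout; comparisons against NaN
  are False, so missing epochs never satisfy a rule.
* Gap handling on ingest: inter-sample intervals beyond 1.5× nominal raise
  a gap error listing the intervals; an explicit flag interpolates instead.
  Recordings are validated to ±16 g and finiteness on construction.

## Limitations

* Yaw is unobservable from gravity; mounting errors are corrected in tilt
  only.
* Non-wear vs motionless lying is separated only by duration (see above).
* Acti4-equivalence is not claimed: the sedentary classifier here is the
  minimal inclination/SDVM split, and lying totals depend on bout
  filtration choices (`sed.bridge_s`).
* The literal θ_back < 65° clause and the per-epoch application of the
  reclassification rules are implementation decisions where the source
  procedure is under-specified.
* Binary device formats (CWA/GT3X) are out of scope; ingest is CSV.
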