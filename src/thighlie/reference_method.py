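"""Dual-sensor reference labelling of lying versus sitting.

Within sedentary time (from the thigh sensor), an epoch is primarily
labelled LIE when the back inclination exceeds 45 deg.  Two per-epoch
reclassification rules then remove sitting postures that mimic lying:

* forward lean / stomach-lying disambiguation:
  IF theta_back > 0 AND theta_thigh > 45 deg THEN -> SIT
* sideways lean:
  IF |INC_back - theta_back| < 10 AND INC_back < 65 deg AND theta_back < 65 deg
  THEN -> SIT

Both rules only ever convert LIE to SIT, so total lying time is
non-increasing through the filter chain.  The theta_back < 65 clause is
applied literally on the signed angle (it is almost always satisfied for
negative theta; the binding clauses are the other two).
"""

from __future__ import annotations

import numpy as np

from .features import FeatureSet
from .sedentary import Bout
from .signal_io import EpochSeries

INC_BACK_LIE_DEG = 45.0


def primary_lying(sed_bouts: list[Bout], inc_back: EpochSeries,
                  inc_threshold: float = INC_BACK_LIE_DEG) -> EpochSeries:
    """LIE/SIT inside sedentary bouts by back inclination, OTHER outside.

    Epochs inside a sedentary bout whose back inclination is missing are
    labelled MISSING.
    """
    inc = inc_back.values
    out = np.full(len(inc_back), "OTHER", dtype="<U8")
    for b in sed_bouts:
        if b.label != "SED":
            continue
        sl = b.epoch_slice(inc_back)
        seg = inc[sl]
        lab = np.where(seg > inc_threshold, "LIE", "SIT").astype("<U8")
        lab[~np.isfinite(seg)] = "MISSING"
        out[sl] = lab
    return EpochSeries(out, inc_back.start_time, inc_back.epoch_length, "lying_label")


def apply_eq1(labels: EpochSeries, theta_back: EpochSeries,
              theta_thigh: EpochSeries) -> EpochSeries:
    """Reclassify forward-lean sitting: LIE -> SIT where theta_back > 0 and
    theta_thigh > 45 deg."""
    lab = np.array(labels.values, dtype="<U8")
    with np.errstate(invalid="ignore"):
        cond = (lab == "LIE") & (theta_back.values > 0.0) & (theta_thigh.values > 45.0)
    lab[cond] = "SIT"
    return labels.with_values(lab)


def apply_eq2(labels: EpochSeries, inc_back: EpochSeries,
              theta_back: EpochSeries) -> EpochSeries:
    """Reclassify sideways-lean sitting: LIE -> SIT where
    |INC_back - theta_back| < 10, INC_back < 65 and theta_back < 65 deg."""
    lab = np.array(labels.values, dtype="<U8")
    inc = inc_back.values
    th = theta_back.values
    with np.errstate(invalid="ignore"):
        cond = (
            (lab == "LIE")
            & (np.abs(inc - th) < 10.0)
            & (inc < 65.0)
            & (th < 65.0)
        )
    lab[cond] = "SIT"
    return labels.with_values(lab)


def reference_labels(sed_bouts: list[Bout], features_thigh: FeatureSet,
                     features_back: FeatureSet,
                     inc_threshold: float = INC_BACK_LIE_DEG) -> EpochSeries:
    """Full reference chain: primary rule, then Eq.-style reclassifications.

    The back features must already live on the thigh timeline (after clock
    alignment); the result shares the thigh epoch grid.
    """
    if not features_thigh.sdvm.same_grid(features_back.sdvm):
        from .errors import AlignmentError

        raise AlignmentError("thigh and back features must share one grid")
    lab = primary_lying(sed_bouts, features_back.inc, inc_threshold)
    lab = apply_eq1(lab, features_back.theta, features_thigh.theta)
    lab = apply_eq2(lab, features_back.inc, features_back.theta)
    return lab
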