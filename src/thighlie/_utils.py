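"""Small numeric helpers shared across modules: angle wrapping, minimal
rotations, and centered-window statistics on the 1 s epoch grid."""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_deg",
    "circular_median_deg",
    "unit",
    "rotation_between",
    "rotation_about",
    "epoch_window_mean",
    "epoch_window_sd",
    "n_epochs",
]


def wrap_deg(a):
    """Wrap angles (degrees) into [-180, 180)."""
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


def circular_median_deg(a) -> float:
    """Circular median of angles in degrees.

    Returns the sample angle minimising the summed absolute wrapped
    deviation; NaNs are ignored, all-NaN input yields NaN.  O(n^2) but only
    ever applied to short reference windows.
    """
    a = np.asarray(a, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        return float("nan")
    costs = np.abs(wrap_deg(a[None, :] - a[:, None])).sum(axis=1)
    return float(a[int(np.argmin(costs))])


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def rotation_about(axis, angle_deg: float) -> np.ndarray:
    """Proper rotation matrix about `axis` by `angle_deg` (Rodrigues)."""
    k = unit(axis)
    th = np.deg2rad(angle_deg)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * kx + (1 - np.cos(th)) * (kx @ kx)


def rotation_between(u, v) -> np.ndarray:
    """Minimal proper rotation R with R @ u ∝ v (u, v need not be unit)."""
    u = unit(u)
    v = unit(v)
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 deg turn: any axis perpendicular to u
        helper = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, helper)
        return rotation_about(axis, 180.0)
    axis = np.cross(u, v)
    angle = np.degrees(np.arctan2(np.linalg.norm(axis), c))
    return rotation_about(axis, angle)


def n_epochs(n_samples: int, sample_rate: float, epoch_s: float = 1.0) -> int:
    return int(np.floor(n_samples / (sample_rate * epoch_s) + 1e-9))


def _window_bounds(n_samples: int, sample_rate: float, epoch_s: float, window_s: float):
    m = n_epochs(n_samples, sample_rate, epoch_s)
    centers = (np.arange(m) + 0.5) * epoch_s * sample_rate
    half = 0.5 * window_s * sample_rate
    lo = np.clip(np.round(centers - half).astype(np.int64), 0, n_samples)
    hi = np.clip(np.round(centers + half).astype(np.int64), 0, n_samples)
    return lo, hi


def epoch_window_mean(x: np.ndarray, sample_rate: float, window_s: float = 2.0,
                      epoch_s: float = 1.0) -> np.ndarray:
    """Per-epoch mean of `x` over a centered window.

    `x` is (N,) or (N, k); one value (row) per epoch, window clipped at the
    recording edges.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = _window_bounds(x.shape[0], sample_rate, epoch_s, window_s)
    csum = np.concatenate([np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)], axis=0)
    count = (hi - lo).astype(float)
    if x.ndim == 1:
        return (csum[hi] - csum[lo]) / count
    return (csum[hi] - csum[lo]) / count[:, None]


def epoch_window_sd(x: np.ndarray, sample_rate: float, window_s: float = 2.0,
                    epoch_s: float = 1.0) -> np.ndarray:
    """Per-epoch population SD of 1-D `x` over a centered window."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("epoch_window_sd expects a 1-D signal")
    lo, hi = _window_bounds(x.shape[0], sample_rate, epoch_s, window_s)
    if np.any(hi - lo < 2):
        raise ValueError("window too short: fewer than 2 samples per epoch window")
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    count = (hi - lo).astype(float)
    mean = (c1[hi] - c1[lo]) / count
    var = (c2[hi] - c2[lo]) / count - mean * mean
    return np.sqrt(np.clip(var, 0.0, None))
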