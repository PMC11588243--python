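"""Movement parameters from raw acceleration, and 30-s window features.

The raw tri-axial signal mixes a slowly varying gravity component (body
orientation) with body motion. A centred 91-s running mean per axis
estimates the *static* (gravity) component — 91 s being the dominant stroke
period of the study species — and the residual is the *dynamic* component:

    static_i  = running_mean_91s(raw_i)          i in {x, y, z}
    dynamic_i = raw_i - static_i
    ODBA      = |Dx| + |Dy| + |Dz|               movement-intensity proxy
    pitch     = atan2(Sx, sqrt(Sy^2 + Sz^2)) * 180/pi     degrees

Window features feed the HMM: per non-overlapping 30-s window, log10 mean
ODBA, log10 variance-in-pitch (sample variance, n-1), and a binary
immersion flag from the 1 Hz analog channel (voltage at or below the 500 V
threshold means "in water"; a window is immersed if a majority of its
seconds are wet).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RawBurst

logger = logging.getLogger(__name__)

__all__ = [
    "MotionSeries",
    "decompose",
    "compute_odba",
    "compute_pitch",
    "summarize_windows",
    "transform_features",
    "features_from_bursts",
]

SMOOTH_WINDOW_S = 91.0
WINDOW_S = 30.0
IMMERSION_THRESHOLD_V = 500.0
LOG_FLOOR = 1e-12


@dataclass
class MotionSeries:
    """Per-sample static/dynamic decomposition with derived ODBA and pitch."""

    burst: RawBurst
    static_x: np.ndarray
    static_y: np.ndarray
    static_z: np.ndarray
    dynamic_x: np.ndarray
    dynamic_y: np.ndarray
    dynamic_z: np.ndarray
    odba: np.ndarray
    pitch: np.ndarray

    def __len__(self) -> int:
        return len(self.odba)


def _running_mean(x: np.ndarray, half: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges.

    Window at i covers [i-half, i+half] clipped to the series; O(n) via a
    cumulative sum.
    """
    n = len(x)
    c = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    lo = np.clip(np.arange(n) - half, 0, None)
    hi = np.clip(np.arange(n) + half + 1, None, n)
    return (c[hi] - c[lo]) / (hi - lo)


def decompose(burst: RawBurst, smooth_window_s: float = SMOOTH_WINDOW_S) -> MotionSeries:
    """Split raw acceleration into static + dynamic and derive ODBA / pitch.

    The smoothing window is rounded to an odd sample count for symmetry
    (911 samples at 10 Hz for the default 91 s). ``static + dynamic``
    reconstructs the raw signal exactly, per axis, per sample.
    """
    if burst.n_samples < 1:
        raise ValueError("cannot decompose an empty burst")
    if smooth_window_s <= 0:
        raise ValueError("smooth_window_s must be positive")
    w = int(round(smooth_window_s * burst.accel_hz))
    if w % 2 == 0:
        w += 1
    half = w // 2
    sx = _running_mean(burst.ax, half)
    sy = _running_mean(burst.ay, half)
    sz = _running_mean(burst.az, half)
    dx, dy, dz = burst.ax - sx, burst.ay - sy, burst.az - sz
    motion = MotionSeries(
        burst=burst,
        static_x=sx, static_y=sy, static_z=sz,
        dynamic_x=dx, dynamic_y=dy, dynamic_z=dz,
        odba=np.empty(0), pitch=np.empty(0),
    )
    motion.odba = compute_odba(motion)
    motion.pitch = compute_pitch(motion)
    return motion


def compute_odba(motion: MotionSeries) -> np.ndarray:
    """Overall dynamic body acceleration: |Dx| + |Dy| + |Dz| per sample (g)."""
    return np.abs(motion.dynamic_x) + np.abs(motion.dynamic_y) + np.abs(motion.dynamic_z)


def compute_pitch(motion: MotionSeries) -> np.ndarray:
    """Vertical body angle in degrees, in [-90, +90].

    A sample where all three static components are zero (free-fall artefact)
    gets pitch 0 with a logged warning.
    """
    sx, sy, sz = motion.static_x, motion.static_y, motion.static_z
    horiz = np.hypot(sy, sz)
    degenerate = (sx == 0) & (horiz == 0)
    if np.any(degenerate):
        logger.warning(
            "%d sample(s) with zero static vector; pitch set to 0", int(degenerate.sum())
        )
    return np.degrees(np.arctan2(sx, horiz))


def summarize_windows(
    motion: MotionSeries,
    window_s: float = WINDOW_S,
    threshold_v: float = IMMERSION_THRESHOLD_V,
    wet_below: bool = True,
    floor: float = LOG_FLOOR,
) -> pd.DataFrame:
    """Summarise a burst into model-ready 30-s window features.

    Windows are non-overlapping, aligned to the burst start; a trailing
    partial window is discarded. Each row carries the three HMM features
    (``mean_odba_log10``, ``var_pitch_log10``, ``immersed``) plus the full
    summary block (max / mean / IQR / variance of ODBA and pitch) retained
    for export. ``wet_below`` selects the immersion comparator: True means
    voltage <= threshold is scored "in water".
    """
    burst = motion.burst
    n_acc = int(round(window_s * burst.accel_hz))
    n_imm = int(round(window_s * burst.immersion_hz))
    if n_acc <= 0 or abs(window_s * burst.accel_hz - n_acc) > 1e-9:
        raise ValueError("window_s must divide into whole samples at both rates")
    n_win = len(motion) // n_acc
    if n_win == 0:
        logger.warning("burst %s shorter than one window; no features", burst.burst_id)
    cols: dict[str, list] = {k: [] for k in (
        "window_index", "burst_id", "individual_id", "sex", "gravid", "window_start",
        "odba_max", "odba_mean", "odba_iqr", "odba_var",
        "pitch_max", "pitch_mean", "pitch_iqr", "pitch_var",
        "immersed",
    )}
    step = pd.Timedelta(seconds=window_s)
    wet_all = (
        motion.burst.analog_immersion <= threshold_v
        if wet_below
        else motion.burst.analog_immersion >= threshold_v
    )
    for w in range(n_win):
        o = motion.odba[w * n_acc : (w + 1) * n_acc]
        p = motion.pitch[w * n_acc : (w + 1) * n_acc]
        wet = wet_all[w * n_imm : (w + 1) * n_imm]
        q75o, q25o = np.percentile(o, [75, 25])
        q75p, q25p = np.percentile(p, [75, 25])
        cols["window_index"].append(w)
        cols["burst_id"].append(burst.burst_id)
        cols["individual_id"].append(burst.individual_id)
        cols["sex"].append(burst.sex)
        cols["gravid"].append(burst.gravid)
        cols["window_start"].append(burst.start_time + w * step)
        cols["odba_max"].append(o.max())
        cols["odba_mean"].append(o.mean())
        cols["odba_iqr"].append(q75o - q25o)
        cols["odba_var"].append(o.var(ddof=1))
        cols["pitch_max"].append(p.max())
        cols["pitch_mean"].append(p.mean())
        cols["pitch_iqr"].append(q75p - q25p)
        cols["pitch_var"].append(p.var(ddof=1))
        cols["immersed"].append(int(2 * int(wet.sum()) > len(wet)))
    df = pd.DataFrame(cols)
    return transform_features(df, floor=floor)


def transform_features(windows: pd.DataFrame, floor: float = LOG_FLOOR) -> pd.DataFrame:
    """Add the log10-transformed model features (floored to stay finite)."""
    out = windows.copy()
    out["mean_odba_log10"] = np.log10(np.maximum(out["odba_mean"], floor))
    out["var_pitch_log10"] = np.log10(np.maximum(out["pitch_var"], floor))
    return out


def features_from_bursts(
    bursts: list[RawBurst],
    smooth_window_s: float = SMOOTH_WINDOW_S,
    window_s: float = WINDOW_S,
    threshold_v: float = IMMERSION_THRESHOLD_V,
    wet_below: bool = True,
    floor: float = LOG_FLOOR,
) -> pd.DataFrame:
    """Full feature pipeline for a list of bursts: one row per 30-s window."""
    frames = []
    for burst in bursts:
        motion = decompose(burst, smooth_window_s=smooth_window_s)
        df = summarize_windows(
            motion, window_s=window_s, threshold_v=threshold_v,
            wet_below=wet_below, floor=floor,
        )
        if len(df):
            frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
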