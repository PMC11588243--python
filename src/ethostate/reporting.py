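"""Recording bookkeeping: partitioning deployment durations into the
quantities a study reports (windows, sample counts, hours, per-device
statistics, day lengths)."""

from __future__ import annotations

import numpy as np

__all__ = ["recording_bookkeeping", "seconds_to_days"]


def recording_bookkeeping(
    total_seconds: float,
    device_seconds: list[float] | None = None,
    accel_hz: float = 10.0,
    window_s: float = 30.0,
) -> dict:
    """Derived totals for a multi-device accelerometer study.

    ``device_seconds`` are the per-device recording durations; hour-scale
    figures are rounded to the whole hour, the convention deployment
    tables use.
    """
    out = {
        "total_seconds": float(total_seconds),
        "total_hours": int(round(total_seconds / 3600.0)),
        "n_windows": int(total_seconds // window_s),
        "n_accel_samples": int(round(total_seconds * accel_hz)),
    }
    if device_seconds is not None:
        sec = np.asarray(device_seconds, dtype=float)
        out["n_devices"] = len(sec)
        out["mean_device_seconds"] = total_seconds / len(sec)
        out["sd_device_seconds"] = float(sec.std(ddof=1))
        out["mean_device_hours"] = int(round(sec.mean() / 3600.0))
        out["sd_device_hours"] = int(round(sec.std(ddof=1) / 3600.0))
    return out


def seconds_to_days(seconds: float, decimals: int = 1) -> float:
    return float(np.round(seconds / 86400.0, decimals))
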