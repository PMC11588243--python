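"""Reading, segmenting and writing biologger sensor exports.

Deployments arrive as CSV exports with one row per 10 Hz accelerometer
sample; the 1 Hz analog immersion channel is populated once per second
(blank elsewhere). Because the logger dialect is not standardised, the
reader takes an explicit schema mapping instead of guessing columns.

Recordings are split into gap-free bursts wherever the sampling clock jumps
by more than ``max_gap`` seconds (battery dropouts, magnet-switch restarts);
the downstream HMM likelihood assumes regular sampling, so bursts are the
unit everything else operates on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RawBurst",
    "SchemaError",
    "ParseError",
    "default_schema",
    "load_schema",
    "read_axy_csv",
    "write_axy_csv",
    "segment_bursts",
]


class SchemaError(ValueError):
    """The schema config does not match the file."""


class ParseError(ValueError):
    """A data value could not be parsed; the message names the row."""


@dataclass
class RawBurst:
    """One gap-free segment of 10 Hz tri-axial acceleration + 1 Hz immersion.

    Acceleration is in g (sensor range ±2 g by default), the analog
    immersion channel in the logger's voltage units. ``analog_immersion``
    holds one value per second: ``ceil(n_samples * immersion_hz / accel_hz)``
    entries.
    """

    individual_id: str
    sex: str  # "male" | "female"
    gravid: bool
    start_time: pd.Timestamp
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    analog_immersion: np.ndarray
    accel_hz: float = 10.0
    immersion_hz: float = 1.0
    burst_id: str = ""
    range_g: float = 2.0

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        self.analog_immersion = np.asarray(self.analog_immersion, dtype=float)
        n = len(self.ax)
        if not (len(self.ay) == len(self.az) == n):
            raise ValueError("acceleration axes must have equal length")
        expected = math.ceil(n * self.immersion_hz / self.accel_hz)
        if len(self.analog_immersion) != expected:
            raise ValueError(
                f"immersion length {len(self.analog_immersion)} != expected {expected}"
            )
        for name, a in (("x", self.ax), ("y", self.ay), ("z", self.az)):
            bad = np.flatnonzero(np.abs(a) > self.range_g + 1e-9)
            if bad.size:
                raise ValueError(
                    f"{name}-axis sample {bad[0]} out of sensor range ±{self.range_g} g"
                )
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.gravid and self.sex != "female":
            raise ValueError("gravid implies female")
        self.start_time = pd.Timestamp(self.start_time)
        if self.start_time.tzinfo is None:
            self.start_time = self.start_time.tz_localize("UTC")
        if not self.burst_id:
            self.burst_id = f"{self.individual_id}_b0"

    @property
    def n_samples(self) -> int:
        return len(self.ax)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.accel_hz

    def timestamps(self) -> pd.DatetimeIndex:
        offsets = pd.to_timedelta(np.arange(self.n_samples) / self.accel_hz, unit="s")
        return pd.DatetimeIndex(self.start_time + offsets)


def default_schema() -> dict:
    """Schema for the package's own CSV dialect (also used by the writer)."""
    return {
        "delimiter": ",",
        "timestamp_format": "iso",  # or "epoch" (seconds)
        "columns": {
            "timestamp": "timestamp",
            "x": "accX",
            "y": "accY",
            "z": "accZ",
            "analog": "analog",
        },
        "metadata": {"individual_id": "unknown", "sex": "female", "gravid": False},
        "accel_hz": 10.0,
        "immersion_hz": 1.0,
        "range_g": 2.0,
        "max_gap_s": 2.0,
    }


def load_schema(path) -> dict:
    import yaml

    with open(path) as fh:
        schema = yaml.safe_load(fh)
    base = default_schema()
    base.update(schema or {})
    return base


def _parse_numeric(raw: pd.Series, colname: str, allow_blank: bool = False) -> np.ndarray:
    # numpy's string parser is correctly rounded (exact round-trips)
    stripped = raw.fillna("").astype(str).str.strip().to_numpy()
    blank = stripped == ""
    if blank.any() and not allow_blank:
        row = int(np.flatnonzero(blank)[0])
        raise ParseError(f"missing value in column {colname!r} at data row {row + 1}")
    try:
        return np.asarray(np.where(blank, "nan", stripped), dtype=float)
    except ValueError:
        for row, tok in enumerate(stripped):
            if tok == "":
                continue
            try:
                float(tok)
            except ValueError:
                raise ParseError(
                    f"non-numeric value {raw.iloc[row]!r} in column {colname!r} "
                    f"at data row {row + 1}"
                ) from None
        raise


def read_axy_csv(path, schema: dict | None = None) -> list[RawBurst]:
    """Read a logger CSV export into gap-segmented :class:`RawBurst` objects.

    ``schema`` maps the file's columns and carries per-deployment metadata
    (see :func:`default_schema`). Returns an empty list for an empty file.
    """
    schema = {**default_schema(), **(schema or {})}
    cols = schema["columns"]
    for key in ("timestamp", "x", "y", "z", "analog"):
        if key not in cols:
            raise SchemaError(f"schema is missing a mapping for {key!r}")
    try:
        df = pd.read_csv(path, sep=schema["delimiter"], dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing = [c for c in (cols["timestamp"], cols["x"], cols["y"], cols["z"], cols["analog"])
               if c not in df.columns]
    if missing:
        raise SchemaError(f"file {path} is missing columns {missing}")

    if schema["timestamp_format"] == "epoch":
        ts = pd.to_datetime(
            _parse_numeric(df[cols["timestamp"]], cols["timestamp"]), unit="s", utc=True
        )
    else:
        ts = pd.to_datetime(df[cols["timestamp"]], utc=True, format="ISO8601")
    stream = pd.DataFrame(
        {
            "timestamp": ts,
            "x": _parse_numeric(df[cols["x"]], cols["x"]),
            "y": _parse_numeric(df[cols["y"]], cols["y"]),
            "z": _parse_numeric(df[cols["z"]], cols["z"]),
            "analog": _parse_numeric(df[cols["analog"]], cols["analog"], allow_blank=True),
        }
    )

    meta = schema.get("metadata", {})
    if "individual_id" in cols and cols["individual_id"] in df.columns:
        groups = [
            (str(ind), grp)
            for ind, grp in stream.groupby(df[cols["individual_id"]].to_numpy(), sort=True)
        ]
    else:
        groups = [(str(meta.get("individual_id", "unknown")), stream)]

    bursts: list[RawBurst] = []
    for ind, grp in groups:
        bursts.extend(
            segment_bursts(
                grp.reset_index(drop=True),
                max_gap=float(schema["max_gap_s"]),
                individual_id=ind,
                sex=str(meta.get("sex", "female")),
                gravid=bool(meta.get("gravid", False)),
                accel_hz=float(schema["accel_hz"]),
                immersion_hz=float(schema["immersion_hz"]),
                range_g=float(schema["range_g"]),
            )
        )
    return bursts


def _segment_slices(timestamps: np.ndarray, max_gap_s: float) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of gap-free runs.

    ``timestamps`` is in seconds (monotone strictly increasing required).
    """
    t = np.asarray(timestamps, dtype=float)
    if len(t) == 0:
        return []
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    breaks = np.flatnonzero(dt > max_gap_s) + 1
    edges = np.concatenate([[0], breaks, [len(t)]])
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def segment_bursts(
    stream: pd.DataFrame,
    max_gap: float = 2.0,
    *,
    individual_id: str = "unknown",
    sex: str = "female",
    gravid: bool = False,
    accel_hz: float = 10.0,
    immersion_hz: float = 1.0,
    range_g: float = 2.0,
    min_burst_s: float = 30.0,
) -> list[RawBurst]:
    """Split a time-stamped sensor stream into gap-free bursts.

    ``stream`` needs columns ``timestamp`` (datetime), ``x``, ``y``, ``z``
    and ``analog`` (non-null once per second, NaN elsewhere is fine). Any
    inter-sample step larger than ``max_gap`` seconds starts a new burst;
    segments shorter than one 30-s analysis window are logged and dropped.
    Within a burst the 1 Hz analog channel is aligned to whole seconds since
    burst start and forward-filled across occasional missing seconds.
    """
    if len(stream) == 0:
        return []
    t = stream["timestamp"]
    tsec = t.astype("int64").to_numpy() / 1e9
    slices = _segment_slices(tsec, max_gap)
    bursts: list[RawBurst] = []
    k = 0
    for a, b in slices:
        n = b - a
        if n / accel_hz < min_burst_s:
            logger.warning(
                "dropping %0.1f-s segment of %s (< one %d-s window)",
                n / accel_hz, individual_id, int(min_burst_s),
            )
            continue
        seg = stream.iloc[a:b]
        sec = np.floor(tsec[a:b] - tsec[a] + 1e-9).astype(int)
        n_imm = math.ceil(n * immersion_hz / accel_hz)
        analog = np.full(n_imm, np.nan)
        vals = seg["analog"].to_numpy(dtype=float)
        has = ~np.isnan(vals)
        if has.any():
            # first non-null reading per second wins
            for i in np.flatnonzero(has)[::-1]:
                if sec[i] < n_imm:
                    analog[sec[i]] = vals[i]
        filled = pd.Series(analog).ffill().bfill().to_numpy()
        if np.any(np.isnan(filled)):
            raise ParseError(f"burst of {individual_id} has no analog immersion readings")
        bursts.append(
            RawBurst(
                individual_id=individual_id,
                sex=sex,
                gravid=gravid,
                start_time=t.iloc[a],
                ax=seg["x"].to_numpy(dtype=float),
                ay=seg["y"].to_numpy(dtype=float),
                az=seg["z"].to_numpy(dtype=float),
                analog_immersion=filled,
                accel_hz=accel_hz,
                immersion_hz=immersion_hz,
                burst_id=f"{individual_id}_b{k}",
                range_g=range_g,
            )
        )
        k += 1
    return bursts


def write_axy_csv(bursts: list[RawBurst], path, schema: dict | None = None) -> None:
    """Write bursts back to the CSV dialect :func:`read_axy_csv` reads.

    The analog channel is written on the first sample of each second and
    left blank elsewhere, as loggers export it. Round-trips are
    sample-identical for conforming data.
    """
    schema = {**default_schema(), **(schema or {})}
    cols = schema["columns"]
    frames = []
    for burst in bursts:
        ts = burst.timestamps()
        analog = np.full(burst.n_samples, np.nan)
        step = int(round(burst.accel_hz / burst.immersion_hz))
        idx = np.arange(len(burst.analog_immersion)) * step
        analog[idx[idx < burst.n_samples]] = burst.analog_immersion[
            : np.sum(idx < burst.n_samples)
        ]
        if schema["timestamp_format"] == "epoch":
            ts_out = ts.astype("int64") / 1e9
        else:
            ts_out = ts.strftime("%Y-%m-%dT%H:%M:%S.%f")
        frames.append(
            pd.DataFrame(
                {
                    cols["timestamp"]: ts_out,
                    cols["x"]: burst.ax,
                    cols["y"]: burst.ay,
                    cols["z"]: burst.az,
                    cols["analog"]: analog,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep=schema["delimiter"], index=False)
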