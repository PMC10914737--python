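"""Reading, validation and windowing of long-format sensor streams.

All pipeline stages consume the containers defined here.  A session is a
mapping from sensor modality (accelerometer, step detector, ambient light,
screen status, foreground app, room location, fridge contact, appliance
power, room lights, wrist-worn activity probabilities) to a time-sorted
:class:`SensorSeries`.  Timestamps are seconds since session start; readers
convert epoch-millisecond sources.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MODALITIES",
    "ROOMS",
    "APPLIANCES",
    "SensorSample",
    "SensorSeries",
    "SessionBundle",
    "ModalityError",
    "SensorFormatError",
    "read_sensor_csv",
    "write_sensor_csv",
    "slice_windows",
    "load_session",
]

#: Rooms available for the room-level location modality.
ROOMS = ("kitchen", "living_room", "bathroom", "toilet", "bedroom", "hallway")

#: Appliances monitored through power sensors.
APPLIANCES = ("cooking_plate", "cooking_hood", "kettle", "coffee_machine", "tv")

# modality -> (value arity, kind); kind is "numeric" or "categorical"
_BASE_MODALITIES = {
    "accelerometer": (3, "numeric"),
    "step": (1, "numeric"),
    "light_phone": (1, "numeric"),
    "screen": (1, "categorical"),
    "app": (1, "categorical"),
    "location": (1, "categorical"),
    "fridge": (1, "numeric"),
    "wearable_probs": (5, "numeric"),
}
MODALITIES = dict(_BASE_MODALITIES)
for _a in APPLIANCES:
    MODALITIES[f"power_{_a}"] = (1, "numeric")
for _r in ("bathroom", "toilet"):
    MODALITIES[f"light_{_r}"] = (1, "numeric")


class ModalityError(ValueError):
    """Unknown modality or value arity mismatch."""


class SensorFormatError(ValueError):
    """Malformed sensor file (bad timestamp, wrong columns)."""


@dataclass(frozen=True)
class SensorSample:
    """One observation: time in seconds since session start plus values."""

    t: float
    values: tuple

    def __post_init__(self):
        if not math.isfinite(self.t) or self.t < 0:
            raise SensorFormatError(f"timestamp must be finite and >= 0, got {self.t}")


@dataclass
class SensorSeries:
    """Time-sorted samples of one modality for one session."""

    modality: str
    samples: list[SensorSample] = field(default_factory=list)
    nominal_rate: float | None = None  # Hz; None for event-based streams
    duration: float | None = None  # seconds; session span if known

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ModalityError(
                f"unknown modality {self.modality!r}; registered: {sorted(MODALITIES)}"
            )
        arity = MODALITIES[self.modality][0]
        for s in self.samples:
            if len(s.values) != arity:
                raise ModalityError(
                    f"{self.modality}: expected {arity} value(s), got {len(s.values)}"
                )
        ts = self.times()
        if len(ts) > 1 and np.any(np.diff(ts) < 0):
            raise SensorFormatError(f"{self.modality}: timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.samples)

    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples], dtype=float)

    def values_array(self) -> np.ndarray:
        """Numeric samples as an (n, arity) array."""
        if MODALITIES[self.modality][1] != "numeric":
            raise ModalityError(f"{self.modality} carries categorical values")
        return np.array([s.values for s in self.samples], dtype=float)

    def span(self) -> float:
        """Nominal span T used for windowing.

        `duration` wins if set; otherwise last minus first timestamp, padded
        by one grid step when a nominal rate is declared (a grid of n samples
        at rate r covers n/r seconds, not (n-1)/r).
        """
        if self.duration is not None:
            return float(self.duration)
        if not self.samples:
            return 0.0
        ts = self.times()
        span = float(ts[-1] - ts[0])
        if self.nominal_rate:
            span += 1.0 / self.nominal_rate
        return span


@dataclass
class SessionBundle:
    """All streams plus raw self-reported ADL label entries of one session."""

    participant_id: str
    streams: dict[str, SensorSeries]
    adl_labels: list = field(default_factory=list)  # list[RawLabelEntry]
    duration: float = 0.0

    def __post_init__(self):
        if not self.participant_id:
            raise ValueError("participant_id must be non-empty")
        for name, series in self.streams.items():
            if series.samples and series.times()[-1] > self.duration + 1e-9:
                raise SensorFormatError(
                    f"stream {name}: timestamp {series.times()[-1]:.3f} exceeds "
                    f"session duration {self.duration:.3f}"
                )

    def stream(self, modality: str) -> SensorSeries:
        if modality not in self.streams:
            raise KeyError(f"session {self.participant_id} has no {modality!r} stream")
        return self.streams[modality]


_EPOCH_MS_THRESHOLD = 1e11  # epoch-ms timestamps are ~1.7e12; session-seconds never are


def _normalize_timestamps(ts: np.ndarray) -> np.ndarray:
    # raw exports may carry epoch milliseconds; convert to session seconds
    if ts.size and np.nanmax(ts) > _EPOCH_MS_THRESHOLD:
        ts = (ts - np.nanmin(ts)) / 1000.0
    return ts


def read_sensor_csv(path: str | Path, modality: str) -> SensorSeries:
    """Read one modality CSV (``timestamp,value...`` with a header row).

    Rows are sorted ascending by timestamp; duplicate timestamps keep the
    last occurrence (sensor retransmission convention).
    """
    if modality not in MODALITIES:
        raise ModalityError(f"unknown modality {modality!r}")
    arity, kind = MODALITIES[modality]
    df = pd.read_csv(path)
    if df.shape[1] < 1 + arity:
        raise SensorFormatError(
            f"{path}: expected timestamp + {arity} value column(s), got {df.shape[1]}"
        )
    ts_raw = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(ts_raw))
    if bad.size:
        raise SensorFormatError(f"{path}: unparseable timestamp in data row {bad[0] + 1}")
    ts = _normalize_timestamps(ts_raw)
    order = np.argsort(ts, kind="stable")
    samples: list[SensorSample] = []
    seen_t: float | None = None
    for i in order:
        if kind == "numeric":
            vals = tuple(float(v) for v in df.iloc[int(i), 1 : 1 + arity])
        else:
            vals = tuple(str(v) for v in df.iloc[int(i), 1 : 1 + arity])
        t = float(ts[i])
        if samples and seen_t == t:
            samples[-1] = SensorSample(t, vals)  # keep last duplicate
        else:
            samples.append(SensorSample(t, vals))
        seen_t = t
    return SensorSeries(modality=modality, samples=samples)


def write_sensor_csv(series: SensorSeries, path: str | Path) -> None:
    """Inverse of :func:`read_sensor_csv`; round-trips exactly."""
    arity, kind = MODALITIES[series.modality]
    if series.modality == "accelerometer":
        cols = ["timestamp", "x", "y", "z"]
    elif kind == "categorical":
        cols = ["timestamp", "event"]
    elif arity == 1:
        cols = ["timestamp", "value"]
    else:
        cols = ["timestamp"] + [f"v{i}" for i in range(arity)]
    rows = [(s.t, *s.values) for s in series.samples]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def slice_windows(
    series: SensorSeries, window_s: float, stride_s: float
) -> list[tuple[float, list[SensorSample]]]:
    """Cut the series into half-open windows ``[start, start + window_s)``.

    For a series spanning ``T >= window_s`` the window count equals
    ``floor((T - window_s) / stride_s) + 1``; shorter series give an empty
    list.  A sample sitting exactly on a window's right edge belongs to the
    next window.
    """
    if window_s <= 0 or stride_s <= 0:
        raise ValueError("window_s and stride_s must be > 0")
    T = series.span()
    if T < window_s or not series.samples:
        return []
    t0 = 0.0 if series.duration is not None else float(series.times()[0])
    n = int(math.floor((T - window_s) / stride_s + 1e-9)) + 1
    ts = series.times()
    out = []
    for k in range(n):
        start = t0 + k * stride_s
        lo = int(np.searchsorted(ts, start, side="left"))
        hi = int(np.searchsorted(ts, start + window_s, side="left"))
        out.append((start, series.samples[lo:hi]))
    return out


def load_session(manifest_path: str | Path) -> SessionBundle:
    """Load a session from a YAML manifest mapping modality -> CSV path.

    Manifest schema::

        participant_id: P01
        duration: 3600.0
        streams:
          accelerometer: {path: accel.csv, rate: 32}
          location: {path: location.csv}
        adl_labels: labels.csv   # optional: start,end,adls (';'-separated)
    """
    from .adl_labels import RawLabelEntry  # local import: no runtime cycle

    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        spec = yaml.safe_load(fh)
    base = manifest_path.parent
    streams: dict[str, SensorSeries] = {}
    for modality, entry in spec.get("streams", {}).items():
        if isinstance(entry, str):
            entry = {"path": entry}
        series = read_sensor_csv(base / entry["path"], modality)
        series.nominal_rate = entry.get("rate")
        series.duration = spec.get("duration")
        streams[modality] = series
    labels: list[RawLabelEntry] = []
    if spec.get("adl_labels"):
        df = pd.read_csv(base / spec["adl_labels"])
        for _, row in df.iterrows():
            labels.append(
                RawLabelEntry(
                    start_t=float(row["start"]),
                    end_t=float(row["end"]),
                    adls=[a.strip() for a in str(row["adls"]).split(";") if a.strip()],
                )
            )
    return SessionBundle(
        participant_id=str(spec["participant_id"]),
        streams=streams,
        adl_labels=labels,
        duration=float(spec.get("duration", 0.0)),
    )
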