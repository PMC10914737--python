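"""Threshold detection of a smartphone lying stationary on a surface.

When the phone rests on a table its accelerometer says nothing about the
person, and wrist-derived activity labels cannot be trusted for training a
phone-based model either.  The detector slides a 1 s window over the
3-axis accelerometer: the phone is flagged stationary when the mean Z
acceleration exceeds 9 m/s² in magnitude (screen up or down) and the
standard deviation stays below 0.7 m/s² on every axis.  Both inequalities
are strict; boundary values do not flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io_streams import SensorSeries
from .lowlevel_labels import MinuteLabels

__all__ = ["OnTableConfig", "OnTableMask", "detect_on_table", "overrule_with_on_table"]

log = logging.getLogger(__name__)

_G = 9.80665  # standard gravity, m/s² — used to rescale thresholds for g-unit input


@dataclass(frozen=True)
class OnTableConfig:
    """Thresholds of the stationarity rule (m/s² unless ``units='g'``)."""

    window_s: float = 1.0
    z_mean_abs_min: float = 9.0
    std_max: float = 0.7
    units: str = "m/s^2"  # or "g": thresholds are divided by standard gravity

    def __post_init__(self):
        if self.window_s <= 0 or self.z_mean_abs_min <= 0 or self.std_max <= 0:
            raise ValueError("all thresholds must be strictly positive")
        if self.units not in ("m/s^2", "g"):
            raise ValueError(f"units must be 'm/s^2' or 'g', got {self.units!r}")

    @property
    def z_threshold(self) -> float:
        return self.z_mean_abs_min / _G if self.units == "g" else self.z_mean_abs_min

    @property
    def std_threshold(self) -> float:
        return self.std_max / _G if self.units == "g" else self.std_max


@dataclass
class OnTableMask:
    """Per-window stationarity flags at ``window_s`` spacing."""

    window_starts: np.ndarray
    flags: np.ndarray
    window_s: float = 1.0

    def __post_init__(self):
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        self.flags = np.asarray(self.flags, dtype=bool)
        if len(self.window_starts) != len(self.flags):
            raise ValueError("window_starts and flags length mismatch")
        if len(self.window_starts) > 1 and np.any(np.diff(self.window_starts) <= 0):
            raise ValueError("window starts must be strictly increasing")


def detect_on_table(accel: SensorSeries, cfg: OnTableConfig | None = None) -> OnTableMask:
    """Flag each 1 s window where the phone lies flat and still.

    A window is flagged iff |mean(Z)| > ``z_mean_abs_min`` and the per-axis
    standard deviation is < ``std_max`` on X, Y and Z separately.  Windows
    holding fewer than two samples are flagged False with a warning (the
    standard deviation is undefined there).
    """
    cfg = cfg or OnTableConfig()
    if accel.modality != "accelerometer":
        raise ValueError(f"expected accelerometer series, got {accel.modality!r}")
    T = accel.span()
    if T < cfg.window_s or not accel.samples:
        return OnTableMask(np.array([]), np.array([], dtype=bool), cfg.window_s)
    ts = accel.times()
    xyz = accel.values_array()
    t0 = 0.0 if accel.duration is not None else float(ts[0])
    n = int(math.floor((T - cfg.window_s) / cfg.window_s + 1e-9)) + 1
    starts = t0 + cfg.window_s * np.arange(n)
    flags = np.zeros(n, dtype=bool)
    short = 0
    for k in range(n):
        lo = int(np.searchsorted(ts, starts[k], side="left"))
        hi = int(np.searchsorted(ts, starts[k] + cfg.window_s, side="left"))
        if hi - lo < 2:
            short += 1
            continue
        w = xyz[lo:hi]
        mean_z = w[:, 2].mean()
        stds = w.std(axis=0)
        flags[k] = abs(mean_z) > cfg.z_threshold and bool(np.all(stds < cfg.std_threshold))
    if short:
        log.warning("%d window(s) with < 2 samples flagged not-on-table", short)
    return OnTableMask(starts, flags, cfg.window_s)


def overrule_with_on_table(
    minute_labels: MinuteLabels, mask: OnTableMask, min_fraction: float = 0.5
) -> MinuteLabels:
    """Replace a minute's wrist-derived label by ``on table`` when the
    stationary-window fraction within that minute reaches ``min_fraction``.
    """
    if len(minute_labels) == 0:
        return MinuteLabels(minute_labels.minute_starts.copy(), list(minute_labels.labels))
    if len(mask.window_starts) == 0:
        raise ValueError("on-table mask is empty: spans are disjoint")
    m_lo, m_hi = minute_labels.minute_starts[0], minute_labels.minute_starts[-1] + 60.0
    if mask.window_starts[-1] + mask.window_s <= m_lo or mask.window_starts[0] >= m_hi:
        raise ValueError("on-table mask does not overlap the labeled minutes")
    out = list(minute_labels.labels)
    for i, start in enumerate(minute_labels.minute_starts):
        sel = (mask.window_starts >= start) & (mask.window_starts < start + 60.0)
        n_win = int(sel.sum())
        if n_win == 0:
            continue
        if mask.flags[sel].sum() / n_win >= min_fraction:
            out[i] = "on table"
    return MinuteLabels(minute_labels.minute_starts.copy(), out)
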