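"""Low-level activity labels from wrist-worn probability predictions.

A wrist-worn wearable model emits an activity probability vector every
7.5 s over {lying down, running, sitting, standing, walking}.  This module
smooths those predictions, aggregates them to one label per minute, and
drops the running class (too rare to be useful for downstream ADL work).
The per-minute labels are the training ground truth for the smartphone
accelerometer CNN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WEARABLE_CLASSES",
    "LOWLEVEL_CLASSES",
    "CNN_CLASSES",
    "ActivityProbSeries",
    "MinuteLabels",
    "smooth_predictions",
    "aggregate_to_minutes",
    "drop_running",
    "read_probs_csv",
    "write_probs_csv",
]

#: Classes emitted by the wrist-worn wearable model (its fixed order).
WEARABLE_CLASSES = ("lying down", "running", "sitting", "standing", "walking")

#: Full low-level label set after phone-on-table overruling.
LOWLEVEL_CLASSES = ("lying down", "on table", "running", "sitting", "standing", "walking")

#: Classes the smartphone CNN is trained on (running discarded).
CNN_CLASSES = ("lying down", "on table", "sitting", "standing", "walking")

_SIMPLEX_TOL = 1e-6


@dataclass
class ActivityProbSeries:
    """Probability vectors on a fixed time grid (step 7.5 s or 3 s)."""

    t0: float
    step: float
    classes: tuple[str, ...]
    probs: np.ndarray  # (T, C)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(self.classes):
            raise ValueError("probs must be (T, n_classes)")
        if self.probs.size:
            if np.any(self.probs < -_SIMPLEX_TOL):
                raise ValueError("probabilities must be non-negative")
            sums = self.probs.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-5):
                raise ValueError("probability vectors must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    def times(self) -> np.ndarray:
        return self.t0 + self.step * np.arange(len(self))

    def at(self, t: float) -> np.ndarray:
        """Zero-order-hold lookup: vector of the last grid point <= t."""
        idx = int(np.floor((t - self.t0) / self.step + 1e-9))
        idx = min(max(idx, 0), len(self) - 1)
        return self.probs[idx]


@dataclass
class MinuteLabels:
    """One low-level label (or None = missing) per minute."""

    minute_starts: np.ndarray  # seconds, 60 s spacing
    labels: list[str | None] = field(default_factory=list)

    def __post_init__(self):
        self.minute_starts = np.asarray(self.minute_starts, dtype=float)
        if len(self.minute_starts) != len(self.labels):
            raise ValueError("minute_starts and labels length mismatch")
        for lab in self.labels:
            if lab is not None and lab not in LOWLEVEL_CLASSES:
                raise ValueError(f"label {lab!r} not in {LOWLEVEL_CLASSES}")

    def __len__(self) -> int:
        return len(self.labels)

    def label_at(self, t: float) -> str | None:
        if len(self) == 0:
            return None
        idx = int(np.floor((t - self.minute_starts[0]) / 60.0))
        if idx < 0 or idx >= len(self):
            return None
        return self.labels[idx]


def smooth_predictions(series: ActivityProbSeries, kernel: int = 3) -> ActivityProbSeries:
    """Temporal mean filter over the probability vectors.

    Each output vector is the arithmetic mean of the ``kernel`` surrounding
    input vectors (window truncated at the edges), which keeps every vector
    on the simplex.  ``kernel`` must be odd; 1 is the identity.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
    if kernel == 1 or len(series) == 0:
        return ActivityProbSeries(series.t0, series.step, series.classes, series.probs.copy())
    half = kernel // 2
    T = len(series)
    out = np.empty_like(series.probs)
    for i in range(T):
        lo, hi = max(0, i - half), min(T, i + half + 1)
        out[i] = series.probs[lo:hi].mean(axis=0)
    return ActivityProbSeries(series.t0, series.step, series.classes, out)


def aggregate_to_minutes(series: ActivityProbSeries) -> MinuteLabels:
    """Per minute: argmax of the mean probability vector over that minute.

    The grid step must divide 60 s evenly (8 steps of 7.5 s per minute).
    Ties break toward the first class in declared order; minutes covering no
    grid point are labeled missing.
    """
    if abs((60.0 / series.step) - round(60.0 / series.step)) > 1e-9:
        raise ValueError(f"grid step {series.step} must divide 60 s evenly")
    if len(series) == 0:
        return MinuteLabels(np.array([]), [])
    ts = series.times()
    first_minute = int(np.floor(ts[0] / 60.0))
    last_minute = int(np.floor(ts[-1] / 60.0))
    starts, labels = [], []
    for m in range(first_minute, last_minute + 1):
        mask = (ts >= m * 60.0) & (ts < (m + 1) * 60.0)
        starts.append(m * 60.0)
        if not mask.any():
            labels.append(None)
        else:
            mean_vec = series.probs[mask].mean(axis=0)
            labels.append(series.classes[int(np.argmax(mean_vec))])
    return MinuteLabels(np.array(starts), labels)


def drop_running(labels: MinuteLabels) -> MinuteLabels:
    """Mark minutes labeled ``running`` as missing (excluded from training)."""
    out = [None if lab == "running" else lab for lab in labels.labels]
    if labels.labels and all(lab is None for lab in out):
        warnings.warn("no labeled minutes remain after dropping running", stacklevel=2)
    return MinuteLabels(labels.minute_starts.copy(), out)


_PROB_COLS = {
    "lying down": "p_lying",
    "running": "p_running",
    "sitting": "p_sitting",
    "standing": "p_standing",
    "walking": "p_walking",
    "on table": "p_on_table",
}


def read_probs_csv(path: str | Path, classes: tuple[str, ...] = WEARABLE_CLASSES) -> ActivityProbSeries:
    df = pd.read_csv(path)
    ts = df["timestamp"].to_numpy(dtype=float)
    if len(ts) > 1:
        steps = np.diff(ts)
        if np.ptp(steps) > 1e-6:
            raise ValueError("probability timestamps must lie on a fixed grid")
        step = float(steps[0])
    else:
        step = 7.5
    probs = df[[_PROB_COLS[c] for c in classes]].to_numpy(dtype=float)
    return ActivityProbSeries(float(ts[0]) if len(ts) else 0.0, step, classes, probs)


def write_probs_csv(series: ActivityProbSeries, path: str | Path) -> None:
    df = pd.DataFrame({"timestamp": series.times()})
    for j, c in enumerate(series.classes):
        df[_PROB_COLS[c]] = series.probs[:, j]
    df.to_csv(path, index=False)
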