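"""Per-3 s feature construction from phone and ambient sensor streams.

The ADL sequence model consumes 10-minute windows of feature vectors, one
vector per 3 s (200 rows per window).  Features:

* low-level activity probabilities (from the accelerometer CNN or any
  other producer of the probability stream);
* phone: binary usage flag reconstructed from app/screen events, step
  count per bin, mean ambient-light lux (log-scaled);
* ambient: time since the fridge was last opened, time since each of five
  appliances was last drawing power (both normalized over 12 h), room
  location one-hot, bathroom/toilet light state.

Eight named presets select which of these enter the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_streams import APPLIANCES, ROOMS, SensorSeries, SessionBundle
from .lowlevel_labels import ActivityProbSeries

__all__ = [
    "PRESETS",
    "TWELVE_HOURS_S",
    "AppEvent",
    "ScreenEvent",
    "UsageInterval",
    "FeatureSequence",
    "MissingModalityError",
    "DEFAULT_SYSTEM_UTILS",
    "reconstruct_usage_intervals",
    "phone_usage_feature",
    "step_feature",
    "light_mean_feature",
    "elapsed_since_feature",
    "power_to_events",
    "appliance_elapsed_feature",
    "room_location_feature",
    "room_light_binary",
    "assemble_features",
    "preset_feature_names",
]

TWELVE_HOURS_S = 43200.0
LUX_CEILING = 10000.0

#: The eight feature-combination presets.
PRESETS = (
    "probs_only",
    "probs_phone_steps",
    "probs_appliances",
    "probs_all_phone",
    "probs_location",
    "all",
    "all_except_location",
    "ambient_only",
)

#: Default foreground-app names treated as system utilities (filtered out
#: before usage-interval reconstruction).  User-extensible via a plain-text
#: file, one name per line.
DEFAULT_SYSTEM_UTILS = frozenset(
    {
        "keyboard",
        "launcher",
        "systemui",
        "packageinstaller",
        "permissioncontroller",
        "inputmethod",
        "lockscreen",
    }
)

SCREEN_OFF_STATES = frozenset({"off", "locked"})


class MissingModalityError(KeyError):
    """A preset requires a stream the session does not provide."""


@dataclass(frozen=True)
class AppEvent:
    t: float
    app: str

    def __post_init__(self):
        if not self.app:
            raise ValueError("app name must be non-empty")


@dataclass(frozen=True)
class ScreenEvent:
    t: float
    state: str

    def __post_init__(self):
        if self.state not in ("on", "off", "locked", "unlocked"):
            raise ValueError(f"unknown screen state {self.state!r}")


@dataclass(frozen=True)
class UsageInterval:
    """A period of active interaction with one foreground app."""

    app: str
    start_t: float
    end_t: float

    def __post_init__(self):
        if not self.start_t < self.end_t:
            raise ValueError("start_t must be < end_t")


def reconstruct_usage_intervals(
    apps: list[AppEvent],
    screens: list[ScreenEvent],
    system_utils: frozenset[str] | set[str] = DEFAULT_SYSTEM_UTILS,
    session_end: float | None = None,
) -> list[UsageInterval]:
    """Rebuild active phone-usage intervals from foreground/screen events.

    Procedure: (1) drop system-utility app entries; (2) insert *Off*
    entries at every screen lock/off timestamp; (3) sort ascending; (4) end
    each entry at its successor's timestamp; (5) drop the *Off* entries.
    Consecutive identical app events are merged (foreground
    re-notifications).  An app still in the foreground at the end of the
    record is closed at ``session_end`` when given, else at its own start
    (and dropped as zero-length).
    """
    entries: list[tuple[float, str | None]] = [
        (e.t, e.app) for e in apps if e.app not in system_utils
    ]
    entries += [(s.t, None) for s in screens if s.state in SCREEN_OFF_STATES]
    entries.sort(key=lambda p: (p[0], p[1] is None))
    merged: list[tuple[float, str | None]] = []
    for t, app in entries:
        if merged and app is not None and merged[-1][1] == app:
            continue
        merged.append((t, app))
    out: list[UsageInterval] = []
    for i, (t, app) in enumerate(merged):
        if app is None:
            continue
        end = merged[i + 1][0] if i + 1 < len(merged) else session_end
        if end is not None and end > t:
            out.append(UsageInterval(app, t, end))
    return out


def phone_usage_feature(intervals: list[UsageInterval], t: float) -> int:
    """1 iff ``t`` falls inside some usage interval (half-open [start, end))."""
    return int(any(iv.start_t <= t < iv.end_t for iv in intervals))


def step_feature(steps: SensorSeries, bin_start: float, bin_s: float = 3.0) -> int:
    """Step-detector events counted in the half-open bin [t, t + bin_s)."""
    ts = steps.times()
    lo = np.searchsorted(ts, bin_start, side="left")
    hi = np.searchsorted(ts, bin_start + bin_s, side="left")
    return int(hi - lo)


def light_mean_feature(light: SensorSeries, bin_start: float, bin_s: float = 3.0) -> float:
    """Mean lux over the bin; empty bins carry the last known value, else 0."""
    ts = light.times()
    vals = light.values_array()[:, 0] if len(light) else np.array([])
    lo = int(np.searchsorted(ts, bin_start, side="left"))
    hi = int(np.searchsorted(ts, bin_start + bin_s, side="left"))
    if hi > lo:
        return float(vals[lo:hi].mean())
    if lo > 0:
        return float(vals[lo - 1])
    return 0.0


def elapsed_since_feature(
    event_times: np.ndarray, t: float, cap: float = TWELVE_HOURS_S
) -> float:
    """min(t − last event ≤ t, cap) / cap; 1.0 when no prior event exists."""
    if cap <= 0:
        raise ValueError("cap must be > 0")
    event_times = np.asarray(event_times, dtype=float)
    idx = int(np.searchsorted(event_times, t, side="right")) - 1
    if idx < 0:
        return 1.0
    return min(t - float(event_times[idx]), cap) / cap


def power_to_events(
    power: SensorSeries, on_threshold: float = 5.0
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Binarize a power trace at ``on_threshold`` watts.

    Returns the rising-edge trigger times and the above-threshold
    intervals; an appliance counts as in use throughout such an interval.
    """
    if on_threshold <= 0:
        raise ValueError("on_threshold must be > 0")
    ts = power.times()
    vals = power.values_array()[:, 0] if len(power) else np.array([])
    on = vals > on_threshold
    triggers: list[float] = []
    intervals: list[tuple[float, float]] = []
    start: float | None = None
    for i in range(len(on)):
        if on[i] and (i == 0 or not on[i - 1]):
            triggers.append(float(ts[i]))
            start = float(ts[i])
        if start is not None and (not on[i]):
            intervals.append((start, float(ts[i])))
            start = None
    if start is not None:
        intervals.append((start, float(ts[-1])))
    return np.array(triggers), intervals


def appliance_elapsed_feature(
    power: SensorSeries, t: float, on_threshold: float = 5.0, cap: float = TWELVE_HOURS_S
) -> float:
    """Normalized time since the appliance was last drawing power.

    0 while the appliance is above threshold; otherwise time since the end
    of the last above-threshold period (or rising edge), capped at 12 h.
    """
    triggers, intervals = power_to_events(power, on_threshold)
    last: float | None = None
    for lo, hi in intervals:
        if lo <= t < hi or (lo <= t <= hi):
            return 0.0
        if hi <= t:
            last = hi
    if triggers.size:
        prior = triggers[triggers <= t]
        if prior.size:
            last = max(last or -np.inf, float(prior[-1]))
    if last is None or last == -np.inf:
        return 1.0
    return min(t - last, cap) / cap


def room_location_feature(locs: SensorSeries, t: float) -> str:
    """Room of the last location event at or before ``t`` ('unknown' before any)."""
    ts = locs.times()
    idx = int(np.searchsorted(ts, t, side="right")) - 1
    if idx < 0:
        return "unknown"
    room = locs.samples[idx].values[0]
    if room not in ROOMS:
        raise ValueError(f"room {room!r} not in registry {ROOMS}")
    return room


def room_light_binary(light_state: SensorSeries, t: float) -> int:
    """Last on/off state at or before ``t``; 0 before any event."""
    ts = light_state.times()
    idx = int(np.searchsorted(ts, t, side="right")) - 1
    if idx < 0:
        return 0
    return int(float(light_state.samples[idx].values[0]) > 0.5)


def _scale_lux(lux: float) -> float:
    return min(np.log1p(max(lux, 0.0)) / np.log1p(LUX_CEILING), 1.0)


_ROOM_CATEGORIES = ROOMS + ("unknown",)
_ROOM_LIGHT_MODALITIES = ("light_bathroom", "light_toilet")


def preset_feature_names(preset: str, prob_classes: tuple[str, ...]) -> list[str]:
    """Deterministic, recorded feature order for a preset."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    probs = [f"p_{c.replace(' ', '_')}" for c in prob_classes]
    phone_basic = ["phone_usage", "steps"]
    phone_all = phone_basic + ["light_phone"]
    appliances = ["fridge_elapsed"] + [f"{a}_elapsed" for a in APPLIANCES]
    location = [f"room_{r}" for r in _ROOM_CATEGORIES]
    room_lights = list(_ROOM_LIGHT_MODALITIES)
    if preset == "probs_only":
        return probs
    if preset == "probs_phone_steps":
        return probs + phone_basic
    if preset == "probs_appliances":
        return probs + appliances
    if preset == "probs_all_phone":
        return probs + phone_all
    if preset == "probs_location":
        return probs + location
    if preset == "all":
        return probs + phone_all + appliances + room_lights + location
    if preset == "all_except_location":
        return probs + phone_all + appliances + room_lights
    return appliances + room_lights + location  # ambient_only


_PRESET_MODALITIES = {
    "probs_only": (),
    "probs_phone_steps": ("app", "screen", "step"),
    "probs_appliances": ("fridge",) + tuple(f"power_{a}" for a in APPLIANCES),
    "probs_all_phone": ("app", "screen", "step", "light_phone"),
    "probs_location": ("location",),
    "all": ("app", "screen", "step", "light_phone", "fridge", "location")
    + tuple(f"power_{a}" for a in APPLIANCES)
    + _ROOM_LIGHT_MODALITIES,
    "all_except_location": ("app", "screen", "step", "light_phone", "fridge")
    + tuple(f"power_{a}" for a in APPLIANCES)
    + _ROOM_LIGHT_MODALITIES,
    "ambient_only": ("fridge", "location")
    + tuple(f"power_{a}" for a in APPLIANCES)
    + _ROOM_LIGHT_MODALITIES,
}


@dataclass
class FeatureSequence:
    """One model window: a (steps, F) matrix on the 3 s grid."""

    window_start: float
    step: float
    matrix: np.ndarray
    feature_names: list[str]
    preset: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("matrix columns must match feature_names")


def assemble_features(
    session: SessionBundle,
    probs: ActivityProbSeries | None,
    preset: str,
    window_start: float,
    window_s: float = 600.0,
    step: float = 3.0,
) -> FeatureSequence:
    """Build the (200, F) feature matrix for one 10-min window.

    ``probs`` may be None only for the ``ambient_only`` preset.  Raises
    :class:`MissingModalityError` naming the first stream a preset needs
    but the session lacks.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    needs_probs = preset != "ambient_only"
    if needs_probs and probs is None:
        raise MissingModalityError("low-level activity probabilities")
    for modality in _PRESET_MODALITIES[preset]:
        if modality not in session.streams:
            raise MissingModalityError(modality)
    names = preset_feature_names(preset, probs.classes if needs_probs else ())
    n_steps = int(round(window_s / step))
    grid = window_start + step * np.arange(n_steps)
    cols: dict[str, np.ndarray] = {}

    if needs_probs:
        for j, c in enumerate(probs.classes):
            cols[f"p_{c.replace(' ', '_')}"] = np.array([probs.at(t)[j] for t in grid])
    if any(n in names for n in ("phone_usage", "steps")):
        apps = [AppEvent(s.t, s.values[0]) for s in session.stream("app").samples]
        screens = [ScreenEvent(s.t, s.values[0]) for s in session.stream("screen").samples]
        intervals = reconstruct_usage_intervals(apps, screens, session_end=session.duration)
        cols["phone_usage"] = np.array([phone_usage_feature(intervals, t) for t in grid], float)
        steps_series = session.stream("step")
        cols["steps"] = np.array([step_feature(steps_series, t, step) for t in grid], float)
    if "light_phone" in names:
        lp = session.stream("light_phone")
        cols["light_phone"] = np.array(
            [_scale_lux(light_mean_feature(lp, t, step)) for t in grid]
        )
    if "fridge_elapsed" in names:
        fridge_times = session.stream("fridge").times()
        cols["fridge_elapsed"] = np.array(
            [elapsed_since_feature(fridge_times, t) for t in grid]
        )
        for a in APPLIANCES:
            pw = session.stream(f"power_{a}")
            cols[f"{a}_elapsed"] = np.array(
                [appliance_elapsed_feature(pw, t) for t in grid]
            )
    if _ROOM_LIGHT_MODALITIES[0] in names:
        for m in _ROOM_LIGHT_MODALITIES:
            series = session.stream(m)
            cols[m] = np.array([room_light_binary(series, t) for t in grid], float)
    if f"room_{ROOMS[0]}" in names:
        locs = session.stream("location")
        rooms_at = [room_location_feature(locs, t) for t in grid]
        for r in _ROOM_CATEGORIES:
            cols[f"room_{r}"] = np.array([1.0 if x == r else 0.0 for x in rooms_at])

    matrix = np.column_stack([cols[n] for n in names])
    return FeatureSequence(window_start, step, matrix, names, preset)
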