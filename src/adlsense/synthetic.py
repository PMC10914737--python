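"""Seedable generator of structurally realistic smart-home sessions.

Emulates the shape of a day-in-the-house recording: a scripted sequence of
ADLs drives every sensor stream — 32 Hz smartphone accelerometer windows
follow per-activity motion signatures (gravity orientation, oscillation,
noise), the wrist-worn stream emits softened one-hot activity probability
vectors every 7.5 s, room-location beacons fire on room changes, the
fridge and appliance power traces pulse during cooking, bathroom/toilet
lights switch with occupancy, and phone app/screen/step/light streams
follow phone-related activities.  Self-report pathologies (boundary
jitter, merged multi-label entries, dropped entries) are applied to the
ground-truth label intervals by :func:`corrupt_labels`.

Signatures are separable by construction: tests built on this generator
exercise the pipeline's plumbing and training machinery, not the
difficulty of real accelerometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .adl_labels import ADL_CLASSES, RawLabelEntry, DenseLabelSet, clean_entries, densify
from .io_streams import APPLIANCES, ROOMS, SensorSample, SensorSeries, SessionBundle
from .lowlevel_labels import (
    ActivityProbSeries,
    LOWLEVEL_CLASSES,
    MinuteLabels,
    WEARABLE_CLASSES,
)

__all__ = [
    "ActivitySignature",
    "ActivitySignatureBank",
    "ScriptEntry",
    "ScenarioScript",
    "SyntheticSession",
    "default_signature_bank",
    "daily_routine_script",
    "order_dependent_script",
    "generate_session",
    "corrupt_labels",
    "generate_cohort",
]

ACCEL_RATE = 32.0
WEARABLE_STEP = 7.5
LIGHT_RATE = 1.0
POWER_SAMPLE_S = 15.0


@dataclass(frozen=True)
class ActivitySignature:
    """Accelerometer regime of one low-level activity."""

    gravity: tuple[float, float, float]
    freq_hz: float = 0.0
    amplitude: float = 0.0  # m/s², applied on Z and X
    noise_std: float = 0.2


def default_signature_bank() -> dict[str, ActivitySignature]:
    """Pairwise-distinguishable signatures for the six low-level regimes.

    The phone hangs on a lanyard, so gravity sits mostly along the phone's
    Y axis when upright; *on table* is flat (gravity on Z) and nearly
    still, which is exactly what the threshold detector looks for.
    """
    return {
        "lying down": ActivitySignature((9.81, 0.0, 0.0), noise_std=0.2),
        "on table": ActivitySignature((0.0, 0.0, 9.81), noise_std=0.05),
        "running": ActivitySignature((0.0, 9.5, 1.0), freq_hz=3.0, amplitude=6.0, noise_std=0.5),
        "sitting": ActivitySignature((0.0, 6.94, 6.94), noise_std=0.2),
        "standing": ActivitySignature((0.0, 9.81, 0.5), noise_std=0.2),
        "walking": ActivitySignature((0.0, 9.4, 1.5), freq_hz=2.0, amplitude=3.0, noise_std=0.3),
    }


ActivitySignatureBank = dict[str, ActivitySignature]

# ADL -> (room, low-level regime); emissions are handled per-ADL below.
_ADL_SEMANTICS: dict[str, tuple[str, str]] = {
    "preparing drink": ("kitchen", "standing"),
    "preparing meal": ("kitchen", "standing"),
    "toileting": ("toilet", "sitting"),
    "eating": ("living_room", "sitting"),
    "using computer": ("bedroom", "sitting"),
    "watching tv": ("living_room", "sitting"),
    "walking": ("hallway", "walking"),
    "showering": ("bathroom", "standing"),
    "organizing": ("bedroom", "standing"),
    "using phone": ("living_room", "sitting"),
    "room transition": ("hallway", "walking"),
    "other": ("living_room", "standing"),
}

_ROOM_LUX = {
    "kitchen": 300.0, "living_room": 200.0, "bathroom": 400.0,
    "toilet": 150.0, "bedroom": 100.0, "hallway": 80.0,
}

_PLAUSIBLE_PARALLEL = {
    frozenset(("eating", "watching tv")),
    frozenset(("eating", "using phone")),
    frozenset(("watching tv", "using phone")),
    frozenset(("using computer", "using phone")),
}


@dataclass(frozen=True)
class ScriptEntry:
    adl: str
    duration: float
    room: str | None = None        # defaults to the ADL's natural room
    parallel_with: str | None = None
    lowlevel: str | None = None    # override the low-level regime

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.adl not in _ADL_SEMANTICS:
            raise ValueError(f"unknown ADL {self.adl!r}")
        if self.room is not None and self.room not in ROOMS:
            raise ValueError(f"room {self.room!r} not registered")
        if self.parallel_with is not None:
            pair = frozenset((self.adl, self.parallel_with))
            if pair not in _PLAUSIBLE_PARALLEL:
                raise ValueError(f"implausible parallel pair {set(pair)}")


@dataclass
class ScenarioScript:
    entries: list[ScriptEntry]
    rng_seed: int = 0
    label_noise: tuple[float, float, float] = (0.0, 0.0, 0.0)  # jitter_s, merge_p, drop_p

    @property
    def total_duration(self) -> float:
        return sum(e.duration for e in self.entries)


@dataclass
class SyntheticSession:
    """A generated session plus every ground truth the pipeline could need."""

    bundle: SessionBundle
    truth_entries: list[RawLabelEntry]
    dense_truth: DenseLabelSet
    minute_labels: MinuteLabels
    lowlevel_probs_3s: ActivityProbSeries  # oracle features for the ADL stage


def daily_routine_script(seed: int = 0, label_noise=(0.0, 0.0, 0.0)) -> ScenarioScript:
    """A plausible ~80 min home routine covering all 12 ADLs."""
    e = ScriptEntry
    entries = [
        e("other", 300), e("preparing drink", 180), e("preparing meal", 600),
        e("room transition", 30), e("eating", 600, parallel_with="watching tv"),
        e("room transition", 30), e("toileting", 240),
        e("using computer", 780, lowlevel="on table"),
        e("walking", 180), e("showering", 480), e("organizing", 360),
        e("using phone", 300), e("watching tv", 720),
        e("other", 240, lowlevel="lying down"),  # resting on the sofa
    ]
    return ScenarioScript(entries, rng_seed=seed, label_noise=tuple(label_noise))


def order_dependent_script(seed: int = 0, n_blocks: int = 6) -> ScenarioScript:
    """A routine where *eating* is identifiable only by what preceded it.

    Eating and watching TV share the same room and posture (sitting in the
    living room), so their instantaneous features coincide under presets
    without appliance power; but eating always follows preparing meal while
    watching TV always follows organizing.  A model with temporal memory
    can separate them; a pointwise model cannot.
    """
    rng = np.random.default_rng(seed)
    e = ScriptEntry
    entries: list[ScriptEntry] = [e("other", 120)]
    for _ in range(n_blocks):
        if rng.random() < 0.5:
            entries += [e("preparing meal", 360), e("room transition", 30), e("eating", 480)]
        else:
            entries += [e("organizing", 360), e("room transition", 30), e("watching tv", 480)]
        entries.append(e("walking", 60))
    return ScenarioScript(entries, rng_seed=seed)


def _segment_bounds(script: ScenarioScript) -> list[tuple[float, float, ScriptEntry]]:
    out, t = [], 0.0
    for e in script.entries:
        out.append((t, t + e.duration, e))
        t += e.duration
    return out


def _accel_signal(
    segs, duration: float, bank: ActivitySignatureBank, rng: np.random.Generator
) -> np.ndarray:
    n = int(round(duration * ACCEL_RATE))
    t = np.arange(n) / ACCEL_RATE
    out = np.empty((n, 3))
    for lo, hi, e in segs:
        sig = bank[e.lowlevel or _ADL_SEMANTICS[e.adl][1]]
        m = (t >= lo) & (t < hi)
        k = int(m.sum())
        seg = np.tile(np.asarray(sig.gravity), (k, 1))
        if sig.freq_hz > 0:
            osc = sig.amplitude * np.sin(2 * np.pi * sig.freq_hz * t[m])
            seg[:, 2] += osc
            seg[:, 0] += 0.5 * sig.amplitude * np.sin(2 * np.pi * sig.freq_hz * t[m] + 1.0)
        seg += rng.normal(0.0, sig.noise_std, size=seg.shape)
        out[m] = seg
    return out


def _softened_onehot(cls: str, classes: tuple[str, ...], rng: np.random.Generator) -> np.ndarray:
    alpha = np.ones(len(classes))
    if cls in classes:
        alpha[classes.index(cls)] = 20.0
    return rng.dirichlet(alpha)


def generate_session(
    script: ScenarioScript,
    bank: ActivitySignatureBank | None = None,
    participant_id: str = "P00",
) -> SyntheticSession:
    """Deterministically expand a script into a full SessionBundle."""
    bank = bank or default_signature_bank()
    rng = np.random.default_rng(script.rng_seed)
    segs = _segment_bounds(script)
    duration = script.total_duration

    def S(t, *vals):
        return SensorSample(float(t), tuple(vals))

    streams: dict[str, SensorSeries] = {}

    accel = _accel_signal(segs, duration, bank, rng)
    t_accel = np.arange(len(accel)) / ACCEL_RATE
    streams["accelerometer"] = SensorSeries(
        "accelerometer",
        [S(t, *row) for t, row in zip(t_accel, accel)],
        nominal_rate=ACCEL_RATE, duration=duration,
    )

    # wrist-worn probabilities every 7.5 s over the 5 wearable classes
    wt = np.arange(0.0, duration, WEARABLE_STEP)
    wp = np.empty((len(wt), len(WEARABLE_CLASSES)))
    # oracle low-level probabilities every 3 s over all 6 classes
    ot = np.arange(0.0, duration, 3.0)
    op = np.empty((len(ot), len(LOWLEVEL_CLASSES)))
    seg_i = 0
    for i, t in enumerate(wt):
        while seg_i + 1 < len(segs) and t >= segs[seg_i][1]:
            seg_i += 1
        e = segs[seg_i][2]
        low = e.lowlevel or _ADL_SEMANTICS[e.adl][1]
        wp[i] = _softened_onehot(low, WEARABLE_CLASSES, rng)
    seg_i = 0
    for i, t in enumerate(ot):
        while seg_i + 1 < len(segs) and t >= segs[seg_i][1]:
            seg_i += 1
        e = segs[seg_i][2]
        low = e.lowlevel or _ADL_SEMANTICS[e.adl][1]
        op[i] = _softened_onehot(low, LOWLEVEL_CLASSES, rng)
    streams["wearable_probs"] = SensorSeries(
        "wearable_probs", [S(t, *row) for t, row in zip(wt, wp)], duration=duration
    )
    probs3s = ActivityProbSeries(0.0, 3.0, LOWLEVEL_CLASSES, op)

    # room-location beacons: one event per room change
    loc_samples, last_room = [], None
    for lo, hi, e in segs:
        room = e.room or _ADL_SEMANTICS[e.adl][0]
        if room != last_room:
            loc_samples.append(S(lo, room))
            last_room = room
    streams["location"] = SensorSeries("location", loc_samples, duration=duration)

    # phone ambient light at 1 Hz follows the current room
    lt = np.arange(0.0, duration, 1.0 / LIGHT_RATE)
    lux, seg_i = np.empty(len(lt)), 0
    for i, t in enumerate(lt):
        while seg_i + 1 < len(segs) and t >= segs[seg_i][1]:
            seg_i += 1
        e = segs[seg_i][2]
        room = e.room or _ADL_SEMANTICS[e.adl][0]
        lux[i] = max(_ROOM_LUX[room] + rng.normal(0.0, 10.0), 0.0)
    streams["light_phone"] = SensorSeries(
        "light_phone", [S(t, v) for t, v in zip(lt, lux)],
        nominal_rate=LIGHT_RATE, duration=duration,
    )

    # step events during ambulatory segments (~2 steps/s)
    step_samples = []
    for lo, hi, e in segs:
        if (e.lowlevel or _ADL_SEMANTICS[e.adl][1]) in ("walking", "running"):
            for t in np.arange(lo, hi, 0.5):
                step_samples.append(S(t, 1.0))
    streams["step"] = SensorSeries("step", step_samples, duration=duration)

    # fridge contact + appliance power traces
    fridge, power_on = [], {a: [] for a in APPLIANCES}
    for lo, hi, e in segs:
        adls = {e.adl} | ({e.parallel_with} if e.parallel_with else set())
        if "preparing meal" in adls:
            for t in np.arange(lo, hi, 300.0):
                fridge.append(S(t, 1.0))
            power_on["cooking_plate"].append((lo + 30.0, hi))
            power_on["cooking_hood"].append((lo + 60.0, hi))
        if "preparing drink" in adls:
            fridge.append(S(lo, 1.0))
            power_on["kettle"].append((lo + 10.0, min(lo + 120.0, hi)))
            power_on["coffee_machine"].append((lo + 20.0, min(lo + 90.0, hi)))
        if "watching tv" in adls:
            power_on["tv"].append((lo, hi))
    streams["fridge"] = SensorSeries("fridge", fridge, duration=duration)
    pt = np.arange(0.0, duration, POWER_SAMPLE_S)
    for a in APPLIANCES:
        watts = np.full(len(pt), 1.0)
        for lo, hi in power_on[a]:
            watts[(pt >= lo) & (pt < hi)] = 1500.0
        streams[f"power_{a}"] = SensorSeries(
            f"power_{a}", [S(t, v) for t, v in zip(pt, watts)], duration=duration
        )

    # bathroom / toilet lights switch with occupancy
    for room, mod in (("bathroom", "light_bathroom"), ("toilet", "light_toilet")):
        events = []
        for lo, hi, e in segs:
            if (e.room or _ADL_SEMANTICS[e.adl][0]) == room:
                events.append(S(lo, 1.0))
                events.append(S(min(hi, duration - 1e-3), 0.0))
        streams[mod] = SensorSeries(mod, events, duration=duration)

    # app/screen events during phone-use segments
    apps, screens = [], []
    for lo, hi, e in segs:
        adls = {e.adl} | ({e.parallel_with} if e.parallel_with else set())
        if "using phone" in adls:
            apps.append(S(lo, "messenger"))
            screens.append(S(min(hi, duration - 1e-3), "off"))
    streams["app"] = SensorSeries("app", apps, duration=duration)
    streams["screen"] = SensorSeries("screen", screens, duration=duration)

    # ground truth
    truth_entries = []
    for lo, hi, e in segs:
        adls = [e.adl] + ([e.parallel_with] if e.parallel_with else [])
        truth_entries.append(RawLabelEntry(lo, hi, adls))
    noisy = corrupt_labels(truth_entries, script.label_noise, script.rng_seed)
    dense_truth = densify(clean_entries(truth_entries), duration)
    minute_labels = []
    n_min = int(duration // 60)
    for m in range(n_min):
        center = m * 60.0 + 30.0
        for lo, hi, e in segs:
            if lo <= center < hi:
                minute_labels.append(e.lowlevel or _ADL_SEMANTICS[e.adl][1])
                break
        else:
            minute_labels.append(None)
    minutes = MinuteLabels(60.0 * np.arange(n_min), minute_labels)

    bundle = SessionBundle(
        participant_id=participant_id, streams=streams,
        adl_labels=noisy, duration=duration,
    )
    return SyntheticSession(bundle, truth_entries, dense_truth, minutes, probs3s)


def corrupt_labels(
    truth: list[RawLabelEntry],
    noise: tuple[float, float, float],
    seed: int,
) -> list[RawLabelEntry]:
    """Apply self-report pathologies: jitter, merges, drops.

    Boundaries move uniformly within ±jitter_s; adjacent entries merge into
    one multi-label entry with probability merge_prob; entries drop with
    probability drop_prob.  Zero noise is the identity.
    """
    jitter_s, merge_p, drop_p = noise
    if not (0 <= merge_p <= 1 and 0 <= drop_p <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if jitter_s == 0 and merge_p == 0 and drop_p == 0:
        return [RawLabelEntry(e.start_t, e.end_t, list(e.adls)) for e in truth]
    rng = np.random.default_rng(seed)
    out: list[RawLabelEntry] = []
    for e in truth:
        if rng.random() < drop_p:
            continue
        start = max(e.start_t + rng.uniform(-jitter_s, jitter_s), 0.0)
        end = e.end_t + rng.uniform(-jitter_s, jitter_s)
        if end - start < 1.0:
            end = start + 1.0
        if out and rng.random() < merge_p:
            prev = out[-1]
            merged_adls = list(prev.adls) + [a for a in e.adls if a not in prev.adls]
            out[-1] = RawLabelEntry(prev.start_t, max(prev.end_t, end), merged_adls)
        else:
            out.append(RawLabelEntry(start, end, list(e.adls)))
    return out


def generate_cohort(
    n_participants: int,
    script_factory=daily_routine_script,
    seed: int = 0,
) -> list[SyntheticSession]:
    """Generate a cohort with deterministic per-participant seeds and mild
    per-participant signature perturbation (amplitudes ±20 %)."""
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_participants)
    out = []
    for i in range(n_participants):
        pseed = int(child_seeds[i])
        prng = np.random.default_rng(pseed)
        bank = {}
        for name, sig in default_signature_bank().items():
            f = 1.0 + prng.uniform(-0.2, 0.2)
            bank[name] = replace(
                sig,
                gravity=tuple(np.asarray(sig.gravity)),
                amplitude=sig.amplitude * f,
                noise_std=sig.noise_std * (1.0 + prng.uniform(-0.2, 0.2)),
            )
        script = script_factory(seed=pseed)
        out.append(generate_session(script, bank, participant_id=f"P{i:02d}"))
    return out
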