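"""Cleaning of self-reported ADL intervals and densification to the 3 s grid.

Participants self-report activity intervals (start, end, one or more ADL
names).  Self-reporting produces pathologies the model must not be trained
on verbatim: physically sequential activities grouped into a single entry
(room transition + toileting), passive activities reported alongside an
actively engaged one (preparing meal + toileting), and names outside the
target set.  Cleaning rules:

* a multi-ADL entry whose first (last) reported activity is *room
  transition* allocates the first (last) 30 s to the transition and the
  rest to the remaining activities;
* for pairs with a precedence rule, only the actively engaged activity is
  kept (e.g. preparing meal + toileting -> toileting);
* unlisted names map to *other*;
* genuinely parallel pairs (eating + watching TV) pass through multi-label.

The cleaned segments are densified into a T×12 multi-hot matrix on a 3 s
grid plus a time-weight vector that is 0 on unlabeled grid points, so the
sequence model can consume continuous sensor context while the loss only
sees labeled time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ADL_CLASSES",
    "ROOM_TRANSITION_S",
    "RawLabelEntry",
    "DenseLabelSet",
    "ClassWeights",
    "PrecedenceError",
    "default_precedence",
    "default_parallel",
    "clean_entry",
    "clean_entries",
    "densify",
    "class_weights",
]

#: The 12 target ADL classes, fixed order.
ADL_CLASSES = (
    "preparing drink",
    "preparing meal",
    "toileting",
    "eating",
    "using computer",
    "watching tv",
    "walking",
    "showering",
    "organizing",
    "using phone",
    "room transition",
    "other",
)

#: Seconds allocated to room transition when grouped with other activities.
ROOM_TRANSITION_S = 30.0


class PrecedenceError(ValueError):
    """Inconsistent precedence table (both members of a pair claim precedence)."""


@dataclass
class RawLabelEntry:
    """One self-reported interval with its (possibly multiple) ADL names."""

    start_t: float
    end_t: float
    adls: list[str]

    def __post_init__(self):
        if not self.start_t < self.end_t:
            raise ValueError(f"start_t {self.start_t} must be < end_t {self.end_t}")
        if not self.adls:
            raise ValueError("adls must be non-empty")

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


@dataclass
class DenseLabelSet:
    """Multi-hot labels and time weights on a fixed 3 s grid."""

    t0: float
    step: float
    Y: np.ndarray  # (T, 12) in {0, 1}
    w: np.ndarray  # (T,) in [0, 1]; 0 = unlabeled

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape[1] != len(ADL_CLASSES):
            raise ValueError(f"Y must be (T, {len(ADL_CLASSES)})")
        if self.w.shape != (self.Y.shape[0],):
            raise ValueError("w must have one entry per grid row")
        if not np.isin(self.Y, (0.0, 1.0)).all():
            raise ValueError("Y entries must be 0 or 1")
        if np.any((self.w < 0) | (self.w > 1)):
            raise ValueError("weights must lie in [0, 1]")

    def __len__(self) -> int:
        return self.Y.shape[0]

    def times(self) -> np.ndarray:
        return self.t0 + self.step * np.arange(len(self))


@dataclass
class ClassWeights:
    """Positive/negative weight per class for the balanced binary losses."""

    w_pos: np.ndarray
    w_neg: np.ndarray

    def __post_init__(self):
        self.w_pos = np.asarray(self.w_pos, dtype=float)
        self.w_neg = np.asarray(self.w_neg, dtype=float)
        if self.w_pos.shape != self.w_neg.shape:
            raise ValueError("w_pos / w_neg shape mismatch")
        if np.any(~np.isfinite(self.w_pos)) or np.any(~np.isfinite(self.w_neg)):
            raise ValueError("class weights must be finite")
        if np.any(self.w_pos <= 0) or np.any(self.w_neg <= 0):
            raise ValueError("class weights must be > 0")


def default_precedence() -> dict[frozenset, str]:
    """Pairs where one activity is the actively engaged one.

    Maps an unordered pair to the member that keeps the interval.
    """
    rules: dict[frozenset, str] = {}
    for passive in ("preparing meal", "using computer", "watching tv", "eating"):
        rules[frozenset((passive, "toileting"))] = "toileting"
    rules[frozenset(("using computer", "organizing"))] = "organizing"
    return rules


def default_parallel() -> set[frozenset]:
    """Pairs that legitimately happen at the same time (kept multi-label)."""
    return {
        frozenset(("eating", "watching tv")),
        frozenset(("eating", "using phone")),
        frozenset(("using computer", "using phone")),
        frozenset(("watching tv", "using phone")),
    }


def _validate_rules(rules: dict[frozenset, str]) -> None:
    for pair, winner in rules.items():
        if winner not in pair:
            raise PrecedenceError(f"winner {winner!r} not a member of pair {set(pair)}")


def _canonical(name: str) -> str:
    name = name.strip().lower()
    return name if name in ADL_CLASSES else "other"


def clean_entry(
    entry: RawLabelEntry,
    rules: dict[frozenset, str] | None = None,
    parallel: set[frozenset] | None = None,
) -> list[RawLabelEntry]:
    """Split/filter one raw entry into clean segments covering the same span.

    Returns non-overlapping segments whose union equals ``[start_t, end_t)``;
    each output entry's ADL list is the (possibly multi-label) set active on
    that sub-interval.
    """
    rules = default_precedence() if rules is None else rules
    _validate_rules(rules)
    parallel = default_parallel() if parallel is None else parallel

    adls: list[str] = []
    for a in entry.adls:  # map unlisted names, de-duplicate preserving order
        c = _canonical(a)
        if c not in adls:
            adls.append(c)

    segments: list[RawLabelEntry] = []
    start, end = entry.start_t, entry.end_t

    if len(adls) > 1 and adls[0] == "room transition":
        cut = min(ROOM_TRANSITION_S, end - start)
        segments.append(RawLabelEntry(start, start + cut, ["room transition"]))
        start += cut
        adls = adls[1:]
    tail: RawLabelEntry | None = None
    if len(adls) > 1 and adls[-1] == "room transition" and end > start:
        cut = min(ROOM_TRANSITION_S, end - start)
        tail = RawLabelEntry(end - cut, end, ["room transition"])
        end -= cut
        adls = adls[:-1]

    if end > start and adls:
        kept = list(adls)
        changed = True
        while changed and len(kept) > 1:  # precedence closure
            changed = False
            for i in range(len(kept)):
                for j in range(i + 1, len(kept)):
                    pair = frozenset((kept[i], kept[j]))
                    if len(pair) == 2 and pair in rules:
                        loser = next(iter(pair - {rules[pair]}))
                        kept.remove(loser)
                        changed = True
                        break
                if changed:
                    break
        if len(kept) > 1:
            for i in range(len(kept)):
                for j in range(i + 1, len(kept)):
                    pair = frozenset((kept[i], kept[j]))
                    if len(pair) == 2 and pair not in parallel:
                        warnings.warn(
                            f"no precedence rule for pair {set(pair)}; keeping both",
                            stacklevel=2,
                        )
        segments.append(RawLabelEntry(start, end, kept))
    if tail is not None:
        segments.append(tail)
    return segments


def clean_entries(
    entries: list[RawLabelEntry],
    rules: dict[frozenset, str] | None = None,
    parallel: set[frozenset] | None = None,
) -> list[RawLabelEntry]:
    out: list[RawLabelEntry] = []
    for e in entries:
        out.extend(clean_entry(e, rules=rules, parallel=parallel))
    return out


def densify(
    entries: list[RawLabelEntry], duration: float, step: float = 3.0, t0: float = 0.0
) -> DenseLabelSet:
    """Rasterize cleaned segments onto the 3 s grid.

    ``Y[t, c] = 1`` iff grid point t falls inside a segment labeled c
    (half-open intervals); ``w[t] = 1`` iff t falls inside any segment.
    Overlapping segments union their labels (the problem is multi-label).
    """
    T = int(np.floor((duration - t0) / step + 1e-9))
    Y = np.zeros((T, len(ADL_CLASSES)))
    w = np.zeros(T)
    idx = {c: i for i, c in enumerate(ADL_CLASSES)}
    for e in entries:
        lo = int(np.ceil((e.start_t - t0) / step - 1e-9))
        hi = int(np.ceil((e.end_t - t0) / step - 1e-9))
        lo, hi = max(lo, 0), min(hi, T)
        if hi <= lo:
            continue
        w[lo:hi] = 1.0
        for a in e.adls:
            Y[lo:hi, idx[_canonical(a)]] = 1.0
    return DenseLabelSet(t0, step, Y, w)


def class_weights(dense: DenseLabelSet) -> ClassWeights:
    """Balanced inverse-frequency weights over labeled time.

    With L = Σw and P_c = Σ_t w_t Y_tc:
    ``w_pos_c = L / (2 P_c)``, ``w_neg_c = L / (2 (L - P_c))``, so that
    ``w_pos_c P_c + w_neg_c (L - P_c) = L`` for every class.  Classes absent
    from the labeled span get ``w_pos = 1`` with a warning.
    """
    L = float(dense.w.sum())
    if L == 0:
        raise ValueError("nothing labeled: all time weights are zero")
    P = dense.w @ dense.Y
    w_pos = np.ones(len(ADL_CLASSES))
    w_neg = np.ones(len(ADL_CLASSES))
    for c in range(len(ADL_CLASSES)):
        if P[c] == 0:
            warnings.warn(
                f"class {ADL_CLASSES[c]!r} has no positive labeled time; w_pos set to 1",
                stacklevel=2,
            )
            # w_neg = 1 keeps the balancing identity w_pos*P + w_neg*(L-P) = L
        elif P[c] == L:
            w_pos[c] = 1.0
        else:
            w_pos[c] = L / (2 * P[c])
            w_neg[c] = L / (2 * (L - P[c]))
    return ClassWeights(w_pos, w_neg)
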