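"""Smartphone-accelerometer CNN for low-level activity recognition.

6 s windows of 3-axis accelerometer data (32 Hz -> 192 samples) slide with
a 3 s stride; each window is classified into the low-level activities and
the resulting probability vectors, one per 3 s, feed the downstream ADL
model as features.  Training uses per-minute labels derived from the
wrist-worn wearable stream (after phone-on-table overruling), random 3-D
rotation augmentation and additive Gaussian noise, and a participant-level
holdout + 4-fold group cross-validation protocol.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .io_streams import SensorSeries
from .lowlevel_labels import ActivityProbSeries, CNN_CLASSES, MinuteLabels

__all__ = [
    "WINDOW_S",
    "STRIDE_S",
    "RATE_HZ",
    "SAMPLES_PER_WINDOW",
    "AccelWindow",
    "HarCnnConfig",
    "CvSplit",
    "rotate_augment",
    "random_rotation_matrix",
    "build_har_cnn",
    "HarCnn",
    "make_cv_split",
    "extract_windows",
    "label_windows",
    "train_har",
    "predict_probs",
]

WINDOW_S = 6.0
STRIDE_S = 3.0
RATE_HZ = 32.0  # nominal smartphone accelerometer rate; 6 s x 32 Hz = 192
SAMPLES_PER_WINDOW = int(WINDOW_S * RATE_HZ)


@dataclass
class AccelWindow:
    """One 6 s window: exactly 192 x 3 accelerations in m/s²."""

    start_t: float
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (SAMPLES_PER_WINDOW, 3):
            raise ValueError(
                f"window must be ({SAMPLES_PER_WINDOW}, 3), got {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window contains non-finite values")


@dataclass
class HarCnnConfig:
    """Architecture and augmentation settings of the low-level CNN.

    Seven convolutional layers with 16 or 32 filters and kernel size 5 or
    3, max pooling of size 2 after every second conv layer, two dense
    layers (32, 16) and a softmax head.
    """

    conv_layers: tuple = (
        (32, 5, False), (32, 5, True),      # (filters, kernel, pool-after)
        (32, 5, False), (32, 3, True),
        (16, 3, False), (16, 3, True),
        (16, 3, False),
    )
    dense: tuple[int, int] = (32, 16)
    n_classes: int = len(CNN_CLASSES)
    rotation_max_deg: float = 15.0
    gauss_noise_std: float = 0.1  # m/s²
    spatial_dropout: float = 0.1
    dropout: float = 0.2
    learning_rate: float = 1e-3
    class_names: tuple[str, ...] = CNN_CLASSES

    def __post_init__(self):
        if len(self.conv_layers) != 7:
            raise ValueError("exactly 7 convolutional layers are required")
        for filters, kernel, _ in self.conv_layers:
            if filters not in (16, 32) or kernel not in (3, 5):
                raise ValueError("conv filters must be 16/32 and kernels 5/3")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class CvSplit:
    """Participant-level holdout set plus group cross-validation folds."""

    holdout: tuple[str, ...]
    folds: list[tuple[tuple[str, ...], tuple[str, ...]]]  # (train ids, val ids)

    def __post_init__(self):
        hold = set(self.holdout)
        for train, val in self.folds:
            if hold & (set(train) | set(val)):
                raise ValueError("holdout participants leak into CV folds")
            if set(train) & set(val):
                raise ValueError("train and validation overlap within a fold")


def random_rotation_matrix(max_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Rotation X·Y·Z with per-axis angles uniform in ±max_deg."""
    ax, ay, az = np.deg2rad(rng.uniform(-max_deg, max_deg, size=3))
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


def rotate_augment(window: AccelWindow, max_deg: float, rng_seed: int) -> AccelWindow:
    """Apply one small random 3-D rotation shared by all samples of the window.

    Simulates slight differences in how the phone hangs on the person;
    vector norms are preserved.
    """
    if max_deg < 0:
        raise ValueError("max_deg must be >= 0")
    if max_deg == 0:
        return AccelWindow(window.start_t, window.samples.copy())
    R = random_rotation_matrix(max_deg, np.random.default_rng(rng_seed))
    return AccelWindow(window.start_t, window.samples @ R.T)


class HarCnn:
    """The CNN with train/inference forward passes and a softmax head."""

    def __init__(self, cfg: HarCnnConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = [nn.GaussianNoise(cfg.gauss_noise_std, rng=rng)]
        in_ch = 3
        for filters, kernel, pool in cfg.conv_layers:
            layers.append(nn.Conv1D(in_ch, filters, kernel, activation="relu", rng=rng))
            in_ch = filters
            if pool:
                layers.append(nn.MaxPool1D(2))
        layers.append(nn.SpatialDropout1D(cfg.spatial_dropout, rng=rng))
        layers.append(nn.Flatten())
        n_pools = sum(1 for *_ , p in cfg.conv_layers if p)
        flat = (SAMPLES_PER_WINDOW // (2 ** n_pools)) * in_ch
        layers.append(nn.Dense(flat, cfg.dense[0], activation="relu", rng=rng))
        layers.append(nn.Dropout(cfg.dropout, rng=rng))
        layers.append(nn.Dense(cfg.dense[0], cfg.dense[1], activation="relu", rng=rng))
        layers.append(nn.Dense(cfg.dense[1], cfg.n_classes, activation="softmax", rng=rng))
        self.net = nn.Sequential(layers)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(B, 192, 3) -> (B, n_classes) probability vectors summing to 1."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != (SAMPLES_PER_WINDOW, 3):
            raise ValueError(f"expected (B, {SAMPLES_PER_WINDOW}, 3), got {X.shape}")
        return self.net.forward(X, train=False)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for k, (layer, name) in enumerate(self.net.parameters()):
            arrays[f"{k}_{name}"] = layer.params[name]
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "n_classes": self.cfg.n_classes,
            "class_names": list(self.cfg.class_names),
            "conv_layers": [list(c) for c in self.cfg.conv_layers],
            "dense": list(self.cfg.dense),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def build_har_cnn(cfg: HarCnnConfig | None = None, seed: int = 0) -> HarCnn:
    return HarCnn(cfg or HarCnnConfig(), seed=seed)


def make_cv_split(
    participants: list[str], holdout_n: int = 10, k: int = 4, seed: int = 0
) -> CvSplit:
    """Hold out ``holdout_n`` participants; split the rest into ``k`` group
    folds with near-equal validation sizes (6/5/5/5 for 21 remaining)."""
    if len(participants) < holdout_n + k:
        raise ValueError(
            f"need >= {holdout_n + k} participants, got {len(participants)}"
        )
    rng = np.random.default_rng(seed)
    ids = list(participants)
    rng.shuffle(ids)
    holdout = tuple(sorted(ids[:holdout_n]))
    rest = ids[holdout_n:]
    sizes = [len(rest) // k + (1 if i < len(rest) % k else 0) for i in range(k)]
    folds = []
    pos = 0
    for s in sizes:
        val = tuple(sorted(rest[pos : pos + s]))
        train = tuple(sorted(set(rest) - set(val)))
        folds.append((train, val))
        pos += s
    return CvSplit(holdout, folds)


def extract_windows(accel: SensorSeries) -> list[AccelWindow]:
    """Slide 6 s / 3 s-stride windows; resample onto the 32 Hz nominal grid.

    Linear interpolation onto the nominal grid absorbs source jitter;
    windows not fully covered by data are skipped.
    """
    if accel.modality != "accelerometer":
        raise ValueError("expected an accelerometer series")
    if len(accel) < 2:
        return []
    ts = accel.times()
    xyz = accel.values_array()
    T = accel.span()
    if T < WINDOW_S:
        return []
    t0 = 0.0 if accel.duration is not None else float(ts[0])
    n = int(np.floor((T - WINDOW_S) / STRIDE_S + 1e-9)) + 1
    out = []
    for k in range(n):
        start = t0 + k * STRIDE_S
        grid = start + np.arange(SAMPLES_PER_WINDOW) / RATE_HZ
        if grid[0] < ts[0] - 1.0 / RATE_HZ or grid[-1] > ts[-1] + 1.0 / RATE_HZ:
            continue
        w = np.column_stack([np.interp(grid, ts, xyz[:, a]) for a in range(3)])
        out.append(AccelWindow(start, w))
    return out


def label_windows(
    windows: list[AccelWindow], minutes: MinuteLabels, classes: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Window label = label of the minute containing the window center.

    Windows whose minute is missing or outside ``classes`` are excluded.
    Returns (X, y) with y as integer class indices.
    """
    X, y = [], []
    index = {c: i for i, c in enumerate(classes)}
    for w in windows:
        lab = minutes.label_at(w.start_t + WINDOW_S / 2.0)
        if lab in index:
            X.append(w.samples)
            y.append(index[lab])
    if not X:
        return np.empty((0, SAMPLES_PER_WINDOW, 3)), np.empty(0, dtype=int)
    return np.stack(X), np.array(y, dtype=int)


def train_har(
    model: HarCnn,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 10,
    batch_size: int = 128,
    seed: int = 0,
) -> list[float]:
    """Fit with class-weighted categorical cross-entropy and rotation
    augmentation; returns the per-epoch mean training loss."""
    cfg = model.cfg
    n = len(y)
    if n == 0:
        raise ValueError("no labeled windows to train on")
    counts = np.bincount(y, minlength=cfg.n_classes).astype(float)
    missing = [cfg.class_names[c] for c in range(cfg.n_classes) if counts[c] == 0]
    if missing:
        warnings.warn(f"classes absent from training data: {missing}", stacklevel=2)
    cw = np.where(counts > 0, n / (cfg.n_classes * np.maximum(counts, 1)), 0.0)
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.net.parameters(), lr=cfg.learning_rate)
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            xb = X[idx]
            if cfg.rotation_max_deg > 0:  # one shared rotation per window
                xb = np.stack(
                    [w @ random_rotation_matrix(cfg.rotation_max_deg, rng).T for w in xb]
                )
            probs = model.net.forward(xb, train=True)
            onehot = np.eye(cfg.n_classes)[y[idx]]
            wvec = cw[y[idx]]
            p = np.clip(probs, 1e-12, 1.0)
            losses.append(float(-(wvec * (onehot * np.log(p)).sum(axis=1)).mean()))
            grad = (probs - onehot) * wvec[:, None] / len(idx)  # fused softmax-CE
            model.net.backward(grad)
            opt.step()
        history.append(float(np.mean(losses)))
    return history


def predict_probs(model: HarCnn, accel: SensorSeries, batch_size: int = 256) -> ActivityProbSeries:
    """Classify every 6 s window -> probability series at the 3 s stride."""
    windows = extract_windows(accel)
    if not windows:
        return ActivityProbSeries(0.0, STRIDE_S, model.cfg.class_names,
                                  np.empty((0, model.cfg.n_classes)))
    X = np.stack([w.samples for w in windows])
    probs = np.vstack([
        model.predict_proba(X[lo : lo + batch_size])
        for lo in range(0, len(X), batch_size)
    ])
    return ActivityProbSeries(windows[0].start_t, STRIDE_S, model.cfg.class_names, probs)
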