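"""Multi-label ADL sequence network, masked balanced loss and training.

The network consumes 10-minute windows of per-3 s feature vectors
(200 × F) and emits one 12-class sigmoid probability vector per 6 s
(100 × 12): an LSTM over time returns the full hidden sequence, which is
concatenated with the raw input (skip connection), passed through a
pointwise convolution (16 filters, kernel 1, ReLU), max-pooled by 2 along
time, and mapped to the 12 classes by a second pointwise convolution with
sigmoid activation.  Dropping the LSTM and the skip connection gives the
no-temporal-context baseline (two kernel-1 convolutions only).

The loss is the mean over the 12 classes of a balanced binary
cross-entropy, weighted along the time dimension; unlabeled time steps
carry weight zero and therefore contribute exactly nothing, which lets the
model see continuous sensor context without labels everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .adl_labels import ADL_CLASSES, ClassWeights, DenseLabelSet
from .features import FeatureSequence

__all__ = [
    "ADL_WINDOW_S",
    "ADL_STRIDE_S",
    "STEPS_PER_WINDOW",
    "OUTPUT_STEPS",
    "AdlNetConfig",
    "AdlNetwork",
    "AdlPrediction",
    "build_adl_network",
    "pool_labels_to_output_grid",
    "masked_balanced_bce",
    "train_adl",
    "predict_session",
    "hyperparam_search",
]

ADL_WINDOW_S = 600.0
ADL_STRIDE_S = 120.0
STEPS_PER_WINDOW = 200   # one feature vector per 3 s
OUTPUT_STEPS = 100       # one prediction per 6 s after the pool of size 2
N_ADL = len(ADL_CLASSES)
_EPS = 1e-7


@dataclass
class AdlNetConfig:
    lstm_units: int = 32
    conv1_filters: int = 16
    dropout: float = 0.1
    gauss_noise_std: float = 0.0
    l1: float = 0.0
    l2: float = 0.0
    learning_rate: float = 1e-3
    epochs: int = 350
    batch_size: int = 1024
    use_lstm: bool = True
    threshold: float = 0.5  # sigmoid binarization for evaluation

    def __post_init__(self):
        if self.lstm_units < 1:
            raise ValueError("lstm_units must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class AdlPrediction:
    """Sigmoid probabilities for one window: (100, 12), one row per 6 s."""

    window_start: float
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (OUTPUT_STEPS, N_ADL):
            raise ValueError(f"probs must be ({OUTPUT_STEPS}, {N_ADL})")
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


class AdlNetwork:
    """LSTM + skip-connection + two pointwise convolutions (Fig.-style)."""

    def __init__(self, cfg: AdlNetConfig, n_features: int, seed: int = 0):
        if n_features < 1:
            raise ValueError("n_features must be >= 1")
        self.cfg = cfg
        self.n_features = n_features
        rng = np.random.default_rng(seed)
        self.noise = nn.GaussianNoise(cfg.gauss_noise_std, rng=rng)
        if cfg.use_lstm:
            self.lstm = nn.LSTM(n_features, cfg.lstm_units, rng=rng)
            conv_in = cfg.lstm_units + n_features
        else:
            self.lstm = None
            conv_in = n_features
        self.conv1 = nn.Conv1D(conv_in, cfg.conv1_filters, 1, activation="relu", rng=rng)
        self.drop = nn.Dropout(cfg.dropout, rng=rng)
        self.pool = nn.MaxPool1D(2)
        self.conv2 = nn.Conv1D(cfg.conv1_filters, N_ADL, 1, activation="sigmoid", rng=rng)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, T, F) -> (B, T/2, 12); T must be even."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[2] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {x.shape[2]}")
        if x.shape[1] % 2:
            raise ValueError("time dimension must be even (pool of size 2)")
        x = self.noise.forward(x, train=train)
        if self.lstm is not None:
            h = self.lstm.forward(x, train=train)
            z = np.concatenate([h, x], axis=2)
        else:
            z = x
        a = self.conv1.forward(z, train=train)
        a = self.drop.forward(a, train=train)
        p = self.pool.forward(a, train=train)
        return self.conv2.forward(p, train=train)

    def backward(self, grad: np.ndarray) -> None:
        g = self.conv2.backward(grad)
        g = self.pool.backward(g)
        g = self.drop.backward(g)
        g = self.conv1.backward(g)
        if self.lstm is not None:
            U = self.cfg.lstm_units
            self.lstm.backward(g[:, :, :U])  # skip-path gradient ends at the input

    def parameters(self) -> list[tuple[nn.Layer, str]]:
        layers = [self.conv1, self.conv2] + ([self.lstm] if self.lstm else [])
        return [(layer, name) for layer in layers for name in layer.params]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)


def build_adl_network(cfg: AdlNetConfig, n_features: int, seed: int = 0) -> AdlNetwork:
    return AdlNetwork(cfg, n_features, seed=seed)


def pool_labels_to_output_grid(Y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reconcile 3 s labels with the 6 s output grid.

    Each output step covers two label steps: the pooled label is the max of
    the two rows (an activity present in either 3 s half is present in the
    6 s step) and the pooled weight is their mean.
    """
    Y = np.asarray(Y, dtype=float)
    w = np.asarray(w, dtype=float)
    if Y.shape[0] % 2 or w.shape[0] != Y.shape[0]:
        raise ValueError("label length must be even and match the weights")
    T2 = Y.shape[0] // 2
    Yp = Y.reshape(T2, 2, -1).max(axis=1)
    wp = w.reshape(T2, 2).mean(axis=1)
    return Yp, wp


def masked_balanced_bce(
    pred: np.ndarray, Y: np.ndarray, w: np.ndarray, cw: ClassWeights
) -> float:
    """Mean over classes of the time-weighted balanced binary cross-entropy.

    loss = (1/12) Σ_c Σ_t w_t [w_pos_c Y_tc (−log p_tc)
                               + w_neg_c (1−Y_tc)(−log(1−p_tc))] / max(Σ_t w_t, ε)

    A window whose weights are all zero contributes exactly 0.  The divisor
    is the fixed registry size (12): passing fewer columns evaluates the
    same formula with the remaining classes contributing zero.
    """
    pred = np.asarray(pred, dtype=float)
    Y = np.asarray(Y, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(~np.isfinite(pred)) or np.any(~np.isfinite(Y)) or np.any(~np.isfinite(w)):
        raise ValueError("NaN/inf in loss inputs")
    if pred.shape != Y.shape or w.shape[0] != pred.shape[0]:
        raise ValueError("shape mismatch between predictions, labels and weights")
    wsum = w.sum()
    if wsum == 0:
        return 0.0
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    per_tc = cw.w_pos * Y * (-np.log(p)) + cw.w_neg * (1.0 - Y) * (-np.log(1.0 - p))
    per_c = (w[:, None] * per_tc).sum(axis=0) / max(wsum, _EPS)
    return float(per_c.sum() / N_ADL)


def _loss_grad(pred: np.ndarray, Y: np.ndarray, w: np.ndarray, cw: ClassWeights) -> np.ndarray:
    """d(masked_balanced_bce)/d(pred) for one window."""
    wsum = w.sum()
    if wsum == 0:
        return np.zeros_like(pred)
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    g = (-cw.w_pos * Y / p + cw.w_neg * (1.0 - Y) / (1.0 - p)) * w[:, None]
    return g / (N_ADL * max(wsum, _EPS))


@dataclass
class _TrainWindow:
    X: np.ndarray   # (200, F)
    Yp: np.ndarray  # (100, 12) pooled labels
    wp: np.ndarray  # (100,) pooled weights


def _prepare_windows(
    windows: list[tuple[FeatureSequence, np.ndarray, np.ndarray]]
) -> list[_TrainWindow]:
    out = []
    for feats, Y, w in windows:
        Yp, wp = pool_labels_to_output_grid(Y, w)
        out.append(_TrainWindow(feats.matrix, Yp, wp))
    return out


def train_adl(
    model: AdlNetwork,
    windows: list[tuple[FeatureSequence, np.ndarray, np.ndarray]],
    cw: ClassWeights,
    epochs: int | None = None,
    batch_size: int | None = None,
    seed: int = 0,
) -> list[float]:
    """Fit on (features, 200×12 labels, 200 weights) windows; returns the
    per-epoch training-loss curve.  Deterministic given the seed."""
    cfg = model.cfg
    epochs = cfg.epochs if epochs is None else epochs
    batch_size = cfg.batch_size if batch_size is None else batch_size
    prepared = _prepare_windows(windows)
    if not prepared or all(tw.wp.sum() == 0 for tw in prepared):
        raise ValueError("all training windows are fully unlabeled")
    X = np.stack([tw.X for tw in prepared])
    Yp = np.stack([tw.Yp for tw in prepared])
    wp = np.stack([tw.wp for tw in prepared])
    n = len(prepared)
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate, l1=cfg.l1, l2=cfg.l2)
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            pred = model.forward(X[idx], train=True)
            batch_loss = 0.0
            grads = np.empty_like(pred)
            for b, i in enumerate(idx):
                batch_loss += masked_balanced_bce(pred[b], Yp[i], wp[i], cw)
                grads[b] = _loss_grad(pred[b], Yp[i], wp[i], cw)
            model.backward(grads / len(idx))
            opt.step()
            losses.append(batch_loss / len(idx))
        history.append(float(np.mean(losses)))
    return history


def predict_session(
    model: AdlNetwork,
    window_features: list[FeatureSequence],
    window_s: float = ADL_WINDOW_S,
    stride_s: float = ADL_STRIDE_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Run every window and average overlapping predictions.

    Returns (grid_times, probs) on the session-wide 6 s output grid; a time
    step covered by several windows (up to 5 for 10 min / 2 min) gets the
    arithmetic mean of their probabilities.
    """
    if not window_features:
        warnings.warn("session shorter than one window: empty prediction", stacklevel=2)
        return np.array([]), np.empty((0, N_ADL))
    out_step = window_s / OUTPUT_STEPS  # 6 s
    t_end = max(f.window_start for f in window_features) + window_s
    t0 = min(f.window_start for f in window_features)
    n_grid = int(round((t_end - t0) / out_step))
    acc = np.zeros((n_grid, N_ADL))
    cnt = np.zeros(n_grid)
    for feats in window_features:
        pred = model.predict(feats.matrix[None])[0]
        k0 = int(round((feats.window_start - t0) / out_step))
        acc[k0 : k0 + OUTPUT_STEPS] += pred
        cnt[k0 : k0 + OUTPUT_STEPS] += 1
    covered = cnt > 0
    acc[covered] /= cnt[covered, None]
    return t0 + out_step * np.arange(n_grid), acc


def hyperparam_search(
    windows: list[tuple[FeatureSequence, np.ndarray, np.ndarray]],
    cw: ClassWeights,
    folds: list[tuple[list[int], list[int]]],
    n_features: int,
    n_trials: int = 10,
    epochs: int = 20,
    seed: int = 0,
    space: dict | None = None,
) -> tuple[AdlNetConfig, list[dict]]:
    """Seeded random search minimizing mean validation loss across folds.

    ``folds`` holds (train indices, validation indices) into ``windows``.
    Returns the best config and the full trial log.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    space = space or {
        "lstm_units": (16, 256),        # log-uniform integers
        "dropout": (0.0, 0.5),
        "gauss_noise_std": (0.0, 0.5),
        "l1": (1e-7, 1e-2),             # log-uniform
        "l2": (1e-7, 1e-2),             # log-uniform
        "learning_rate": (1e-4, 1e-2),  # log-uniform
    }
    rng = np.random.default_rng(seed)
    trials: list[dict] = []
    best: tuple[float, AdlNetConfig] | None = None
    for trial in range(n_trials):
        params = {
            "lstm_units": int(round(np.exp(rng.uniform(*np.log(space["lstm_units"]))))),
            "dropout": float(rng.uniform(*space["dropout"])),
            "gauss_noise_std": float(rng.uniform(*space["gauss_noise_std"])),
            "l1": float(np.exp(rng.uniform(*np.log(space["l1"])))),
            "l2": float(np.exp(rng.uniform(*np.log(space["l2"])))),
            "learning_rate": float(np.exp(rng.uniform(*np.log(space["learning_rate"])))),
        }
        cfg = AdlNetConfig(**params)
        val_losses = []
        for f, (train_idx, val_idx) in enumerate(folds):
            model = AdlNetwork(cfg, n_features, seed=seed + trial)
            train_adl(model, [windows[i] for i in train_idx], cw,
                      epochs=epochs, batch_size=64, seed=seed + trial)
            fold_loss = 0.0
            for i in val_idx:
                feats, Y, w = windows[i]
                Yp, wp = pool_labels_to_output_grid(Y, w)
                fold_loss += masked_balanced_bce(model.predict(feats.matrix[None])[0], Yp, wp, cw)
            val_losses.append(fold_loss / max(len(val_idx), 1))
        mean_val = float(np.mean(val_losses))
        trials.append({"trial": trial, "params": params, "val_loss": mean_val})
        if best is None or mean_val < best[0]:
            best = (mean_val, cfg)
    return best[1], trials
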