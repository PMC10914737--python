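"""End-to-end glue: synthetic cohort -> features -> model -> evaluation.

Convenience layer used by the command-line interface and by the
demonstration workflows; each step is a thin call into the stage modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .adl_labels import DenseLabelSet, class_weights, clean_entries, densify
from .adl_model import (
    ADL_STRIDE_S,
    ADL_WINDOW_S,
    AdlNetConfig,
    AdlNetwork,
    pool_labels_to_output_grid,
    predict_session,
    train_adl,
)
from .evaluation import multilabel_report
from .features import FeatureSequence, assemble_features
from .synthetic import SyntheticSession, generate_cohort

__all__ = [
    "session_windows",
    "train_on_cohort",
    "evaluate_on_sessions",
]


def session_windows(
    session: SyntheticSession, preset: str, use_truth_labels: bool = True
) -> list[tuple[FeatureSequence, np.ndarray, np.ndarray]]:
    """Cut one session into (features, labels, weights) model windows.

    Features come from the oracle low-level probability stream plus the
    session's ambient/phone streams; labels are the cleaned self-reports
    (or the noiseless ground truth when ``use_truth_labels``).
    """
    bundle = session.bundle
    if use_truth_labels:
        dense = session.dense_truth
    else:
        dense = densify(clean_entries(bundle.adl_labels), bundle.duration)
    out = []
    start = 0.0
    steps = int(ADL_WINDOW_S / 3.0)
    while start + ADL_WINDOW_S <= bundle.duration + 1e-9:
        feats = assemble_features(bundle, session.lowlevel_probs_3s, preset, start)
        k0 = int(round(start / 3.0))
        Y = dense.Y[k0 : k0 + steps]
        w = dense.w[k0 : k0 + steps]
        if len(Y) == steps:
            out.append((feats, Y, w))
        start += ADL_STRIDE_S
    return out


def train_on_cohort(
    preset: str = "probs_location",
    n_participants: int = 12,
    n_test: int = 4,
    epochs: int = 30,
    seed: int = 0,
    use_lstm: bool = True,
    lstm_units: int = 32,
    learning_rate: float = 3e-3,
    cohort: list[SyntheticSession] | None = None,
) -> tuple[AdlNetwork, pd.DataFrame]:
    """Train on the first ``n - n_test`` synthetic participants and report
    mean/std metrics across the held-out ones."""
    cohort = cohort if cohort is not None else generate_cohort(n_participants, seed=seed)
    train_sessions = cohort[: len(cohort) - n_test]
    test_sessions = cohort[len(cohort) - n_test :]
    train_windows = [w for s in train_sessions for w in session_windows(s, preset)]
    Y_all = np.vstack([s.dense_truth.Y for s in train_sessions])
    w_all = np.concatenate([s.dense_truth.w for s in train_sessions])
    cw = class_weights(DenseLabelSet(0.0, 3.0, Y_all, w_all))
    n_features = train_windows[0][0].matrix.shape[1]
    cfg = AdlNetConfig(
        lstm_units=lstm_units, use_lstm=use_lstm, learning_rate=learning_rate
    )
    model = AdlNetwork(cfg, n_features, seed=seed)
    train_adl(model, train_windows, cw, epochs=epochs, batch_size=64, seed=seed)
    report = evaluate_on_sessions(model, test_sessions, preset)
    return model, report


def evaluate_on_sessions(
    model: AdlNetwork, sessions: list[SyntheticSession], preset: str,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Pooled per-class metric report over the given sessions' labeled time."""
    Ys, Ps = [], []
    for s in sessions:
        windows = session_windows(s, preset)
        feats = [w[0] for w in windows]
        _, probs = predict_session(model, feats)
        Yp, wp = pool_labels_to_output_grid(s.dense_truth.Y, s.dense_truth.w)
        n = min(len(probs), len(Yp))
        labeled = wp[:n] > 0
        Ys.append(Yp[:n][labeled])
        Ps.append(probs[:n][labeled])
    Y = np.vstack(Ys)
    P = np.vstack(Ps)
    return multilabel_report(Y, P, threshold)
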