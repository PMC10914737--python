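"""Multi-label evaluation: per-activity binary metrics, and the
prediction–label flattening that yields a joint 13×13 confusion matrix.

Per activity, predictions are binarized and compared with labels on
nonzero-weight (labeled) time steps only, giving precision, recall,
TPR/TNR, balanced accuracy = (TPR + TNR)/2, F1 and the binary log loss.

Because every time step may carry several labels and several predictions,
a joint confusion matrix needs the three-step flattening: exact matches
pair first, the remaining predictions and labels cross-pair in seeded
random order, and leftovers pair with a FALSE_NEGATIVE column (missed
labels) or FALSE_POSITIVE row (spurious predictions).  The pair count per
time step is max(#predictions, #labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adl_labels import ADL_CLASSES

__all__ = [
    "FALSE_NEGATIVE",
    "FALSE_POSITIVE",
    "BinaryCounts",
    "ClassMetrics",
    "per_class_metrics",
    "multilabel_report",
    "flatten_pairs",
    "accumulate_confusion",
    "confusion_from_dense",
    "aggregate_over_participants",
]

FALSE_NEGATIVE = "false negative"
FALSE_POSITIVE = "false positive"
_EPS = 1e-15


@dataclass(frozen=True)
class BinaryCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ClassMetrics:
    """Binary metrics of one activity; None marks undefined quantities."""

    counts: BinaryCounts
    precision: float | None
    recall: float | None  # = TPR
    tnr: float | None
    balanced_accuracy: float | None
    f1: float | None
    logloss: float


def _binary_counts(y: np.ndarray, yhat: np.ndarray) -> BinaryCounts:
    return BinaryCounts(
        tp=int(((y == 1) & (yhat == 1)).sum()),
        fp=int(((y == 0) & (yhat == 1)).sum()),
        fn=int(((y == 1) & (yhat == 0)).sum()),
        tn=int(((y == 0) & (yhat == 0)).sum()),
    )


def per_class_metrics(y: np.ndarray, p: np.ndarray, threshold: float = 0.5) -> ClassMetrics:
    """Binary metrics for one activity from labels and probabilities.

    Precision = TP/(TP+FP); Recall = TP/(TP+FN); balanced accuracy =
    (TPR+TNR)/2; log loss is the mean binary cross-entropy.  A side with no
    support reports None rather than 0.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    yhat = (p >= threshold).astype(float)
    c = _binary_counts(y, yhat)
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    tnr = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    bal = (recall + tnr) / 2.0 if recall is not None and tnr is not None else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    logloss = float(-(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)).mean())
    return ClassMetrics(c, precision, recall, tnr, bal, f1, logloss)


def multilabel_report(
    Y: np.ndarray, P: np.ndarray, threshold: float = 0.5,
    classes: tuple[str, ...] = ADL_CLASSES,
) -> pd.DataFrame:
    """Per-class metric table plus micro/macro aggregates.

    F1-micro pools TP/FP/FN across classes; F1-macro averages the
    per-class F1; balanced accuracy (multi-class sense) averages the
    per-class recalls.  Classes with no labeled positives are excluded
    from macro averages.
    """
    rows = {}
    counts = []
    for j, cname in enumerate(classes):
        m = per_class_metrics(Y[:, j], P[:, j], threshold)
        counts.append(m.counts)
        rows[cname] = {
            "logloss": m.logloss,
            "balanced_accuracy": m.balanced_accuracy,
            "f1": m.f1,
            "tpr": m.recall,
            "tnr": m.tnr,
            "precision": m.precision,
        }
    df = pd.DataFrame(rows).T
    tp = sum(c.tp for c in counts)
    fp = sum(c.fp for c in counts)
    fn = sum(c.fn for c in counts)
    micro_p = tp / (tp + fp) if (tp + fp) else np.nan
    micro_r = tp / (tp + fn) if (tp + fn) else np.nan
    f1_micro = (
        2 * micro_p * micro_r / (micro_p + micro_r)
        if np.isfinite(micro_p) and np.isfinite(micro_r) and (micro_p + micro_r) > 0
        else np.nan
    )
    agg = {
        "logloss": df["logloss"].mean(),
        "balanced_accuracy": df["balanced_accuracy"].dropna().mean(),
        "f1": df["f1"].dropna().mean(),  # F1-macro
        "tpr": df["tpr"].dropna().mean(),
        "tnr": df["tnr"].dropna().mean(),
        "precision": df["precision"].dropna().mean(),
    }
    df.loc["macro"] = agg
    df.loc["micro", "f1"] = f1_micro
    return df


def flatten_pairs(
    preds: set[str], labels: set[str], rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Three-step matching of one time step's prediction and label sets.

    Returns (label_side, pred_side) pairs; count = max(|preds|, |labels|).
    Step 1 pairs exact matches; step 2 cross-pairs the remainder in seeded
    random order; step 3 pairs leftovers with sentinels.
    """
    preds = set(preds)
    labels = set(labels)
    pairs = [(a, a) for a in sorted(preds & labels)]
    rest_p = sorted(preds - labels)
    rest_l = sorted(labels - preds)
    rng.shuffle(rest_p)
    rng.shuffle(rest_l)
    k = min(len(rest_p), len(rest_l))
    pairs += list(zip(rest_l[:k], rest_p[:k]))
    pairs += [(lab, FALSE_NEGATIVE) for lab in rest_l[k:]]
    pairs += [(FALSE_POSITIVE, pr) for pr in rest_p[k:]]
    return pairs


def accumulate_confusion(pairs) -> pd.DataFrame:
    """13×13 joint confusion: rows = labels + FALSE_POSITIVE row, columns =
    predictions + FALSE_NEGATIVE column."""
    rows = list(ADL_CLASSES) + [FALSE_POSITIVE]
    cols = list(ADL_CLASSES) + [FALSE_NEGATIVE]
    mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for label_side, pred_side in pairs:
        mat.loc[label_side, pred_side] += 1
    return mat


def confusion_from_dense(
    Y: np.ndarray, P: np.ndarray, w: np.ndarray, threshold: float = 0.5, seed: int = 0,
    classes: tuple[str, ...] = ADL_CLASSES,
) -> pd.DataFrame:
    """Flatten every labeled time step and accumulate the joint matrix."""
    rng = np.random.default_rng(seed)
    yhat = P >= threshold
    pairs = []
    for t in np.flatnonzero(w > 0):
        preds = {classes[j] for j in np.flatnonzero(yhat[t])}
        labels = {classes[j] for j in np.flatnonzero(Y[t] > 0)}
        pairs.extend(flatten_pairs(preds, labels, rng))
    return accumulate_confusion(pairs)


def aggregate_over_participants(reports: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean ± std of each metric cell across participants.

    Cells a participant reports as NaN (e.g. a class without positives) are
    excluded from that cell's mean; the std is the population standard
    deviation over the participants contributing to the cell.
    """
    if len(reports) < 2:
        raise ValueError("need >= 2 participant reports to aggregate")
    stacked = pd.concat(reports, keys=range(len(reports)))
    mean = stacked.groupby(level=1, sort=False).mean()
    std = stacked.groupby(level=1, sort=False).std(ddof=0)
    out = pd.concat({"mean": mean, "std": std}, axis=1)
    return out.loc[reports[0].index]
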