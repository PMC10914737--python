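import numpy as np
import pytest

from adlsense.adl_labels import ADL_CLASSES
from adlsense.evaluation import (
    FALSE_NEGATIVE,
    FALSE_POSITIVE,
    accumulate_confusion,
    aggregate_over_participants,
    confusion_from_dense,
    flatten_pairs,
    multilabel_report,
    per_class_metrics,
)


# ---- literal transcriptions of the printed metric formulas (oracle) ----

def _precision(tp, fp):
    return tp / (tp + fp)


def _recall(tp, fn):
    return tp / (tp + fn)


def _f1(p, r):
    return 2 * (p * r) / (p + r)


def _logloss_binary(y, p):
    total = 0.0
    for yi, pi in zip(y, p):
        pi = min(max(pi, 1e-15), 1 - 1e-15)
        total += yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
    return -total / len(y)


class TestPerClassMetrics:
    def test_perfect_prediction(self):
        y = np.array([1, 0, 1, 0])
        p = np.array([0.99, 0.01, 0.99, 0.01])
        m = per_class_metrics(y, p)
        assert m.precision == 1.0 and m.recall == 1.0
        assert m.logloss < 0.05

    def test_hand_counts(self):
        # TP=3, FP=1, FN=2 -> precision 0.75, recall 0.6
        y = np.array([1, 1, 1, 1, 1, 0, 0])
        p = np.array([1, 1, 1, 0, 0, 1, 0], dtype=float)
        m = per_class_metrics(y, p)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)

    def test_logloss_ln2(self):
        m = per_class_metrics(np.array([1, 0]), np.array([0.5, 0.5]))
        assert m.logloss == pytest.approx(np.log(2))

    def test_no_positives_reports_missing_not_zero(self):
        m = per_class_metrics(np.zeros(5), np.zeros(5))
        assert m.recall is None
        assert m.balanced_accuracy is None

    def test_agrees_with_literal_formulas(self, rng):
        """1000 random inputs vs the transcribed formulas, 1e-12."""
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            y = (rng.random(n) < 0.5).astype(float)
            p = rng.random(n)
            m = per_class_metrics(y, p)
            yhat = (p >= 0.5).astype(float)
            tp = int(((y == 1) & (yhat == 1)).sum())
            fp = int(((y == 0) & (yhat == 1)).sum())
            fn = int(((y == 1) & (yhat == 0)).sum())
            tn = int(((y == 0) & (yhat == 0)).sum())
            if tp + fp:
                assert abs(m.precision - _precision(tp, fp)) < 1e-12
            if tp + fn:
                assert abs(m.recall - _recall(tp, fn)) < 1e-12
            if (tp + fn) and (tn + fp):
                bal = (_recall(tp, fn) + tn / (tn + fp)) / 2
                assert abs(m.balanced_accuracy - bal) < 1e-12
            if (tp + fp) and (tp + fn) and (tp > 0):
                f1 = _f1(_precision(tp, fp), _recall(tp, fn))
                assert abs(m.f1 - f1) < 1e-12
            assert abs(m.logloss - _logloss_binary(y, p)) < 1e-12
            assert m.counts.total == n


class TestFlattenPairs:
    def test_worked_example_more_labels(self, rng):
        labels = {"watching tv", "toileting", "organizing", "other"}
        preds = {"watching tv", "using phone", "room transition"}
        pairs = flatten_pairs(preds, labels, rng)
        assert len(pairs) == 4  # max(3, 4)
        assert ("watching tv", "watching tv") in pairs
        fn_pairs = [p for p in pairs if p[1] == FALSE_NEGATIVE]
        assert len(fn_pairs) == 1  # one unmatched label remains
        cross = [p for p in pairs if p[0] != p[1] and FALSE_NEGATIVE not in p]
        assert len(cross) == 2
        assert {c[1] for c in cross} == {"using phone", "room transition"}

    def test_worked_example_more_predictions(self, rng):
        pairs = flatten_pairs({"watching tv", "other"}, {"watching tv"}, rng)
        assert ("watching tv", "watching tv") in pairs
        assert (FALSE_POSITIVE, "other") in pairs

    def test_empty_sets(self, rng):
        assert flatten_pairs(set(), set(), rng) == []

    def test_single_exact_match(self, rng):
        assert flatten_pairs({"eating"}, {"eating"}, rng) == [("eating", "eating")]

    def test_count_is_max_of_cardinalities(self, rng):
        """10,000 random set pairs; oracle = max of the set sizes."""
        for _ in range(10000):
            preds = set(rng.choice(ADL_CLASSES, size=rng.integers(0, 5), replace=False))
            labels = set(rng.choice(ADL_CLASSES, size=rng.integers(0, 5), replace=False))
            pairs = flatten_pairs(preds, labels, rng)
            assert len(pairs) == max(len(preds), len(labels))
            # every common ADL appears in exactly one exact-match pair
            for a in preds & labels:
                assert pairs.count((a, a)) == 1

    def test_randomness_never_touches_diagonal_or_sentinels(self):
        preds = {"eating", "walking", "using phone", "other"}
        labels = {"eating", "toileting", "showering"}
        results = []
        for seed in range(100):
            pairs = flatten_pairs(preds, labels, np.random.default_rng(seed))
            diag = sorted(p for p in pairs if p[0] == p[1])
            n_fp = sum(1 for p in pairs if p[0] == FALSE_POSITIVE)
            n_fn = sum(1 for p in pairs if p[1] == FALSE_NEGATIVE)
            results.append((tuple(diag), n_fp, n_fn))
        assert len(set(results)) == 1


class TestConfusion:
    def test_diagonal_increment(self, rng):
        mat = accumulate_confusion([("eating", "eating")])
        assert mat.loc["eating", "eating"] == 1
        assert mat.to_numpy().sum() == 1

    def test_sentinel_margins(self, rng):
        mat = accumulate_confusion([("other", FALSE_NEGATIVE), (FALSE_POSITIVE, "eating")])
        assert mat.loc["other", FALSE_NEGATIVE] == 1
        assert mat.loc[FALSE_POSITIVE, "eating"] == 1

    def test_total_equals_sum_of_max_cardinalities(self, rng):
        T = 50
        Y = (rng.random((T, 12)) < 0.2).astype(float)
        P = rng.random((T, 12))
        w = np.ones(T)
        mat = confusion_from_dense(Y, P, w, threshold=0.5, seed=0)
        yhat = P >= 0.5
        expected = sum(
            max(int(yhat[t].sum()), int(Y[t].sum())) for t in range(T)
        )
        assert mat.to_numpy().sum() == expected

    def test_shape_is_13_by_13(self, rng):
        mat = accumulate_confusion([])
        assert mat.shape == (13, 13)


class TestAggregate:
    def _report(self, value):
        import pandas as pd

        return pd.DataFrame({"balanced_accuracy": [value]}, index=["eating"])

    def test_identical_reports_have_zero_std(self):
        out = aggregate_over_participants([self._report(0.7)] * 3)
        assert out[("std", "balanced_accuracy")].iloc[0] == 0.0

    def test_mean_of_two(self):
        out = aggregate_over_participants([self._report(0.6), self._report(0.8)])
        assert out[("mean", "balanced_accuracy")].iloc[0] == pytest.approx(0.7)

    def test_missing_cell_excluded_from_mean(self):
        out = aggregate_over_participants(
            [self._report(np.nan), self._report(0.8), self._report(0.6)]
        )
        assert out[("mean", "balanced_accuracy")].iloc[0] == pytest.approx(0.7)

    def test_single_report_rejected(self):
        with pytest.raises(ValueError):
            aggregate_over_participants([self._report(0.5)])


def test_multilabel_report_has_macro_and_micro(rng):
    Y = (rng.random((100, 12)) < 0.3).astype(float)
    P = rng.random((100, 12))
    rep = multilabel_report(Y, P)
    assert "macro" in rep.index and "micro" in rep.index
    assert 0 <= rep.loc["micro", "f1"] <= 1
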