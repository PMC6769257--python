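"""Metrics: confusion matrices, one-vs-rest reductions, windowed CS recall,
ROC — each checked against independent brute-force oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef, precision_score, recall_score

from tpsort.evaluation import (ConfusionMatrix, binary_counts,
                               classification_report, confusion, cs_recall,
                               precision_recall_f1_mcc, roc_auc, roc_points)
from tpsort.model import Prediction
from tpsort.sequence_io import CLASSES, ProteinRecord


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        cm = confusion(list(CLASSES), list(CLASSES))
        np.testing.assert_array_equal(cm.counts, np.eye(5, dtype=int))

    def test_orientation_rows_predicted(self):
        cm = confusion(["mTP"], ["SP"])
        assert cm.counts[2, 1] == 1 and cm.counts.sum() == 1

    def test_row_sums_are_predicted_counts(self):
        rng = np.random.default_rng(0)
        pred = [CLASSES[i] for i in rng.integers(5, size=200)]
        true = [CLASSES[i] for i in rng.integers(5, size=200)]
        cm = confusion(pred, true)
        for k, c in enumerate(CLASSES):
            assert cm.counts[k].sum() == pred.count(c)

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError):
            confusion(["bogus"], ["SP"])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            confusion(["SP"], ["SP", "SP"])


class TestBinaryCounts:
    def test_identity_matrix(self):
        cm = ConfusionMatrix(np.eye(5, dtype=int))
        for c in CLASSES:
            assert binary_counts(cm, c) == (1, 4, 0, 0)

    def test_single_confusion(self):
        cm = confusion(["mTP"], ["SP"])
        tp, tn, fp, fn = binary_counts(cm, "SP")
        assert (tp, fn) == (0, 1)

    def test_counts_partition_total(self):
        rng = np.random.default_rng(1)
        cm = ConfusionMatrix(rng.integers(0, 20, size=(5, 5)))
        for c in CLASSES:
            assert sum(binary_counts(cm, c)) == cm.total


class TestMetricFormulas:
    def test_precision_directly(self):
        p, _, _, _ = precision_recall_f1_mcc(3, 0, 1, 0)
        assert p == 0.75

    def test_perfect_classifier_mcc(self):
        assert precision_recall_f1_mcc(5, 5, 0, 0)[3] == 1.0

    def test_zero_denominators_give_zero(self):
        assert precision_recall_f1_mcc(0, 10, 0, 0) == (0.0, 0.0, 0.0, 0.0)

    def test_swap_fp_fn_swaps_precision_recall(self):
        p1, r1, _, m1 = precision_recall_f1_mcc(7, 9, 2, 5)
        p2, r2, _, m2 = precision_recall_f1_mcc(7, 9, 5, 2)
        assert (p1, r1) == (r2, p2)
        assert m1 == m2  # the MCC formula is symmetric under the swap

    def test_random_tuples_match_exact_rational_oracle(self):
        """200 random (tp, tn, fp, fn) tuples against an independent
        implementation using exact rational arithmetic, to 1e-12."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 50, size=4))
            p, r, f1, mcc = precision_recall_f1_mcc(tp, tn, fp, fn)
            ep = Fraction(tp, tp + fp) if tp + fp else Fraction(0)
            er = Fraction(tp, tp + fn) if tp + fn else Fraction(0)
            ef = 2 * ep * er / (ep + er) if ep + er else Fraction(0)
            d = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
            em = (tp * tn - fp * fn) / math.sqrt(d) if d else 0.0
            assert abs(p - ep) < 1e-12 and abs(r - er) < 1e-12
            assert abs(f1 - ef) < 1e-12 and abs(mcc - em) < 1e-12

    def test_against_sklearn_on_label_vectors(self):
        rng = np.random.default_rng(3)
        true = rng.integers(2, size=300)
        pred = rng.integers(2, size=300)
        tp = int(np.sum((pred == 1) & (true == 1)))
        tn = int(np.sum((pred == 0) & (true == 0)))
        fp = int(np.sum((pred == 1) & (true == 0)))
        fn = int(np.sum((pred == 0) & (true == 1)))
        p, r, _, mcc = precision_recall_f1_mcc(tp, tn, fp, fn)
        assert p == pytest.approx(precision_score(true, pred), abs=1e-12)
        assert r == pytest.approx(recall_score(true, pred), abs=1e-12)
        assert mcc == pytest.approx(matthews_corrcoef(true, pred), abs=1e-10)

    def test_independence_gives_zero_mcc(self):
        # balanced constructed example: predictions carry no information
        assert precision_recall_f1_mcc(25, 25, 25, 25)[3] == 0.0

    def test_mcc_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            mcc = precision_recall_f1_mcc(*(int(x) for x in
                                            rng.integers(0, 30, size=4)))[3]
            assert -1.0 <= mcc <= 1.0


def _fake_prediction(rid, cls, cs, length=60):
    k = CLASSES.index(cls)
    probs = np.full(5, 0.05)
    probs[k] = 0.8
    cs_probs = np.full((4, length), 1e-6)
    if cls != "noTP":
        cs_probs[k - 1, cs - 1] = 1.0
    att = np.vstack([cs_probs, np.full((1, length), 1.0 / length)])
    return Prediction(id=rid, class_probs=probs, cs_probs=cs_probs, attention=att)


class TestCSRecall:
    def _records(self):
        return [ProteinRecord(id=f"r{i}", sequence="M" + "A" * 59,
                              label="SP", cs=20) for i in range(4)]

    def test_exact_prediction_window_zero(self):
        recs = self._records()
        preds = {r.id: _fake_prediction(r.id, "SP", 20) for r in recs}
        assert cs_recall(preds, recs, 0)["SP"] == 1.0

    def test_shift_counts_only_at_wide_window(self):
        recs = self._records()
        preds = {r.id: _fake_prediction(r.id, "SP", 23) for r in recs}
        assert cs_recall(preds, recs, 2)["SP"] == 0.0
        assert cs_recall(preds, recs, 3)["SP"] == 1.0

    def test_misclassified_records_excluded(self):
        recs = self._records()
        preds = {r.id: _fake_prediction(r.id, "mTP", 20) for r in recs}
        # classified as mTP: not in the SP denominator at all
        assert cs_recall(preds, recs, 5)["SP"] == 0.0

    def test_monotone_in_window_over_random_sets(self):
        """Windowed recall is non-decreasing in the window width."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            recs = [ProteinRecord(id=f"q{i}", sequence="M" + "A" * 58,
                                  label=CLASSES[rng.integers(1, 5)],
                                  cs=int(rng.integers(5, 40)))
                    for i in range(20)]
            preds = {}
            for r in recs:
                cls = CLASSES[rng.integers(5)]
                preds[r.id] = _fake_prediction(r.id, cls,
                                               int(rng.integers(5, 40)))
            recalls = [cs_recall(preds, recs, w) for w in range(6)]
            for c in ("SP", "mTP", "cTP", "luTP"):
                vals = [recalls[w][c] for w in range(6)]
                assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


class TestROC:
    def test_perfect_separation_auc_one(self):
        pts = roc_points([0.9, 0.8, 0.2, 0.1], ["SP", "SP", "noTP", "noTP"], "SP")
        assert roc_auc(pts) == 1.0
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_constant_scores_diagonal(self):
        pts = roc_points([0.5] * 6, ["SP"] * 3 + ["noTP"] * 3, "SP")
        assert roc_auc(pts) == pytest.approx(0.5)

    def test_single_class_truth_raises(self):
        with pytest.raises(ValueError):
            roc_points([0.5, 0.4], ["SP", "SP"], "SP")

    def test_auc_matches_brute_force_oracle(self):
        """AUC equals the Mann-Whitney pair-counting statistic on 50 random
        score sets, to 1e-12."""
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            labels = ["SP" if rng.random() < 0.4 else "noTP" for _ in range(n)]
            if len(set(labels)) < 2:
                continue
            scores = rng.random(n).round(2)  # ties included
            auc = roc_auc(roc_points(scores, labels, "SP"))
            pos = [s for s, l in zip(scores, labels) if l == "SP"]
            neg = [s for s, l in zip(scores, labels) if l != "SP"]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert abs(auc - wins / (len(pos) * len(neg))) < 1e-12


def test_report_f1_is_harmonic_mean_and_macro():
    rng = np.random.default_rng(7)
    cm = ConfusionMatrix(rng.integers(0, 30, size=(5, 5)))
    report = classification_report(cm)
    f1s = []
    for c in CLASSES:
        m = report.per_class[c]
        if m["precision"] and m["recall"]:
            h = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
            assert m["f1"] == pytest.approx(h, abs=1e-12)
        f1s.append(m["f1"])
    assert report.macro_f1 == pytest.approx(np.mean(f1s))
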