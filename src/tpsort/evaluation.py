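"""Classification and cleavage-site metrics.

The confusion matrix convention throughout is rows = predicted class,
columns = observed class, in the fixed order (noTP, SP, mTP, cTP, luTP).
Per-class precision, recall, F1 and Matthews correlation are computed from
the one-vs-rest reduction:

    precision = tp / (tp + fp)              recall = tp / (tp + fn)
    F1 = 2 * precision * recall / (precision + recall)
    MCC = (tp*tn - fp*fn) / sqrt((tp+fn)(tp+fp)(tn+fp)(tn+fn))

with every zero-denominator case defined as 0.  Cleavage-site recall is
computed only over records whose class was predicted correctly, as the
fraction whose predicted site lies within +/- ``window`` residues of the
annotated site.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .model import Prediction
from .sequence_io import CLASSES, CLASS_INDEX, CS_CLASSES, ProteinRecord


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (5, 5) ints, rows predicted, columns observed

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (5, 5) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 5x5 non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts, index=[f"pred_{c}" for c in CLASSES],
                     columns=[f"obs_{c}" for c in CLASSES]).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        return cls(pd.read_csv(path, index_col=0).to_numpy())


def confusion(pred_classes: Sequence[str], true_classes: Sequence[str]) -> ConfusionMatrix:
    if len(pred_classes) != len(true_classes):
        raise ValueError("label vectors differ in length")
    counts = np.zeros((5, 5), dtype=np.int64)
    for p, t in zip(pred_classes, true_classes):
        if p not in CLASS_INDEX or t not in CLASS_INDEX:
            raise ValueError(f"unknown label in ({p!r}, {t!r})")
        counts[CLASS_INDEX[p], CLASS_INDEX[t]] += 1
    return ConfusionMatrix(counts)


def binary_counts(cm: ConfusionMatrix, cls: str) -> Tuple[int, int, int, int]:
    """One-vs-rest (tp, tn, fp, fn) for ``cls``."""
    k = CLASS_INDEX[cls]
    tp = int(cm.counts[k, k])
    fp = int(cm.counts[k].sum() - tp)
    fn = int(cm.counts[:, k].sum() - tp)
    tn = cm.total - tp - fp - fn
    return tp, tn, fp, fn


def precision_recall_f1_mcc(tp: int, tn: int, fp: int, fn: int
                            ) -> Tuple[float, float, float, float]:
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return precision, recall, f1, mcc


@dataclass
class MetricsReport:
    per_class: Dict[str, Dict[str, float]]
    cs_recall: Dict[str, Dict[int, float]] = field(default_factory=dict)

    @property
    def macro_f1(self) -> float:
        return float(np.mean([m["f1"] for m in self.per_class.values()]))

    def to_json(self, path) -> None:
        payload = {
            "per_class": self.per_class,
            "macro_f1": self.macro_f1,
            "cs_recall": {c: {str(w): v for w, v in d.items()}
                          for c, d in self.cs_recall.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_table(self) -> str:
        lines = [f"{'class':>6} {'precision':>9} {'recall':>7} {'F1':>6} {'MCC':>6}"]
        for c in CLASSES:
            m = self.per_class[c]
            lines.append(f"{c:>6} {m['precision']:9.3f} {m['recall']:7.3f} "
                         f"{m['f1']:6.3f} {m['mcc']:6.3f}")
        lines.append(f"macro-F1 {self.macro_f1:.3f}")
        return "\n".join(lines)


def classification_report(cm: ConfusionMatrix) -> MetricsReport:
    per_class = {}
    for c in CLASSES:
        p, r, f1, mcc = precision_recall_f1_mcc(*binary_counts(cm, c))
        per_class[c] = {"precision": p, "recall": r, "f1": f1, "mcc": mcc}
    return MetricsReport(per_class=per_class)


def cs_recall(predictions: Dict[str, Prediction],
              records: Sequence[ProteinRecord], window: int) -> Dict[str, float]:
    """Windowed cleavage-site recall per positive class.

    Only records of class c that were also classified as c enter the
    denominator; a record counts as recovered when
    ``|pred_cs - true cs| <= window``.
    """
    if not (0 <= window <= 5):
        raise ValueError("window must lie in [0, 5]")
    hits = {c: 0 for c in CS_CLASSES}
    totals = {c: 0 for c in CS_CLASSES}
    for r in records:
        if r.label not in CS_CLASSES or r.id not in predictions:
            continue
        p = predictions[r.id]
        if p.pred_class != r.label:
            continue
        totals[r.label] += 1
        if p.pred_cs is not None and abs(p.pred_cs - r.cs) <= window:
            hits[r.label] += 1
    return {c: (hits[c] / totals[c] if totals[c] else 0.0) for c in CS_CLASSES}


def cs_recall_table(predictions: Dict[str, Prediction],
                    records: Sequence[ProteinRecord]) -> Dict[str, Dict[int, float]]:
    return {c: {} for c in CS_CLASSES} | {
        c: {w: cs_recall(predictions, records, w)[c] for w in range(6)}
        for c in CS_CLASSES
    }


def roc_points(scores: Sequence[float], true_labels: Sequence[str], cls: str
               ) -> List[Tuple[float, float]]:
    """One-vs-rest ROC curve for ``cls`` from per-record scores in [0, 1]."""
    y = np.array([1 if t == cls else 0 for t in true_labels])
    if y.min() == y.max():
        raise ValueError("ROC needs both positive and negative records")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    pts = list(zip(fpr.tolist(), tpr.tolist()))
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def roc_auc(points: Sequence[Tuple[float, float]]) -> float:
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    return float(np.trapezoid(tpr, fpr))
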