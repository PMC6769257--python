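"""Confusion-matrix count correction for proteome-scale annotation.

Raw predicted per-class counts are biased by class-to-class misprediction.
With a labelled evaluation set one can estimate, for each predicted class k,
the distribution of true classes P(true = c | predicted = k) by row-normalising
the (predicted x observed) confusion matrix.  Each predicted pool is then
redistributed accordingly:

    corrected[c] = sum_k n[k] * P[k][c]

which subtracts the estimated false predictions from a class and adds back the
members estimated to have been mispredicted into other classes.  The total
count is conserved exactly, and when P is estimated on the same labelled set
whose predicted counts are corrected, the true per-class counts are recovered
exactly.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np

from .evaluation import ConfusionMatrix
from .sequence_io import CLASSES


def misprediction_fractions(cm: ConfusionMatrix) -> np.ndarray:
    """Row-stochastic 5x5 matrix P with P[k, c] = P(true=c | predicted=k).

    A predicted class with no members yields an identity row (nothing to
    redistribute) and a warning.
    """
    counts = cm.counts.astype(float)
    P = np.eye(len(CLASSES))
    for k, row in enumerate(counts):
        total = row.sum()
        if total == 0:
            warnings.warn(f"no records predicted as {CLASSES[k]}; "
                          "row left as identity", stacklevel=2)
            continue
        P[k] = row / total
    return P


def correct_counts(predicted_counts: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Redistribute predicted per-class counts through P (see module doc)."""
    n = np.asarray(predicted_counts, dtype=float)
    if n.shape != (len(CLASSES),):
        raise ValueError(f"expected {len(CLASSES)} counts")
    if (n < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError("P must be row-stochastic")
    return n @ P
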