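"""Threshold metrics shared by the classifier and the evaluation module."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC-ROC by the Mann-Whitney rank statistic with tie midranks.

    Equals the probability that a random positive outranks a random negative,
    counting ties as half.  Returns NaN when only one class is present.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def accuracy_f1(labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5):
    """Accuracy and positive-class F1 at a probability threshold."""
    y = np.asarray(labels).astype(int)
    pred = (np.asarray(scores, dtype=float) > threshold).astype(int)
    acc = float(np.mean(pred == y))
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return acc, float(f1)
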