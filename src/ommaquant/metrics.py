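"""Evaluation statistics computed from confusion matrices and class
probabilities: exact binomial accuracy intervals, Cohen's kappa, and the
Hand–Till multiclass pairwise AUC with its ROC curves."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class ConfusionMatrix:
    """Predicted x reference counts: ``counts[i, j]`` is the number of items
    predicted as class ``i`` whose reference label is class ``j``."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K classes")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(pred, truth, class_order) -> ConfusionMatrix:
    """Tabulate predictions (rows) against reference labels (columns)."""
    pred, truth = list(pred), list(truth)
    if len(pred) != len(truth):
        raise ValueError("pred and truth must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order),) * 2, dtype=np.int64)
    for p, t in zip(pred, truth):
        if p not in index or t not in index:
            raise ValueError(f"unknown label in ({p!r}, {t!r})")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(counts, tuple(class_order))


def accuracy_with_ci(cm: ConfusionMatrix, level: float = 0.95):
    """Global accuracy with an exact (Clopper–Pearson) binomial interval.

    With s successes out of n, the bounds are beta quantiles:
    lower = B(alpha/2; s, n-s+1), upper = B(1-alpha/2; s+1, n-s), with the
    conventional endpoints 0 at s = 0 and 1 at s = n.
    """
    n = cm.total
    if n < 1:
        raise ValueError("empty confusion matrix")
    s = int(np.trace(cm.counts))
    alpha = 1.0 - level
    lower = 0.0 if s == 0 else float(beta.ppf(alpha / 2, s, n - s + 1))
    upper = 1.0 if s == n else float(beta.ppf(1 - alpha / 2, s + 1, n - s))
    return s / n, lower, upper


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement: kappa = (po - pe) / (1 - pe), with
    po = trace/n and pe the product of matching marginals."""
    n = cm.total
    if n < 1:
        raise ValueError("empty confusion matrix")
    po = np.trace(cm.counts) / n
    pe = float(cm.counts.sum(axis=1) @ cm.counts.sum(axis=0)) / n ** 2
    if pe >= 1.0 - 1e-15:
        raise ValueError("kappa undefined: expected agreement pe = 1 "
                         "(all mass in a single class)")
    return float((po - pe) / (1.0 - pe))


def _rank_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    # Mann–Whitney AUC with ties counted 1/2, via midranks
    ranks = rankdata(np.concatenate([scores_pos, scores_neg]))
    n_pos, n_neg = len(scores_pos), len(scores_neg)
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def hand_till_mauc(probs: np.ndarray, truth, class_order) -> float:
    """Hand–Till multiclass AUC: the mean over unordered class pairs (i, j)
    of A(i, j) = [A(i|j) + A(j|i)] / 2, where A(i|j) is the rank-based AUC
    of the class-i probability separating class-i from class-j items.

    Pairs with an empty side are skipped; it is an error if every pair is
    skipped (fewer than two classes present).
    """
    probs = np.asarray(probs, dtype=np.float64)
    truth = np.asarray(list(truth))
    aucs = []
    for i, ci in enumerate(class_order):
        for j in range(i + 1, len(class_order)):
            cj = class_order[j]
            mi, mj = truth == ci, truth == cj
            if not mi.any() or not mj.any():
                continue
            a_ij = _rank_auc(probs[mi, i], probs[mj, i])
            a_ji = _rank_auc(probs[mj, j], probs[mi, j])
            aucs.append((a_ij + a_ji) / 2.0)
    if not aucs:
        raise ValueError("Hand–Till AUC needs at least two classes present in truth")
    return float(np.mean(aucs))


def pairwise_roc(probs: np.ndarray, truth, pair, class_order):
    """ROC of the first class's probability restricted to items of the two
    classes in ``pair``.  Returns (fpr, tpr, area); the trapezoidal area
    equals the rank-based A(i|j) used by :func:`hand_till_mauc`."""
    probs = np.asarray(probs, dtype=np.float64)
    truth = np.asarray(list(truth))
    ci, cj = pair
    i = list(class_order).index(ci)
    mask = (truth == ci) | (truth == cj)
    y = (truth[mask] == ci).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"both classes of pair {pair} must be present")
    fpr, tpr, _ = _sk_roc_curve(y, probs[mask, i], drop_intermediate=False)
    area = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, area


def pairwise_auc_table(probs: np.ndarray, truth, class_order) -> np.ndarray:
    """Symmetric K x K table of pairwise Hand–Till AUCs (NaN where a class
    is absent; diagonal NaN)."""
    probs = np.asarray(probs, dtype=np.float64)
    truth = np.asarray(list(truth))
    k = len(class_order)
    table = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            mi, mj = truth == class_order[i], truth == class_order[j]
            if not mi.any() or not mj.any():
                continue
            a_ij = _rank_auc(probs[mi, i], probs[mj, i])
            a_ji = _rank_auc(probs[mj, j], probs[mi, j])
            table[i, j] = table[j, i] = (a_ij + a_ji) / 2.0
    return table
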