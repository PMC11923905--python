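"""Metrics, cross-validation and paired comparisons.

AUC uses the rank (Mann-Whitney) statistic with ties counted 1/2; AUPR is
the step-interpolated precision-recall area; threshold metrics come from
the confusion matrix at logit threshold 0 (the score > 0 decision rule),
with precision/F1 defined as 0 when nothing is predicted positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score


@dataclass
class MetricReport:
    auc: float
    aupr: float
    accuracy: float
    f1: float
    precision: float
    recall: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> Dict[str, float]:
        return {k: getattr(self, k) for k in
                ("auc", "aupr", "accuracy", "f1", "precision", "recall",
                 "specificity", "tp", "fp", "tn", "fn")}


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via mid-ranks: ties between a positive and a negative count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(scores: Sequence[float], labels: Sequence[int],
                    threshold: float = 0.0) -> MetricReport:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels length mismatch")
    pred = scores > threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    tn = int(np.sum(~pred & ~pos))
    fn = int(np.sum(~pred & pos))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    specificity = tn / (tn + fp) if tn + fp > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return MetricReport(
        auc=rank_auc(scores, labels),
        aupr=float(average_precision_score(labels, scores)),
        accuracy=(tp + tn) / len(labels),
        f1=f1, precision=precision, recall=recall, specificity=specificity,
        tp=tp, fp=fp, tn=tn, fn=fn)


def kfold_cv(X: np.ndarray, y: np.ndarray,
             fit_score: Callable[[np.ndarray, np.ndarray, np.ndarray, int], np.ndarray],
             k: int = 5, seed: int = 0,
             threshold: float = 0.0) -> Tuple[List[MetricReport], Dict[str, Tuple[float, float]]]:
    """K-fold cross-validation with disjoint folds of near-equal size.

    ``fit_score(X_train, y_train, X_val, fold_seed)`` must return validation
    scores; any balancing (e.g. SMOTE) belongs inside it, so it touches the
    training fold only.
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    folds = np.array_split(order, k)
    reports = []
    for i, val_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        scores = fit_score(X[train_idx], y[train_idx], X[val_idx], seed + i)
        reports.append(compute_metrics(scores, y[val_idx], threshold))
    summary = {}
    for name in ("auc", "aupr", "accuracy", "f1", "precision", "recall", "specificity"):
        vals = np.array([getattr(r, name) for r in reports])
        summary[name] = (float(vals.mean()), float(vals.std(ddof=1)) if k > 1 else 0.0)
    return reports, summary


def paired_test(a_scores: Sequence[float], b_scores: Sequence[float],
                test: str = "sign", alternative: str = "greater") -> float:
    """Paired comparison of per-item scores; null: no systematic difference.

    sign: exact binomial on strict wins of a over b (ties dropped).
    wilcoxon: signed-rank, exact null for n <= 25, normal approximation beyond.
    """
    a = np.asarray(a_scores, dtype=float)
    b = np.asarray(b_scores, dtype=float)
    if a.shape != b.shape or len(a) < 5:
        raise ValueError("paired_test needs equal-length vectors of >= 5 scores")
    if test == "sign":
        wins = int(np.sum(a > b))
        losses = int(np.sum(a < b))
        n = wins + losses
        if n == 0:
            return 1.0
        return float(stats.binomtest(wins, n, 0.5, alternative=alternative).pvalue)
    if test == "wilcoxon":
        d = a - b
        d = d[d != 0]
        if len(d) == 0:
            return 1.0
        mode = "exact" if len(d) <= 25 else "approx"
        return float(stats.wilcoxon(d, alternative=alternative, mode=mode).pvalue)
    raise ValueError(f"unknown test {test!r}")
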