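"""Classification metrics, stratified cross-validation, and fold summaries.

Implements the standard confusion-matrix metrics — accuracy, precision,
recall, F1, Matthews correlation coefficient and Cohen's kappa — with the
usual one-vs-rest reduction for the five severity grades, plus rank-based
AUROC (Mann-Whitney, ties counted 1/2), step-integrated AUPRC, stratified
5-fold assignment with a 90/10 inner train/validation split, and
Student-t fold summaries (mean, sample SD, 95% CI half-width).

Zero-denominator conventions: precision and recall with an empty
denominator are 0; an MCC with a zero denominator is 0.  These only arise
on degenerate folds and are the standard safe choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix", "FoldAssignment", "confusion", "binary_metrics",
    "multiclass_metrics", "auroc_auprc", "stratified_kfold", "fold_summary",
]

N_CLASSES = 5

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "mcc", "kappa")


@dataclass(frozen=True)
class ConfusionMatrix:
    """5x5 count matrix; rows are true grades, columns predicted grades."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"expected a {N_CLASSES}x{N_CLASSES} matrix")
        if (counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for class ``cls`` against the rest."""
        c = self.counts
        tp = int(c[cls, cls])
        fn = int(c[cls].sum() - tp)
        fp = int(c[:, cls].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn


def confusion(labels, predictions) -> ConfusionMatrix:
    """Count matrix with rows = true class, columns = predicted class."""
    labels = np.asarray(labels, dtype=np.int64)
    predictions = np.asarray(predictions, dtype=np.int64)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    for arr, name in ((labels, "labels"), (predictions, "predictions")):
        if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
            raise ValueError(f"{name} must lie in 0..{N_CLASSES - 1}")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (labels, predictions), 1)
    return ConfusionMatrix(counts)


def binary_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """The six confusion-matrix metrics of a binary problem.

    Kappa uses observed agreement Po = (TP+TN)/n against the
    marginal-product expected agreement Pe.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    po = accuracy
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n ** 2
    kappa = (po - pe) / (1.0 - pe) if pe != 1.0 else 0.0
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "f1": f1, "mcc": float(mcc), "kappa": kappa}


def multiclass_kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa of the full matrix with marginal-product Pe."""
    c = cm.counts
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(c) / n
    pe = float(c.sum(axis=1) @ c.sum(axis=0)) / n ** 2
    return (po - pe) / (1.0 - pe) if pe != 1.0 else 0.0


def multiclass_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class one-vs-rest metrics plus an unweighted macro row.

    The frame's ``attrs`` carry ``overall_accuracy`` (trace / total) and
    ``multiclass_kappa`` computed from the full 5x5 matrix.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    rows = {}
    for cls in range(N_CLASSES):
        rows[cls] = binary_metrics(*cm.one_vs_rest(cls))
    table = pd.DataFrame(rows).T
    table.loc["macro"] = table.mean(axis=0)
    table.attrs["overall_accuracy"] = float(np.trace(cm.counts) / cm.total)
    table.attrs["multiclass_kappa"] = multiclass_kappa(cm)
    return table


def _auroc_rank(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Mann-Whitney AUROC; tied pairs count 1/2."""
    scores = np.concatenate([pos_scores, neg_scores])
    ranks = stats.rankdata(scores)  # average ranks handle ties
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def _auprc_step(labels01: np.ndarray, scores: np.ndarray) -> float:
    """Step-wise precision-recall integration (sum of dRecall * precision)."""
    order = np.argsort(-scores, kind="stable")
    y = labels01[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    precision = tp / np.maximum(tp + fp, 1)
    recall = tp / tp[-1]
    # merge tied-score runs: only the last point of each run is attainable
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    precision, recall = precision[distinct], recall[distinct]
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def auroc_auprc(labels, scores) -> pd.DataFrame:
    """One-vs-rest AUROC and AUPRC per class from an ``(n, 5)`` score matrix.

    A class absent from ``labels`` is reported as NaN with ``defined=False``
    rather than 0.
    """
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != N_CLASSES:
        raise ValueError(f"scores must be (n, {N_CLASSES})")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    rows = []
    for cls in range(N_CLASSES):
        mask = labels == cls
        if not mask.any() or mask.all():
            rows.append({"auroc": np.nan, "auprc": np.nan, "defined": False})
            continue
        s = scores[:, cls]
        rows.append({
            "auroc": _auroc_rank(s[mask], s[~mask]),
            "auprc": _auprc_step(mask.astype(float), s),
            "defined": True,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified k-fold assignment with an inner train/validation split.

    ``test_fold[i]`` is the fold in which sample ``i`` is tested;
    ``splits[f]`` holds the ``(train_idx, val_idx, test_idx)`` index arrays
    of fold ``f``.  Every sample is tested exactly once, the three roles are
    disjoint within a fold, and per-class test proportions track the global
    proportions to within one sample.
    """

    test_fold: np.ndarray
    splits: tuple[tuple[np.ndarray, np.ndarray, np.ndarray], ...]

    @property
    def k(self) -> int:
        return len(self.splits)


def stratified_kfold(labels, k: int = 5, val_fraction: float = 0.1,
                     seed: int = 0) -> FoldAssignment:
    """Stratified k folds with a stratified 90/10 inner train/val split.

    Per class, shuffled members are dealt round-robin to folds (rotating the
    starting fold per class to balance sizes).  In each fold iteration the
    non-test samples are split per class into train and validation, with
    ``val_fraction`` (rounded, at least 1 where the class has >= 2
    non-test members) going to validation.
    """
    labels = np.asarray(labels, dtype=np.int64)
    rng = np.random.default_rng(seed)
    present = np.unique(labels)
    for cls in present:
        count = int((labels == cls).sum())
        if count < k:
            raise ValueError(
                f"class {cls} has only {count} samples; needs >= {k} for "
                f"{k}-fold stratification")

    test_fold = np.empty(len(labels), dtype=np.int64)
    for j, cls in enumerate(present):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        offset = j % k
        test_fold[idx] = (np.arange(len(idx)) + offset) % k

    splits = []
    for f in range(k):
        test_idx = np.flatnonzero(test_fold == f)
        rest = np.flatnonzero(test_fold != f)
        val_parts, train_parts = [], []
        for cls in present:
            cls_rest = rng.permutation(rest[labels[rest] == cls])
            n_val = int(round(val_fraction * len(cls_rest)))
            if len(cls_rest) >= 2:
                n_val = max(1, min(n_val, len(cls_rest) - 1))
            val_parts.append(cls_rest[:n_val])
            train_parts.append(cls_rest[n_val:])
        splits.append((np.sort(np.concatenate(train_parts)),
                       np.sort(np.concatenate(val_parts)),
                       np.sort(test_idx)))
    return FoldAssignment(test_fold=test_fold, splits=tuple(splits))


def fold_summary(values) -> dict[str, float]:
    """Mean, sample SD and Student-t 95% CI half-width across folds."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("fold summary needs at least 2 folds")
    k = values.size
    sd = values.std(ddof=1)
    half = stats.t.ppf(0.975, k - 1) * sd / np.sqrt(k)
    return {"mean": float(values.mean()), "sd": float(sd),
            "ci95_half_width": float(half)}
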