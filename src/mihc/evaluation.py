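"""Balanced leave-a-percent-out evaluation with ROC/AUC.

For each class, n% of its positive genes and an equal number of negative
genes form the (balanced) training set; everything else is the test set.
The grid of n runs from 10% to 90% and each cell is repeated with fresh
random splits.  Performance is summarised by the per-class AUC — the
probability that the classifier scores a random positive above a random
negative — plus TPR/FPR at the classifier's operating threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import classifiers as clf_mod
from .expression import TimeCourseMatrix
from .systems import LearningSystem

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "RocResult",
    "balanced_split",
    "confusion",
    "roc_auc",
    "run_protocol",
    "summarize_protocol",
]


class ClassTooSmallError(ValueError):
    """A class with fewer than 2 positives cannot be split."""


class UndefinedAucError(ValueError):
    """AUC is undefined when only one class is present in the truth."""


@dataclass
class SplitSpec:
    """Balanced train/test split for one class."""

    train_pos: np.ndarray
    train_neg: np.ndarray
    test: np.ndarray
    n_percent: float
    seed: object

    @property
    def train(self) -> np.ndarray:
        return np.concatenate([self.train_pos, self.train_neg])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def balanced_split(Y: np.ndarray, class_idx: int, n_percent: float, seed) -> SplitSpec:
    """Sample a balanced training set for one class.

    The number of training positives is ``round(n_percent * P)`` (half-up)
    clamped to ``[1, P - 1]``, so both the training and the test set always
    contain a positive; the same number of negatives is drawn uniformly
    without replacement.  With P = 49 and n = 10%..90% this yields the
    5, 10, 15, 20, 25, 29, 34, 39, 44 training-positive ladder of a
    49-positive class.  Deterministic given ``seed``.

    Raises
    ------
    ClassTooSmallError
        If the class has fewer than 2 positives or fewer negatives than
        the requested number of training positives.
    """
    if not 0 < n_percent < 1:
        raise ValueError("n_percent must be in (0, 1)")
    Y = np.atleast_2d(np.asarray(Y, dtype=int))
    pos = np.nonzero(Y[:, class_idx] == 1)[0]
    neg = np.nonzero(Y[:, class_idx] == 0)[0]
    P = len(pos)
    if P < 2:
        raise ClassTooSmallError(f"class {class_idx} has {P} positive(s); need >= 2")
    n_train = min(max(_round_half_up(n_percent * P), 1), P - 1)
    if len(neg) < n_train:
        raise ClassTooSmallError(
            f"class {class_idx} has {len(neg)} negatives; need >= {n_train}"
        )
    rng = np.random.default_rng(seed)
    train_pos = np.sort(rng.choice(pos, size=n_train, replace=False))
    train_neg = np.sort(rng.choice(neg, size=n_train, replace=False))
    in_train = np.zeros(Y.shape[0], dtype=bool)
    in_train[train_pos] = True
    in_train[train_neg] = True
    test = np.nonzero(~in_train)[0]
    return SplitSpec(train_pos=train_pos, train_neg=train_neg, test=test,
                     n_percent=n_percent, seed=seed)


def confusion(y_true, y_pred) -> tuple[int, int, int, int]:
    """Counts (TP, FP, TN, FN); TPR = TP/(TP+FN), FPR = FP/(FP+TN)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return tp, fp, tn, fn


@dataclass
class RocResult:
    """ROC sweep and rank AUC for one class."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores, y_true) -> RocResult:
    """Rank-based AUC with a threshold-sweep ROC curve.

    The AUC is the Mann-Whitney statistic (ties counted 1/2); the ROC
    points come from sweeping every distinct score threshold, and their
    trapezoidal area equals the rank AUC to numerical precision.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    if scores.shape != y_true.shape:
        raise ValueError("length mismatch")
    P = int((y_true == 1).sum())
    N = int((y_true == 0).sum())
    if P == 0 or N == 0:
        raise UndefinedAucError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)
    auc = float((ranks[y_true == 1].sum() - P * (P + 1) / 2) / (P * N))
    order = np.argsort(-scores, kind="stable")
    sorted_true = y_true[order]
    sorted_scores = scores[order]
    # indices where a threshold group ends (distinct score values)
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    cut = np.concatenate([distinct, [len(scores) - 1]])
    tps = np.cumsum(sorted_true)[cut]
    fps = np.cumsum(1 - sorted_true)[cut]
    tpr = np.concatenate([[0.0], tps / P])
    fpr = np.concatenate([[0.0], fps / N])
    thresholds = np.concatenate([[np.inf], sorted_scores[cut]])
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def _class_seed(master: int, n_idx: int, rep: int, class_idx: int):
    """Deterministic per-(grid point, repetition, class) RNG stream."""
    return [int(master) & 0x7FFFFFFF, n_idx, rep, class_idx]


def run_protocol(
    system: LearningSystem,
    expr: TimeCourseMatrix,
    clf: str = "mlsvm",
    n_grid=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    reps: int = 20,
    seed: int = 0,
    C: float = 1.0,
    k: int = 5,
) -> pd.DataFrame:
    """Run the balanced leave-a-percent-out protocol for one system.

    For every grid fraction ``n`` and repetition, each class gets its own
    balanced split; the classifier (``"mlsvm"`` or ``"mlknn"``) is trained
    on that class's training set and scored on the held-out genes.  Too
    small classes are skipped with a warning.

    Returns a tidy DataFrame with one row per (n, rep, class): the AUC and
    the confusion counts / TPR / FPR at the classifier's operating point
    (decision value 0 for MLSVM, the similarity-mass majority rule for
    MLKNN).
    """
    if clf not in ("mlsvm", "mlknn"):
        raise ValueError(f"unknown classifier {clf!r}")
    X = expr.subset(system.gene_ids).values
    Y = system.label_matrix
    rows = []
    for n_idx, n in enumerate(n_grid):
        for rep in range(reps):
            for c in range(Y.shape[1]):
                try:
                    split = balanced_split(Y, c, n, _class_seed(seed, n_idx, rep, c))
                except ClassTooSmallError as exc:
                    if n_idx == 0 and rep == 0:
                        logger.warning("run_protocol: %s; class skipped", exc)
                    continue
                train = split.train
                y_train = Y[train, c]
                y_test = Y[split.test, c]
                if y_test.sum() == 0 or y_test.sum() == len(y_test):
                    continue
                if clf == "mlsvm":
                    model = clf_mod.train_mlsvm(X[train], y_train[:, None], C=C)
                    scores = clf_mod.predict_scores(model, X[split.test])[:, 0]
                    y_pred = (scores > 0).astype(int)
                else:
                    kk = min(k, len(train))
                    model = clf_mod.train_mlknn(X[train], y_train[:, None], k=kk)
                    S, L = clf_mod.knn_predict(model, X[split.test])
                    scores, y_pred = S[:, 0], L[:, 0]
                roc = roc_auc(scores, y_test)
                tp, fp, tn, fn = confusion(y_test, y_pred)
                rows.append({
                    "n_percent": n, "rep": rep, "class": c,
                    "class_label": system.classes[c].label,
                    "auc": roc.auc, "tp": tp, "fp": fp, "tn": tn, "fn": fn,
                    "tpr": tp / (tp + fn), "fpr": fp / (fp + tn),
                })
    return pd.DataFrame(rows)


def summarize_protocol(detail: pd.DataFrame, pool: bool = False) -> pd.DataFrame:
    """Mean AUC / TPR / FPR per grid fraction.

    Default averages per class first and then across classes and
    repetitions (macro); ``pool=True`` pools all (class, repetition)
    cells directly.  The two coincide when no cell is missing.
    """
    if detail.empty:
        return pd.DataFrame(columns=["n_percent", "auc", "tpr", "fpr"])
    if pool:
        out = detail.groupby("n_percent")[["auc", "tpr", "fpr"]].mean()
    else:
        per_class = detail.groupby(["n_percent", "class"])[["auc", "tpr", "fpr"]].mean()
        out = per_class.groupby("n_percent").mean()
    return out.reset_index()
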