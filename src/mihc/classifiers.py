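"""Multi-label classifiers over a learning system's label matrix.

MLSVM is a binary-relevance soft-margin SVM with a per-sample loss
amplification that counters class imbalance: positives of a class carry a
hinge-loss weight of N_neg/N_pos so that the few positives are not
swamped by the many negatives.  MLKNN scores a test profile's candidate
classes by summing the similarity of its k nearest training profiles that
belong to the class, similarity being rescaled Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "MlsvmModel",
    "train_mlsvm",
    "predict_scores",
    "MlknnModel",
    "train_mlknn",
    "knn_candidates",
    "knn_scores",
    "knn_labels",
    "knn_predict",
]

SKIPPED_SCORE = -np.inf


# ---------------------------------------------------------------------------
# MLSVM
# ---------------------------------------------------------------------------

@dataclass
class MlsvmModel:
    """One trained SVM per class (binary relevance)."""

    estimators: list  # SVC or None for skipped classes
    skipped: set
    n_features: int
    C: float
    kernel: str


def _amplification(y: np.ndarray, amplify: bool) -> np.ndarray:
    """Per-sample hinge-loss weights: N_neg/N_pos on positives, 1 on negatives."""
    w = np.ones(len(y), dtype=float)
    if amplify:
        n_pos = int(y.sum())
        n_neg = len(y) - n_pos
        w[y == 1] = n_neg / n_pos
    return w


def train_mlsvm(
    X: np.ndarray,
    Y: np.ndarray,
    C: float = 1.0,
    kernel: str = "rbf",
    gamma="auto",
    amplify: bool = True,
) -> MlsvmModel:
    """Train one weighted soft-margin SVM per class.

    ``gamma="auto"`` is an RBF bandwidth of 1/n_features.  A class with no
    positive or no negative training sample is skipped with a warning; its
    score column is filled with a sentinel minimum at prediction time.
    With ``amplify=False`` all loss weights are 1 (the unweighted SVM).
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=int))
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y must be row-aligned")
    if C <= 0:
        raise ValueError("C must be positive")
    estimators: list = []
    skipped: set = set()
    for j in range(Y.shape[1]):
        y = Y[:, j]
        if y.sum() == 0 or y.sum() == len(y):
            logger.warning("mlsvm: class %d has a single label value; skipped", j)
            estimators.append(None)
            skipped.add(j)
            continue
        clf = SVC(C=C, kernel=kernel, gamma=gamma)
        clf.fit(X, y, sample_weight=_amplification(y, amplify))
        estimators.append(clf)
    return MlsvmModel(
        estimators=estimators, skipped=skipped, n_features=X.shape[1], C=C, kernel=kernel
    )


def predict_scores(model: MlsvmModel, X: np.ndarray) -> np.ndarray:
    """Continuous decision values, samples x classes (threshold 0 for labels).

    Skipped classes are filled with ``SKIPPED_SCORE`` (-inf) and recorded
    in ``model.skipped``.
    """
    X = np.asarray(X, dtype=float)
    if X.size and X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training ({model.n_features})"
        )
    n = X.shape[0] if X.ndim == 2 else 0
    out = np.full((n, len(model.estimators)), SKIPPED_SCORE, dtype=float)
    if n == 0:
        return out
    for j, clf in enumerate(model.estimators):
        if clf is not None:
            out[:, j] = clf.decision_function(X)
    return out


# ---------------------------------------------------------------------------
# MLKNN
# ---------------------------------------------------------------------------

def _similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Rescaled Pearson correlation in [0, 1]; 0 if undefined (constant)."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return (1.0 + max(-1.0, min(1.0, r))) / 2.0


@dataclass
class MlknnModel:
    """Stored training set for correlation-based multi-label KNN."""

    X: np.ndarray
    Y: np.ndarray
    k: int = 5

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=int))
        if self.Y.shape[0] != self.X.shape[0]:
            raise ValueError("X and Y must be row-aligned")
        if not 1 <= self.k <= self.X.shape[0]:
            raise ValueError(f"k must be in [1, {self.X.shape[0]}]")

    def neighbors(self, x: np.ndarray) -> np.ndarray:
        """Indices of the k nearest training samples under 1 - Pearson r,
        ties broken by sample index (stable sort)."""
        sims = np.array([_similarity(x, row) for row in self.X])
        dists = 1.0 - 2.0 * sims + 1.0  # = 1 - r, monotone in similarity
        order = np.argsort(dists, kind="stable")
        return order[: self.k]


def train_mlknn(X: np.ndarray, Y: np.ndarray, k: int = 5) -> MlknnModel:
    return MlknnModel(X=X, Y=Y, k=k)


def knn_candidates(x: np.ndarray, model: MlknnModel) -> set[int]:
    """Union of the label sets of x's k nearest training samples."""
    nbrs = model.neighbors(np.asarray(x, dtype=float))
    return set(np.nonzero(model.Y[nbrs].any(axis=0))[0].tolist())


def knn_scores(x: np.ndarray, model: MlknnModel) -> dict[int, float]:
    """Similarity-mass likelihood per candidate class.

    ``score(c)`` sums, over the k nearest neighbours that belong to class
    c, the similarity ``(1 + pearson_r)/2``; non-candidate classes score 0.
    """
    x = np.asarray(x, dtype=float)
    nbrs = model.neighbors(x)
    sims = np.array([_similarity(x, model.X[i]) for i in nbrs])
    scores: dict[int, float] = {}
    for c in range(model.Y.shape[1]):
        mask = model.Y[nbrs, c] == 1
        if mask.any():
            scores[c] = float(sims[mask].sum())
    return scores


def knn_labels(scores: dict[int, float], total_mass: float) -> set[int]:
    """Classes holding a strict majority of the neighbour similarity mass."""
    return {c for c, s in scores.items() if s > total_mass / 2.0}


def knn_predict(model: MlknnModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batch scores and binary labels for a test matrix.

    Returns ``(scores, labels)`` of shape samples x classes; scores of
    non-candidate classes are 0.
    """
    X = np.asarray(X, dtype=float)
    n_classes = model.Y.shape[1]
    S = np.zeros((X.shape[0], n_classes), dtype=float)
    L = np.zeros((X.shape[0], n_classes), dtype=int)
    for i, x in enumerate(X):
        nbrs = model.neighbors(x)
        sims = np.array([_similarity(x, model.X[j]) for j in nbrs])
        total = float(sims.sum())
        sc = knn_scores(x, model)
        for c, s in sc.items():
            S[i, c] = s
        for c in knn_labels(sc, total):
            L[i, c] = 1
    return S, L
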