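"""k-nearest-neighbour classification over the 6-D power features.

Instance-based: a query is assigned the modal class among its k nearest
training points under the Euclidean metric, with deterministic tie
rules. k is chosen by stratified n-fold cross-validation over a
candidate list, preferring the smallest k at equal error (the least
complex model). No feature scaling is applied before distance
computation; the differing numeric ranges of accelerometer- and
gyroscope-power features are accepted as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .features import N_FEATURES, extract_features
from .signals import CLASS_ORDER, MotionClass, ParameterError, SignalWindow

__all__ = [
    "TrainingSet",
    "DEFAULT_K_CANDIDATES",
    "euclidean_distance",
    "knn_classify",
    "select_k",
]

#: Default k candidates: odd 1..15. Odd values reduce (but cannot
#: eliminate) voting ties among the six classes.
DEFAULT_K_CANDIDATES = tuple(range(1, 16, 2))


@dataclass(frozen=True)
class TrainingSet:
    """Labelled feature vectors backing both classifiers.

    ``X`` is an (n, 6) float array of power features; ``y`` is the
    matching tuple of :class:`MotionClass` labels. Must be non-empty.
    """

    X: np.ndarray
    y: tuple[MotionClass, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", tuple(self.y))
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ParameterError(f"X must be (n, {N_FEATURES}), got shape {X.shape}")
        if X.shape[0] == 0:
            raise ParameterError("training set must be non-empty")
        if len(self.y) != X.shape[0]:
            raise ParameterError("X and y lengths differ")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> tuple[MotionClass, ...]:
        """Distinct classes present, in enumeration order."""
        present = set(self.y)
        return tuple(c for c in MotionClass if c in present)

    @classmethod
    def from_corpus(
        cls, corpus: Iterable[tuple[SignalWindow, Optional[MotionClass]]]
    ) -> "TrainingSet":
        """Extract features from labelled recordings; unlabelled ones are rejected."""
        X, y = [], []
        for w, label in corpus:
            if label is None:
                raise ParameterError("training corpus contains an unlabelled recording")
            X.append(extract_features(w))
            y.append(label)
        if not X:
            raise ParameterError("training corpus is empty")
        return cls(np.asarray(X), tuple(y))


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance between two 6-D feature vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != (N_FEATURES,) or y.shape != (N_FEATURES,):
        raise ParameterError(
            f"feature vectors must have shape ({N_FEATURES},), got {x.shape} and {y.shape}"
        )
    return float(np.sqrt(np.sum((x - y) ** 2)))


def _vote(distances: np.ndarray, y: Sequence[MotionClass], k: int) -> MotionClass:
    # Distance-tie expansion: everything at the k-th smallest distance votes.
    kth = np.partition(distances, k - 1)[k - 1]
    voters = np.flatnonzero(distances <= kth)
    votes: dict[MotionClass, int] = {}
    dist_sum: dict[MotionClass, float] = {}
    for i in voters:
        c = y[i]
        votes[c] = votes.get(c, 0) + 1
        dist_sum[c] = dist_sum.get(c, 0.0) + float(distances[i])
    # Majority class; ties by smallest summed neighbour distance, then
    # by enumeration order.
    return min(votes, key=lambda c: (-votes[c], dist_sum[c], CLASS_ORDER[c]))


def knn_classify(train: TrainingSet, x: np.ndarray, k: int) -> MotionClass:
    """Classify a feature vector as the modal class of its k nearest neighbours.

    Ties at the k-th distance expand the electorate to every point at
    that distance; a tied vote goes to the class with the smallest
    summed neighbour distance, then to the class earlier in the
    :class:`MotionClass` enumeration.
    """
    k = int(k)
    if not 1 <= k <= len(train):
        raise ParameterError(f"k must be in [1, {len(train)}], got {k}")
    x = np.asarray(x, dtype=float)
    if x.shape != (N_FEATURES,):
        raise ParameterError(f"query must have shape ({N_FEATURES},), got {x.shape}")
    distances = np.sqrt(np.sum((train.X - x) ** 2, axis=1))
    return _vote(distances, train.y, k)


def _stratified_folds(
    y: Sequence[MotionClass], n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Deal each class's (shuffled) indices round-robin into n_folds folds."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in MotionClass:
        idx = np.flatnonzero(np.asarray([yi is c for yi in y]))
        if idx.size == 0:
            continue
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[j % n_folds].append(int(i))
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def select_k(
    train: TrainingSet,
    n_folds: int = 5,
    candidates: Sequence[int] = DEFAULT_K_CANDIDATES,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Choose k by stratified n-fold cross-validation.

    For each candidate k, the mean misclassification fraction over
    n_folds leave-one-fold-out rounds is computed; the candidate with
    the lowest error wins, smallest k on ties. Folds are stratified by
    class using the given seed, so repeated calls are reproducible.

    Returns ``(best_k, cv_error)`` with ``cv_error`` mapping every
    candidate to its error in [0, 1].
    """
    candidates = [int(k) for k in candidates]
    if not candidates:
        raise ParameterError("candidate list must be non-empty")
    if any(k < 1 for k in candidates):
        raise ParameterError("all k candidates must be positive")
    n_folds = int(n_folds)
    if not 2 <= n_folds <= len(train):
        raise ParameterError(
            f"n_folds must be in [2, {len(train)}], got {n_folds}"
        )
    rng = np.random.default_rng(seed)
    folds = [f for f in _stratified_folds(train.y, n_folds, rng) if f.size > 0]
    min_train_size = len(train) - max(f.size for f in folds)
    if max(candidates) > min_train_size:
        raise ParameterError(
            f"candidate k={max(candidates)} exceeds the smallest training-fold "
            f"size {min_train_size}"
        )

    errors = {k: 0.0 for k in candidates}
    for fold in folds:
        mask = np.ones(len(train), dtype=bool)
        mask[fold] = False
        sub = TrainingSet(train.X[mask], tuple(np.asarray(train.y, dtype=object)[mask]))
        for k in candidates:
            wrong = sum(
                knn_classify(sub, train.X[i], k) is not train.y[i] for i in fold
            )
            errors[k] += wrong / fold.size
    cv_error = {k: errors[k] / len(folds) for k in candidates}
    best_k = min(candidates, key=lambda k: (cv_error[k], k))
    return best_k, cv_error
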