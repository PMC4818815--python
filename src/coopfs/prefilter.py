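"""Phase 1: normalization and univariate feature reduction.

Each feature is scored individually (Fisher ratio or mutual information with
the class) and the top-k survive to the game-theoretic phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import info_theory
from .errors import ClassTooSmallError, TooFewClassesError
from .io import ExpressionDataset

__all__ = [
    "FISHER_CAP",
    "FeatureScoreVector",
    "zscore_normalize",
    "fisher_ratio",
    "fisher_ratio_vector",
    "mi_relevance",
    "rank_and_trim",
]

# Finite stand-in for the zero-within-class-variance / separated-means case,
# so downstream utility multiplication stays finite.
FISHER_CAP = 1e12


@dataclass
class FeatureScoreVector:
    """Per-feature univariate scores plus the induced ranking.

    ``ranking`` sorts by descending score, ties broken by ascending feature
    index, and is always a permutation of 0..n_features-1.
    """

    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if not np.all(np.isfinite(self.scores)) or (self.scores < 0).any():
            raise ValueError("scores must be finite and >= 0")
        if self.method not in ("fisher", "mutual_information", "mi"):
            raise ValueError(f"unknown scoring method: {self.method!r}")
        n = self.scores.size
        self.ranking = np.lexsort((np.arange(n), -self.scores))


def zscore_normalize(data: ExpressionDataset, enabled: bool = True) -> ExpressionDataset:
    """Standardize each feature column to mean 0, population sd 1.

    Zero-variance columns become all-zero.  With ``enabled=False`` the
    dataset is returned unchanged.
    """
    if not enabled:
        return data
    mean = data.matrix.mean(axis=0)
    sd = data.matrix.std(axis=0)  # population (ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    matrix = (data.matrix - mean) / safe
    matrix[:, sd == 0] = 0.0
    return ExpressionDataset(matrix, data.labels, data.feature_ids, data.sample_ids)


def _class_stats(labels: np.ndarray):
    classes, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    if classes.size < 2:
        raise TooFewClassesError("need at least 2 classes")
    if counts.min() < 2:
        raise ClassTooSmallError("every class needs at least 2 samples")
    return classes, inverse, counts


def fisher_ratio(feature, labels) -> float:
    """Interclass-to-intraclass variability ratio of a single feature.

    Two classes: (mean1 - mean2)^2 / (var1 + var2) with population variances.
    More classes: mean of the two-class score over all unordered class pairs.
    Zero denominator yields 0 for equal means and the finite cap otherwise.
    """
    return float(fisher_ratio_vector(np.asarray(feature, dtype=np.float64)[:, None], labels)[0])


def fisher_ratio_vector(matrix: np.ndarray, labels) -> np.ndarray:
    """Fisher ratio of every column of a samples x features matrix."""
    classes, inverse, counts = _class_stats(np.asarray(labels))
    n_classes = classes.size
    n_features = matrix.shape[1]
    means = np.empty((n_classes, n_features))
    variances = np.empty((n_classes, n_features))
    for c in range(n_classes):
        block = matrix[inverse == c]
        means[c] = block.mean(axis=0)
        variances[c] = block.var(axis=0)  # population (ddof=0)

    total = np.zeros(n_features)
    n_pairs = 0
    for a in range(n_classes):
        for b in range(a + 1, n_classes):
            num = (means[a] - means[b]) ** 2
            den = variances[a] + variances[b]
            pair = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.where(num > 0, FISHER_CAP, 0.0))
            total += pair
            n_pairs += 1
    return np.minimum(total / n_pairs, FISHER_CAP)


def mi_relevance(feature, labels, bins: int = 5) -> float:
    """MI (bits) between the equal-frequency-discretized feature and the class."""
    f = info_theory.discretize(np.asarray(feature, dtype=np.float64), bins)
    return info_theory.mutual_information(f, info_theory.from_labels(labels))


def rank_and_trim(
    data: ExpressionDataset, method: str = "fisher", k: int = 300, bins: int = 5
) -> tuple[ExpressionDataset, FeatureScoreVector]:
    """Keep the k best-scoring features (descending score, ties by index).

    Returns the trimmed dataset with columns in rank order, plus the full
    score vector; the surviving original indices are ``scores.ranking[:k]``.
    """
    if not 1 <= k <= data.n_features:
        raise ValueError(f"k={k} out of range [1, {data.n_features}]")
    if method == "fisher":
        scores = fisher_ratio_vector(data.matrix, data.labels)
    elif method in ("mi", "mutual_information"):
        cls = info_theory.from_labels(data.labels)
        scores = np.array(
            [
                info_theory.mutual_information(info_theory.discretize(col, bins), cls)
                for col in data.matrix.T
            ]
        )
    else:
        raise ValueError(f"unknown prefilter method: {method!r}")
    vec = FeatureScoreVector(scores, "mutual_information" if method == "mi" else method)
    kept = vec.ranking[:k]
    return data.subset_features(kept), vec
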