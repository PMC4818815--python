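"""Phase 2: per-feature Shapley weights from coalition payoffs.

Features are players in a cooperative game.  The payoff of adding feature i
to a coalition K is binary: 1 iff i does not decrease K's class relevance
(mean CMI-minus-QMI change >= 0) and i is interdependent with at least half
of K's members.  The Shapley value of feature i sums this payoff over all
coalitions of a fixed size with the classical combinatorial weight
k!(n-k-1)!/n!, which bounds every weight by 1/n.

All information-theoretic quantities are resolved from a precomputed
:class:`PairwiseCache`; nothing is re-estimated inside the coalition loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .info_theory import (
    DiscretizedFeature,
    UtilitySpec,
    mutual_information,
)

__all__ = [
    "PairwiseCache",
    "ShapleyWeights",
    "build_pairwise_cache",
    "interdependence_index",
    "set_relevance",
    "relevance_change",
    "coalition_payoff",
    "shapley_value",
    "weights_from_cache",
    "compute_all_weights",
]


@dataclass
class PairwiseCache:
    """Cached class-relevance quantities driving every coalition payoff.

    ``qmi_class[j]``   = QMI(f_j; class) under the configured utility.
    ``cmi_given[i, j]`` = CMI(f_j; class | f_i) in bits (diagonal unused).
    """

    qmi_class: np.ndarray
    cmi_given: np.ndarray
    utilities: Sequence[UtilitySpec] | None = None

    def __post_init__(self) -> None:
        self.qmi_class = np.asarray(self.qmi_class, dtype=np.float64)
        self.cmi_given = np.asarray(self.cmi_given, dtype=np.float64)
        n = self.qmi_class.size
        if self.cmi_given.shape != (n, n):
            raise ValueError("cmi_given must be n x n")
        if not (np.all(np.isfinite(self.qmi_class)) and np.all(np.isfinite(self.cmi_given))):
            raise ValueError("cache entries must be finite")
        if (self.qmi_class < 0).any() or (self.cmi_given < 0).any():
            raise ValueError("cache entries must be >= 0")

    @property
    def n_features(self) -> int:
        return self.qmi_class.size


@dataclass
class ShapleyWeights:
    """Shapley value per feature for a fixed coalition size."""

    phi: np.ndarray
    coalition_size: int
    n_features: int

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=np.float64)
        if self.phi.shape != (self.n_features,):
            raise ValueError("phi length must equal n_features")
        if (self.phi < 0).any() or (self.phi > 1).any():
            raise ValueError("phi must lie in [0, 1]")


def _cmi_profile(
    code_matrix: np.ndarray, n_bins: int, cond: np.ndarray, cond_bins: int,
    cls: np.ndarray, n_cls: int,
) -> np.ndarray:
    """CMI(f_j; class | cond) for every column j of ``code_matrix`` at once.

    Builds one (n_features, cond_bins, n_bins, n_cls) count tensor and
    evaluates the plug-in sum vectorized; identical (to round-off) to calling
    conditional_mutual_information per column.
    """
    n_samples, n_features = code_matrix.shape
    cell = (cond[:, None].astype(np.int64) * n_bins + code_matrix) * n_cls + cls[:, None]
    cell += np.arange(n_features, dtype=np.int64) * (cond_bins * n_bins * n_cls)
    counts = np.bincount(cell.ravel(), minlength=n_features * cond_bins * n_bins * n_cls)
    p = counts.reshape(n_features, cond_bins, n_bins, n_cls) / n_samples
    pz = p.sum(axis=(2, 3), keepdims=True)
    pxz = p.sum(axis=3, keepdims=True)
    pyz = p.sum(axis=2, keepdims=True)
    mask = p > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mask, p * pz / np.where(mask, pxz * pyz, 1.0), 1.0)
        terms = np.where(mask, p * np.log2(ratio), 0.0)
    return np.maximum(terms.sum(axis=(1, 2, 3)), 0.0)


def build_pairwise_cache(
    features: Sequence[DiscretizedFeature],
    cls: DiscretizedFeature,
    utility: Sequence[UtilitySpec] | UtilitySpec,
) -> PairwiseCache:
    """Precompute QMI(f_j; class) and CMI(f_j; class | f_i) for all i, j.

    ``utility`` may be a single spec applied to every feature or one spec per
    feature (the Fisher-ratio utility differs per feature).
    """
    n = len(features)
    if n < 2:
        raise ValueError("need at least 2 features")
    if isinstance(utility, UtilitySpec):
        utilities = [utility] * n
    else:
        utilities = list(utility)
        if len(utilities) != n:
            raise ValueError("one UtilitySpec per feature required")

    qmi = np.array(
        [u.factor * mutual_information(f, cls) for f, u in zip(features, utilities)]
    )

    n_bins = max(f.n_bins for f in features)
    codes = np.column_stack([f.codes for f in features])
    cmi = np.zeros((n, n))
    for i in range(n):
        row = _cmi_profile(codes, n_bins, features[i].codes, features[i].n_bins,
                           cls.codes, cls.n_bins)
        row[i] = 0.0  # diagonal unused
        cmi[i] = row
    return PairwiseCache(qmi, cmi, utilities)


def interdependence_index(i: int, j: int, cache: PairwiseCache) -> int:
    """1 iff conditioning on f_i strictly increases f_j's class information.

    Strict comparison: CMI(f_j; class | f_i) > QMI(f_j; class); equality
    counts as redundancy.
    """
    if i == j:
        raise ValueError("interdependence index requires i != j")
    return int(cache.cmi_given[i, j] > cache.qmi_class[j])


def set_relevance(K, cache: PairwiseCache) -> float:
    """Mean QMI(f_j; class) over the members of K."""
    K = list(K)
    if not K:
        raise ValueError("K must be non-empty")
    return float(cache.qmi_class[K].mean())


def relevance_change(K, i: int, cache: PairwiseCache) -> float:
    """Mean over j in K of CMI(f_j; class | f_i) - QMI(f_j; class)."""
    K = list(K)
    if not K:
        raise ValueError("K must be non-empty")
    if i in K:
        raise ValueError("i must not belong to K")
    return float((cache.cmi_given[i, K] - cache.qmi_class[K]).mean())


def coalition_payoff(K, i: int, cache: PairwiseCache) -> int:
    """Binary payoff of adding feature i to coalition K.

    1 iff relevance_change(K, i) >= 0 and i is interdependent with at least
    half of K's members (both thresholds inclusive).
    """
    K = list(K)
    if relevance_change(K, i, cache) < 0:
        return 0
    psi_sum = sum(interdependence_index(i, j, cache) for j in K)
    return int(psi_sum >= len(K) / 2)


def _phi_from_count(count: int, n: int, k: int) -> float:
    # exact integer products, one correctly-rounded division
    return count * math.factorial(k) * math.factorial(n - k - 1) / math.factorial(n)


def shapley_value(i: int, cache: PairwiseCache, coalition_size: int) -> float:
    """Shapley value of feature i by explicit coalition enumeration.

    Sums the binary payoff over every size-``coalition_size`` subset of the
    other features, each weighted by k!(n-k-1)!/n!.  Exponential in
    ``coalition_size``; the fast path in :func:`weights_from_cache` covers
    the default size 2.
    """
    n = cache.n_features
    if coalition_size < 1:
        raise ValueError("coalition_size must be >= 1")
    if coalition_size >= n:
        raise ValueError("coalition_size must be < n_features")
    others = [j for j in range(n) if j != i]
    count = sum(coalition_payoff(K, i, cache) for K in combinations(others, coalition_size))
    return _phi_from_count(count, n, coalition_size)


def weights_from_cache(cache: PairwiseCache, coalition_size: int = 2) -> ShapleyWeights:
    """Shapley values for every feature, vectorized for sizes 1 and 2."""
    n = cache.n_features
    if coalition_size >= n:
        raise ValueError("coalition_size must be < n_features")
    phi = np.empty(n)
    if coalition_size == 1:
        for i in range(n):
            d = cache.cmi_given[i] - cache.qmi_class
            psi = cache.cmi_given[i] > cache.qmi_class
            ok = (d >= 0) & psi
            ok[i] = False
            phi[i] = _phi_from_count(int(ok.sum()), n, 1)
    elif coalition_size == 2:
        for i in range(n):
            d = np.delete(cache.cmi_given[i] - cache.qmi_class, i)
            psi = np.delete(cache.cmi_given[i] > cache.qmi_class, i).astype(np.int8)
            rc_ok = (d[:, None] + d[None, :]) >= 0
            psi_ok = (psi[:, None] + psi[None, :]) >= 1
            both = rc_ok & psi_ok
            # each unordered pair counted once: (sum - diagonal) / 2
            count = (int(both.sum()) - int(np.diag(both).sum())) // 2
            phi[i] = _phi_from_count(count, n, 2)
    else:
        for i in range(n):
            phi[i] = shapley_value(i, cache, coalition_size)
    return ShapleyWeights(phi, coalition_size, n)


def compute_all_weights(
    features: Sequence[DiscretizedFeature],
    cls: DiscretizedFeature,
    utility: Sequence[UtilitySpec] | UtilitySpec,
    coalition_size: int = 2,
) -> ShapleyWeights:
    """End-to-end phase 2: build the pairwise cache, then all Shapley values."""
    if len(features) < 3:
        raise ValueError("need at least 3 features")
    cache = build_pairwise_cache(features, cls, utility)
    return weights_from_cache(cache, coalition_size)
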