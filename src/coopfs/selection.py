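"""Phase 3: victory-score forward selection.

Greedy loop: at every step each unselected feature gets a relevance /
redundancy score g (symmetric uncertainty with the class minus the mean SU
with already-selected features) which is modulated by the feature's
min-max-normalized Shapley weight into a victory score V = (1 + w) * g; the
argmax wins (ties: larger Shapley weight, then smaller index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .info_theory import DiscretizedFeature, entropy, mutual_information, symmetric_uncertainty
from .shapley import ShapleyWeights

__all__ = [
    "SelectionResult",
    "normalize_weights",
    "criterion_g",
    "victory_score",
    "forward_select",
]


@dataclass
class SelectionResult:
    """Ordered forward-selection output with per-step diagnostics."""

    selected: list
    victory_trace: list
    g_trace: list
    su_trace: list
    target_count: int
    selected_ids: list | None = None

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected features must be unique")


def normalize_weights(phi: np.ndarray) -> np.ndarray:
    """Min-max normalization of the Shapley vector to [0, 1]; all-equal -> 0."""
    phi = np.asarray(phi, dtype=np.float64)
    lo, hi = phi.min(), phi.max()
    if hi == lo:
        return np.zeros_like(phi)
    return (phi - lo) / (hi - lo)


def criterion_g(
    f: int,
    selected: Sequence[int],
    su_class: np.ndarray,
    su_pairs: Callable[[int, int], float],
) -> float:
    """Relevance-minus-mean-redundancy score of candidate f.

    g = SU(f; class) when nothing is selected yet, otherwise
    g = SU(f; class) - mean over selected s of SU(f; s); may go negative.
    """
    if f in selected:
        raise ValueError(f"feature {f} already selected")
    g = float(su_class[f])
    if selected:
        g -= float(np.mean([su_pairs(f, s) for s in selected]))
    return g


def victory_score(f: int, g: float, weights: ShapleyWeights) -> float:
    """V(f) = (1 + w(f)) * g(f) with w the min-max-normalized Shapley value."""
    w = normalize_weights(weights.phi)
    return (1.0 + float(w[f])) * g


def _su_matrix_column(
    features: Sequence[DiscretizedFeature], entropies: np.ndarray, s: int
) -> np.ndarray:
    """SU(f_j, f_s) for every j, with the constant-feature -> 0 convention."""
    fs = features[s]
    n = len(features)
    out = np.zeros(n)
    if entropies[s] == 0.0:
        return out
    for j in range(n):
        if j == s or entropies[j] == 0.0:
            continue
        out[j] = 2.0 * mutual_information(features[j], fs) / (entropies[j] + entropies[s])
    out[s] = 1.0
    return np.clip(out, 0.0, 1.0)


def forward_select(
    features: Sequence[DiscretizedFeature],
    cls: DiscretizedFeature,
    weights: ShapleyWeights,
    target_count: int,
    feature_ids: Sequence[str] | None = None,
) -> SelectionResult:
    """Greedy victory-score selection of ``target_count`` features.

    Deterministic: argmax of V at each step, ties resolved by larger Shapley
    weight then smaller feature index.  ``target_count`` beyond the feature
    count is clamped with a warning.
    """
    n = len(features)
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    if target_count > n:
        warnings.warn(
            f"target_count={target_count} clamped to n_features={n}", stacklevel=2
        )
        target_count = n

    entropies = np.array([entropy(f) for f in features])
    su_class = np.array([symmetric_uncertainty(f, cls) for f in features])
    w = normalize_weights(weights.phi)

    selected: list[int] = []
    victory_trace: list[float] = []
    g_trace: list[float] = []
    su_trace: list[float] = []
    redundancy_sum = np.zeros(n)
    available = np.ones(n, dtype=bool)

    for _ in range(target_count):
        g = su_class.copy()
        if selected:
            g -= redundancy_sum / len(selected)
        v = (1.0 + w) * g
        # ties: larger V, then larger phi, then smaller index
        order = np.lexsort((np.arange(n), -weights.phi, -v))
        best = order[available[order]][0]
        selected.append(int(best))
        victory_trace.append(float(v[best]))
        g_trace.append(float(g[best]))
        su_trace.append(float(su_class[best]))
        available[best] = False
        if len(selected) < target_count:
            redundancy_sum += _su_matrix_column(features, entropies, int(best))

    ids = None
    if feature_ids is not None:
        ids = [str(feature_ids[i]) for i in selected]
    return SelectionResult(selected, victory_trace, g_trace, su_trace, target_count, ids)
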