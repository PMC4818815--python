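"""Discretization and plug-in information-theoretic estimators.

All quantities are computed from empirical contingency tables in log base 2
(bits), with the convention 0*log(0) = 0.  Expression features are discretized
with equal-frequency binning before estimation; class labels are used as
categorical codes directly (see :func:`from_labels`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConstantClassError

__all__ = [
    "DiscretizedFeature",
    "UtilitySpec",
    "discretize",
    "from_labels",
    "joint",
    "entropy",
    "mutual_information",
    "qualitative_mutual_information",
    "conditional_mutual_information",
    "symmetric_uncertainty",
]


@dataclass
class DiscretizedFeature:
    """Integer-coded random variable over ``n_bins`` states.

    ``bin_edges`` is empty for categorical sources (class labels, joint
    codings) where no ordering of states is implied.
    """

    codes: np.ndarray
    n_bins: int
    bin_edges: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 1 or self.codes.size == 0:
            raise ValueError("codes must be a non-empty 1-D integer vector")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.n_bins > self.codes.size:
            raise ValueError("n_bins may not exceed the number of samples")
        if self.codes.min() < 0 or self.codes.max() >= self.n_bins:
            raise ValueError("codes must lie in [0, n_bins)")

    def __len__(self) -> int:
        return self.codes.size


@dataclass
class UtilitySpec:
    """Per-feature utility multiplier applied inside the QMI sum.

    ``mode='fisher'`` scales every cell of a feature's MI sum by that
    feature's Fisher ratio (a constant over value pairs, so QMI = FR * MI);
    ``mode='constant_one'`` reduces QMI to plain MI.
    """

    mode: str = "constant_one"
    per_feature_value: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("fisher", "constant_one"):
            raise ValueError(f"unknown utility mode: {self.mode!r}")
        v = float(self.per_feature_value)
        if not np.isfinite(v) or v < 0:
            raise ValueError("per_feature_value must be finite and >= 0")
        self.per_feature_value = v

    @property
    def factor(self) -> float:
        return 1.0 if self.mode == "constant_one" else self.per_feature_value


def discretize(values, n_bins: int, strategy: str = "equal_frequency") -> DiscretizedFeature:
    """Bin a continuous vector into integer codes.

    equal_frequency assigns contiguous rank chunks of size ``n // B`` (the
    first ``n % B`` chunks one larger), ties resolved by value order then
    original index (stable sort).  A constant vector collapses to a single
    occupied bin regardless of ``n_bins``.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("values must be a non-empty 1-D vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    n = values.size
    n_bins = min(n_bins, n)

    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        return DiscretizedFeature(np.zeros(n, dtype=np.int64), 1, np.array([vmin, vmax]))

    codes = np.empty(n, dtype=np.int64)
    if strategy == "equal_frequency":
        order = np.argsort(values, kind="stable")
        base, rem = divmod(n, n_bins)
        start = 0
        edges = [vmin]
        for b in range(n_bins):
            size = base + (1 if b < rem else 0)
            codes[order[start : start + size]] = b
            start += size
            edges.append(values[order[start - 1]])
        bin_edges = np.asarray(edges)
    elif strategy == "equal_width":
        bin_edges = np.linspace(vmin, vmax, n_bins + 1)
        codes = np.clip(np.searchsorted(bin_edges, values, side="right") - 1, 0, n_bins - 1)
    else:
        raise ValueError(f"unknown strategy: {strategy!r}")
    return DiscretizedFeature(codes, n_bins, bin_edges)


def from_labels(labels) -> DiscretizedFeature:
    """Code a categorical vector (e.g. class labels) as a DiscretizedFeature."""
    labels = np.asarray(labels)
    _, codes = np.unique(labels, return_inverse=True)
    return DiscretizedFeature(codes.astype(np.int64), int(codes.max()) + 1)


def joint(x: DiscretizedFeature, y: DiscretizedFeature) -> DiscretizedFeature:
    """Joint coding of (x, y) as a single variable over n_bins(x)*n_bins(y) states."""
    _check_lengths(x, y)
    return DiscretizedFeature(x.codes * y.n_bins + y.codes, x.n_bins * y.n_bins)


def _check_lengths(*feats: DiscretizedFeature) -> None:
    sizes = {len(f) for f in feats}
    if len(sizes) > 1:
        raise ValueError(f"length mismatch: {sorted(sizes)}")


def entropy(x: DiscretizedFeature) -> float:
    """Plug-in Shannon entropy in bits; 0 <= H <= log2(n_bins)."""
    counts = np.bincount(x.codes, minlength=x.n_bins)
    p = counts[counts > 0] / x.codes.size
    return float(-(p * np.log2(p)).sum())


def _joint_probs(x: DiscretizedFeature, y: DiscretizedFeature) -> np.ndarray:
    counts = np.bincount(x.codes * y.n_bins + y.codes, minlength=x.n_bins * y.n_bins)
    return counts.reshape(x.n_bins, y.n_bins) / x.codes.size


def mutual_information(x: DiscretizedFeature, y: DiscretizedFeature) -> float:
    """Plug-in MI in bits; symmetric, >= 0, <= min(H(x), H(y))."""
    _check_lengths(x, y)
    p = _joint_probs(x, y)
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(mask, p * np.log2(np.where(mask, p / (px * py), 1.0)), 0.0)
    return max(float(terms.sum()), 0.0)


def qualitative_mutual_information(
    x: DiscretizedFeature, y: DiscretizedFeature, utility: UtilitySpec
) -> float:
    """MI with each joint-probability term multiplied by a utility U.

    The utility here is constant over value pairs (one number per feature),
    so the sum factorizes: QMI = U * MI.  With mode=constant_one this equals
    :func:`mutual_information` exactly.
    """
    _check_lengths(x, y)
    return utility.factor * mutual_information(x, y)


def conditional_mutual_information(
    x: DiscretizedFeature, y: DiscretizedFeature, z: DiscretizedFeature
) -> float:
    """Plug-in CMI(x; y | z) in bits; symmetric in (x, y), clamped at 0."""
    _check_lengths(x, y, z)
    n = len(x)
    dims = (z.n_bins, x.n_bins, y.n_bins)
    flat = (z.codes * x.n_bins + x.codes) * y.n_bins + y.codes
    p = np.bincount(flat, minlength=np.prod(dims)).reshape(dims) / n
    pz = p.sum(axis=(1, 2), keepdims=True)
    pxz = p.sum(axis=2, keepdims=True)
    pyz = p.sum(axis=1, keepdims=True)
    mask = p > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mask, p * pz / np.where(mask, pxz * pyz, 1.0), 1.0)
        terms = np.where(mask, p * np.log2(ratio), 0.0)
    return max(float(terms.sum()), 0.0)


def symmetric_uncertainty(f: DiscretizedFeature, cls: DiscretizedFeature) -> float:
    """SU(f, class) = 2*MI / (H(class) + H(f)), in [0, 1]; 0 for constant f."""
    _check_lengths(f, cls)
    h_cls = entropy(cls)
    if h_cls == 0.0:
        raise ConstantClassError("class vector is constant")
    h_f = entropy(f)
    if h_f == 0.0:
        return 0.0
    su = 2.0 * mutual_information(f, cls) / (h_cls + h_f)
    return float(min(max(su, 0.0), 1.0))
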