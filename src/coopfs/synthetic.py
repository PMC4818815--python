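"""Synthetic microarray-like data with known ground truth.

Gaussian class-conditional model: informative features get class-dependent
means separated by ``effect_size`` within-class standard deviations;
redundant features are noisy copies of informative ones with a tunable
population correlation; noise features are iid standard normal.  All
randomness comes from ``numpy.random.default_rng`` (PCG64), so a seed pins
the output bit-for-bit across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionDataset

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "default_fixture"]


@dataclass
class SyntheticSpec:
    """Parameters of the generator; counts partition the feature index range."""

    n_samples: int = 100
    n_classes: int = 2
    n_informative: int = 10
    n_redundant_per_informative: int = 4
    n_noise: int = 1950
    effect_size: float = 2.0
    redundancy_corr: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_classes) < 2:
            raise ValueError("need >= 2 samples and >= 2 classes")
        if min(self.n_informative, self.n_redundant_per_informative, self.n_noise) < 0:
            raise ValueError("feature counts must be >= 0")
        if self.effect_size > 0 and self.n_informative < 1:
            raise ValueError("effect_size > 0 requires n_informative >= 1")
        if not 0 < self.redundancy_corr <= 1:
            raise ValueError("redundancy_corr must be in (0, 1]")

    @property
    def n_features(self) -> int:
        return self.n_informative * (1 + self.n_redundant_per_informative) + self.n_noise


@dataclass
class GroundTruth:
    """Index sets of the generated feature blocks (a partition of 0..n-1)."""

    informative: np.ndarray
    redundant: np.ndarray
    noise: np.ndarray
    source_of: dict  # redundant index -> informative index it copies


def _class_means(n_classes: int, effect_size: float) -> np.ndarray:
    """Per-feature class means, equally spaced on a segment of length effect_size.

    Adjacent classes are separated by effect_size / (n_classes - 1); for two
    classes this is the classical +/- effect/2 placement.
    """
    return effect_size * (np.arange(n_classes) / (n_classes - 1) - 0.5)


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw a dataset from the spec; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n, c = spec.n_samples, spec.n_classes

    # balanced classes, first n % c classes one sample larger, sorted labels
    base, rem = divmod(n, c)
    counts = [base + (1 if k < rem else 0) for k in range(c)]
    if min(counts) < 2:
        raise ValueError("every class needs at least 2 samples")
    labels = np.repeat([f"c{k}" for k in range(c)], counts)
    class_idx = np.repeat(np.arange(c), counts)

    means = _class_means(c, spec.effect_size)
    n_inf = spec.n_informative
    n_red = n_inf * spec.n_redundant_per_informative

    informative = means[class_idx][:, None] + rng.standard_normal((n, n_inf))

    # redundant = informative + noise sized so the pooled correlation ~ rho
    rho = spec.redundancy_corr
    pooled_var = 1.0 + float(np.var(means[class_idx])) if n_inf else 1.0
    tau = np.sqrt(pooled_var * (1.0 / rho**2 - 1.0))
    redundant = np.empty((n, n_red))
    source_of = {}
    for r in range(n_red):
        src = r % n_inf if n_inf else 0
        redundant[:, r] = informative[:, src] + tau * rng.standard_normal(n)
        source_of[n_inf + r] = src

    noise = rng.standard_normal((n, spec.n_noise))

    matrix = np.concatenate([informative, redundant, noise], axis=1)
    feature_ids = np.array(
        [f"inf{j:04d}" for j in range(n_inf)]
        + [f"red{j:04d}" for j in range(n_red)]
        + [f"noi{j:04d}" for j in range(spec.n_noise)],
        dtype=object,
    )
    sample_ids = np.array([f"s{i:04d}" for i in range(n)], dtype=object)
    dataset = ExpressionDataset(matrix, labels, feature_ids, sample_ids)
    truth = GroundTruth(
        informative=np.arange(n_inf),
        redundant=np.arange(n_inf, n_inf + n_red),
        noise=np.arange(n_inf + n_red, spec.n_features),
        source_of=source_of,
    )
    return dataset, truth


def default_fixture(seed: int = 1234) -> tuple[ExpressionDataset, GroundTruth]:
    """Canonical desk-scale fixture: 100 samples x 2000 features, 2 classes.

    10 informative features (effect 2.0 sd), 4 correlated copies of each
    (corr 0.9), 1950 pure-noise features.
    """
    spec = SyntheticSpec(
        n_samples=100,
        n_classes=2,
        n_informative=10,
        n_redundant_per_informative=4,
        n_noise=1950,
        effect_size=2.0,
        redundancy_corr=0.9,
        seed=seed,
    )
    return generate(spec)
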