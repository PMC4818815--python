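"""Measurement harness: k-fold classification metrics and JC stability.

The JC similarity between two equal-size feature subsets credits exact
overlap plus, for each unshared feature of one subset, its best absolute
Pearson correlation with the unshared features of the other; this keeps
JC in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .config import RunConfig
from .io import ExpressionDataset

__all__ = [
    "MetricsReport",
    "StabilityReport",
    "classification_metrics",
    "cross_validate",
    "resample_subsets",
    "jc_similarity",
    "mean_stability",
    "stability_analysis",
]


@dataclass
class MetricsReport:
    """Cross-validated classification metrics (precision/recall/F only for 2 classes)."""

    accuracy: float
    precision: float | None
    recall: float | None
    f_measure: float | None
    per_fold: dict
    classifier: str


@dataclass
class StabilityReport:
    """Per-resample JC values and their mean +/- sample standard deviation."""

    jc_values: np.ndarray
    mean_jc: float
    sd_jc: float
    subset_size: int
    m: int


def classification_metrics(y_true, y_pred, positive_class=None) -> dict:
    """Confusion-table metrics.

    accuracy = fraction correct for any number of classes; precision,
    recall and F-measure are computed from TP/FP/FN of ``positive_class``
    and reported only for 2-class problems (None otherwise).  Zero
    denominators yield 0 by convention.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between y_true and y_pred")
    accuracy = float(np.mean(y_true == y_pred))
    classes = np.unique(y_true)
    if classes.size != 2:
        return {"accuracy": accuracy, "precision": None, "recall": None, "f_measure": None}
    if positive_class is None:
        positive_class = classes[-1]
    tp = float(np.sum((y_true == positive_class) & (y_pred == positive_class)))
    fp = float(np.sum((y_true != positive_class) & (y_pred == positive_class)))
    fn = float(np.sum((y_true == positive_class) & (y_pred != positive_class)))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f_measure": f}


def _make_classifier(name: str, seed: int, knn_k: int = 3, svm_sigma: float = 20.0):
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=knn_k)
    if name == "svm_rbf":
        # Gaussian kernel exp(-||x-y||^2 / (2 sigma^2))
        return SVC(kernel="rbf", gamma=1.0 / (2.0 * svm_sigma**2))
    if name == "naive_bayes":
        return GaussianNB()
    if name == "cart":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown classifier: {name!r}")


def cross_validate(
    dataset: ExpressionDataset,
    selected_features,
    classifier: str = "knn",
    n_folds: int = 10,
    seed: int = 0,
    knn_k: int = 3,
    svm_sigma: float = 20.0,
    positive_class=None,
) -> MetricsReport:
    """Stratified k-fold CV on the selected feature columns only.

    Falls back to unstratified folds (with a warning) when some class has
    fewer samples than folds.  Deterministic for a fixed seed.
    """
    selected_features = np.asarray(selected_features, dtype=np.int64)
    if selected_features.size == 0:
        raise ValueError("selected_features is empty")
    X = dataset.matrix[:, selected_features]
    y = dataset.labels
    _, counts = np.unique(y, return_counts=True)
    if counts.min() >= n_folds:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)
    else:
        warnings.warn("class too small for stratification; using plain k-fold", stacklevel=2)
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X)

    fold_metrics = []
    for train, test in splits:
        clf = _make_classifier(classifier, seed, knn_k, svm_sigma)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        fold_metrics.append(classification_metrics(y[test], pred, positive_class))

    per_fold = {
        key: [m[key] for m in fold_metrics]
        for key in ("accuracy", "precision", "recall", "f_measure")
    }
    binary = np.unique(y).size == 2

    def _mean(key):
        vals = [v for v in per_fold[key] if v is not None]
        return float(np.mean(vals)) if binary and vals else None

    return MetricsReport(
        accuracy=float(np.mean(per_fold["accuracy"])),
        precision=_mean("precision"),
        recall=_mean("recall"),
        f_measure=_mean("f_measure"),
        per_fold=per_fold,
        classifier=classifier,
    )


def resample_subsets(
    dataset: ExpressionDataset,
    config: RunConfig,
    n_resamples: int = 10,
    subset_size: int = 20,
    seed: int = 0,
) -> tuple[list, np.ndarray]:
    """Feature subsets from resampled data plus the full-data reference.

    The m resamples are the m training portions of an m-fold (stratified
    when possible) partition; every subset has ``subset_size`` members and
    is expressed in original feature indices.
    """
    from .pipeline import select_features  # local import to avoid a cycle

    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    cfg = config.replace(n_selected=subset_size)
    if subset_size > min(cfg.prefilter_k, dataset.n_features):
        raise ValueError("subset_size exceeds the surviving feature count")

    reference = select_features(dataset, cfg).selected_original

    y = dataset.labels
    _, counts = np.unique(y, return_counts=True)
    if counts.min() >= n_resamples:
        splitter = StratifiedKFold(n_splits=n_resamples, shuffle=True, random_state=seed)
        splits = splitter.split(dataset.matrix, y)
    else:
        warnings.warn("class too small for stratification; using plain k-fold", stacklevel=2)
        splitter = KFold(n_splits=n_resamples, shuffle=True, random_state=seed)
        splits = splitter.split(dataset.matrix)

    subsets = []
    for train, _test in splits:
        part = ExpressionDataset(
            dataset.matrix[train],
            dataset.labels[train],
            dataset.feature_ids,
            dataset.sample_ids[train],
        )
        subsets.append(select_features(part, cfg).selected_original)
    return subsets, reference


def jc_similarity(s_i, s_o, data: ExpressionDataset, k: int) -> float:
    """JC = (|S_i n S_o| + SC_i) / k, in [0, 1].

    SC_i matches each unshared S_i feature to its best absolute Pearson
    correlate among the unshared S_o features (computed on the full matrix);
    zero-variance features correlate 0 by convention.
    """
    s_i = set(int(v) for v in np.asarray(s_i).ravel())
    s_o = set(int(v) for v in np.asarray(s_o).ravel())
    if len(s_i) != k or len(s_o) != k:
        raise ValueError(f"both subsets must have size k={k}")
    shared = len(s_i & s_o)
    only_i = sorted(s_i - s_o)
    only_o = sorted(s_o - s_i)
    sc = 0.0
    if only_i and only_o:
        a = data.matrix[:, only_i]
        b = data.matrix[:, only_o]
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        sa = np.sqrt((a**2).sum(axis=0))
        sb = np.sqrt((b**2).sum(axis=0))
        denom = np.outer(sa, sb)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.where(denom > 0, np.abs(a.T @ b) / np.where(denom > 0, denom, 1.0), 0.0)
        sc = float(np.minimum(corr.max(axis=1), 1.0).sum())
    return float(min((shared + sc) / k, 1.0))


def mean_stability(jc_values) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation of the JC values."""
    jc_values = np.asarray(jc_values, dtype=np.float64)
    if jc_values.size == 0:
        raise ValueError("jc_values is empty")
    sd = float(jc_values.std(ddof=1)) if jc_values.size > 1 else 0.0
    return float(jc_values.mean()), sd


def stability_analysis(
    dataset: ExpressionDataset,
    config: RunConfig,
    n_resamples: int = 10,
    subset_size: int = 20,
    seed: int = 0,
) -> StabilityReport:
    """Run the pipeline on full data and m resamples; report the JC profile."""
    subsets, reference = resample_subsets(dataset, config, n_resamples, subset_size, seed)
    jc = np.array([jc_similarity(s, reference, dataset, subset_size) for s in subsets])
    mean, sd = mean_stability(jc)
    return StabilityReport(jc, mean, sd, subset_size, n_resamples)
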