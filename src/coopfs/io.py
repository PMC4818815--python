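"""Reading and writing expression matrices and selection results.

The dataset contract consumed by every other module lives here: a validated
samples x features matrix with class labels and unique identifiers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import (
    ClassTooSmallError,
    DuplicateIdentifierError,
    MissingLabelColumnError,
    MissingValueError,
    NonNumericError,
    TooFewClassesError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .selection import SelectionResult
    from .shapley import ShapleyWeights

__all__ = ["ExpressionDataset", "load_dataset", "save_dataset", "save_selection", "load_selection"]

SAMPLE_ID_COLUMN = "sample_id"


@dataclass
class ExpressionDataset:
    """Continuous expression matrix (samples x features) with class labels."""

    matrix: np.ndarray
    labels: np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (samples x features)")
        n_samples, n_features = self.matrix.shape
        if self.labels.shape != (n_samples,):
            raise ValueError("labels length must equal n_samples")
        if self.feature_ids.shape != (n_features,):
            raise ValueError("feature_ids length must equal n_features")
        if self.sample_ids.shape != (n_samples,):
            raise ValueError("sample_ids length must equal n_samples")
        if not np.all(np.isfinite(self.matrix)):
            raise MissingValueError("matrix contains missing or non-finite entries")
        classes, counts = np.unique(self.labels, return_counts=True)
        if classes.size < 2:
            raise TooFewClassesError("labels must contain at least 2 distinct classes")
        if counts.min() < 2:
            small = classes[counts < 2]
            raise ClassTooSmallError(f"classes with <2 samples: {list(small)}")
        if np.unique(self.feature_ids).size != n_features:
            raise DuplicateIdentifierError("feature_ids are not unique")
        if np.unique(self.sample_ids).size != n_samples:
            raise DuplicateIdentifierError("sample_ids are not unique")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset_features(self, indices) -> "ExpressionDataset":
        """New dataset restricted to the given feature indices, in order."""
        indices = np.asarray(indices, dtype=np.int64)
        return ExpressionDataset(
            matrix=self.matrix[:, indices],
            labels=self.labels,
            feature_ids=self.feature_ids[indices],
            sample_ids=self.sample_ids,
        )


def _infer_delimiter(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    return "\t" if ext in (".tsv", ".txt", ".tab") else ","


def load_dataset(
    path: str,
    label_column: str = "class",
    transpose: bool = False,
    delimiter: str | None = None,
) -> ExpressionDataset:
    """Load a delimited expression file into a validated ExpressionDataset.

    Default orientation is samples x features with a header row of feature
    identifiers plus ``label_column``.  With ``transpose=True`` the file is
    read as features x samples (first column = feature ids, header = sample
    ids, one row named ``label_column`` holding the class labels) and flipped.
    An optional ``sample_id`` column supplies sample identifiers; otherwise
    they are synthesized as s0, s1, ...
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sep = delimiter if delimiter is not None else _infer_delimiter(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if not transpose and len(set(header)) != len(header):
        raise DuplicateIdentifierError("duplicate column names in header")
    if transpose:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str).T
        df.index.name = SAMPLE_ID_COLUMN
        df = df.reset_index()
    else:
        df = pd.read_csv(path, sep=sep, dtype=str)

    if label_column not in df.columns:
        raise MissingLabelColumnError(f"label column {label_column!r} not found")
    labels = df[label_column].to_numpy()
    if pd.isna(labels).any():
        raise MissingValueError("label column contains missing values")
    expr = df.drop(columns=[label_column])

    if SAMPLE_ID_COLUMN in expr.columns:
        sample_ids = expr[SAMPLE_ID_COLUMN].astype(str).to_numpy()
        expr = expr.drop(columns=[SAMPLE_ID_COLUMN])
    else:
        sample_ids = np.array([f"s{i}" for i in range(len(expr))], dtype=object)

    if expr.isna().to_numpy().any():
        raise MissingValueError("expression matrix contains missing cells")
    numeric = expr.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise NonNumericError(
            f"non-numeric cell {expr.iloc[r, c]!r} in column {expr.columns[c]!r}"
        )
    return ExpressionDataset(
        matrix=numeric.to_numpy(dtype=np.float64),
        labels=labels,
        feature_ids=expr.columns.to_numpy(dtype=object),
        sample_ids=sample_ids,
    )


def save_dataset(dataset: ExpressionDataset, path: str, label_column: str = "class") -> None:
    """Write a dataset as delimited text in the default samples x features layout."""
    sep = _infer_delimiter(path)
    df = pd.DataFrame(dataset.matrix, columns=dataset.feature_ids)
    df.insert(0, SAMPLE_ID_COLUMN, dataset.sample_ids)
    df[label_column] = dataset.labels
    df.to_csv(path, sep=sep, index=False)


def save_selection(result: "SelectionResult", weights: "ShapleyWeights", path: str) -> None:
    """Write ranked selected features as TSV.

    Columns: rank (1-based), feature_id, victory_score, shapley_weight,
    su_relevance.  Floats are written with repr precision so a re-read is
    bit-stable.
    """
    if not result.selected:
        raise ValueError("selection result is empty")
    ids = result.selected_ids
    if ids is None:
        ids = [f"f{idx}" for idx in result.selected]
    with open(path, "w") as fh:
        fh.write("rank\tfeature_id\tvictory_score\tshapley_weight\tsu_relevance\n")
        for rank, (idx, fid) in enumerate(zip(result.selected, ids), start=1):
            fh.write(
                f"{rank}\t{fid}\t{float(result.victory_trace[rank - 1])!r}\t"
                f"{float(weights.phi[idx])!r}\t{float(result.su_trace[rank - 1])!r}\n"
            )


def load_selection(path: str) -> pd.DataFrame:
    """Re-read a selection TSV written by :func:`save_selection`."""
    return pd.read_csv(
        path,
        sep="\t",
        dtype={
            "rank": np.int64,
            "feature_id": str,
            "victory_score": np.float64,
            "shapley_weight": np.float64,
            "su_relevance": np.float64,
        },
    )
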