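import numpy as np
import pytest

from coopfs import synthetic
from coopfs.io import ExpressionDataset


@pytest.fixture(scope="session")
def fixture_data():
    """The canonical 100 x 2000 synthetic dataset plus its ground truth."""
    return synthetic.default_fixture()


@pytest.fixture
def small_dataset():
    """Tiny deterministic dataset: 8 samples, 4 features, 2 balanced classes."""
    rng = np.random.default_rng(7)
    labels = np.array(["a", "a", "a", "a", "b", "b", "b", "b"])
    signal = np.where(labels == "a", -1.0, 1.0) + 0.1 * rng.standard_normal(8)
    matrix = np.column_stack(
        [signal, signal + 0.01 * rng.standard_normal(8), rng.standard_normal(8), rng.standard_normal(8)]
    )
    return ExpressionDataset(
        matrix=matrix,
        labels=labels,
        feature_ids=np.array(["g1", "g2", "g3", "g4"], dtype=object),
        sample_ids=np.array([f"s{i}" for i in range(8)], dtype=object),
    )


def count_signal_groups(selected, truth):
    """Number of planted signal groups represented by a selected index set."""
    informative = set(truth.informative.tolist())
    redundant = set(truth.redundant.tolist())
    groups = set()
    for idx in selected:
        idx = int(idx)
        if idx in informative:
            groups.add(idx)
        elif idx in redundant:
            groups.add(truth.source_of[idx])
    return len(groups)
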