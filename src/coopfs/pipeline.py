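"""End-to-end selection pipeline: normalize -> prefilter -> Shapley -> forward select."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import info_theory, prefilter, selection, shapley
from .config import RunConfig
from .io import ExpressionDataset

__all__ = ["PipelineResult", "select_features"]


@dataclass
class PipelineResult:
    """Everything produced by one pipeline run.

    ``selected_original`` maps the selection back to column indices of the
    input dataset (pre-prefilter), which is what stability comparisons need.
    """

    result: selection.SelectionResult
    weights: shapley.ShapleyWeights
    scores: prefilter.FeatureScoreVector
    kept_indices: np.ndarray
    selected_original: np.ndarray
    selected_ids: list


def select_features(dataset: ExpressionDataset, config: RunConfig) -> PipelineResult:
    """Run the three-phase pipeline under ``config``; deterministic."""
    data = prefilter.zscore_normalize(dataset, config.normalize)

    k = min(config.prefilter_k, data.n_features)
    trimmed, scores = prefilter.rank_and_trim(data, config.prefilter_method, k, config.bins)
    kept = scores.ranking[:k]

    cls = info_theory.from_labels(trimmed.labels)
    feats = [info_theory.discretize(col, config.bins) for col in trimmed.matrix.T]

    if config.utility == "fisher":
        fr = prefilter.fisher_ratio_vector(trimmed.matrix, trimmed.labels)
        utilities = [info_theory.UtilitySpec("fisher", v) for v in fr]
    else:
        utilities = info_theory.UtilitySpec("constant_one")

    cache = shapley.build_pairwise_cache(feats, cls, utilities)
    weights = shapley.weights_from_cache(cache, config.coalition_size)

    target = min(config.n_selected, len(feats))
    result = selection.forward_select(
        feats, cls, weights, target, feature_ids=trimmed.feature_ids
    )
    selected_original = kept[np.asarray(result.selected, dtype=np.int64)]
    return PipelineResult(
        result=result,
        weights=weights,
        scores=scores,
        kept_indices=kept,
        selected_original=selected_original,
        selected_ids=list(result.selected_ids),
    )
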