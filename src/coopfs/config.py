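"""Run configuration: one flat, validated record of every tunable.

Accepts the dotted key spelling used in config files (``prefilter.method``)
as well as the attribute spelling (``prefilter_method``); unknown keys are
rejected outright.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "KEY_ALIASES"]

KEY_ALIASES = {
    "prefilter.method": "prefilter_method",
    "prefilter.k": "prefilter_k",
    "shapley.coalition_size": "coalition_size",
    "shapley.utility": "utility",
    "select.n_features": "n_selected",
    "eval.classifier": "classifier",
    "eval.knn_k": "knn_k",
    "eval.svm_sigma": "svm_sigma",
    "eval.folds": "folds",
    "stability.m": "stability_m",
    "stability.subset_size": "stability_subset_size",
}

_CHOICES = {
    "prefilter_method": ("fisher", "mi"),
    "utility": ("fisher", "constant_one"),
    "classifier": ("knn", "svm_rbf", "naive_bayes", "cart"),
    "verbosity": ("quiet", "normal", "verbose"),
}


@dataclass
class RunConfig:
    normalize: bool = True
    bins: int = 5
    prefilter_method: str = "fisher"
    prefilter_k: int = 300
    coalition_size: int = 2
    utility: str = "fisher"
    n_selected: int = 50
    classifier: str = "knn"
    knn_k: int = 3
    svm_sigma: float = 20.0
    folds: int = 10
    stability_m: int = 10
    stability_subset_size: int = 20
    seed: int = 0
    verbosity: str = "normal"
    output_dir: str = "."

    def __post_init__(self) -> None:
        for key, choices in _CHOICES.items():
            if getattr(self, key) not in choices:
                raise ConfigError(f"{key} must be one of {choices}")
        for key in ("bins", "prefilter_k", "coalition_size", "n_selected",
                    "knn_k", "folds", "stability_m", "stability_subset_size"):
            if int(getattr(self, key)) < 1:
                raise ConfigError(f"{key} must be >= 1")
        if self.coalition_size > 3:
            import warnings

            warnings.warn(
                "coalition_size > 3 enumerates every subset of that size "
                "and is very expensive", stacklevel=2,
            )

    @classmethod
    def from_dict(cls, mapping: dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        resolved = {}
        for raw_key, value in mapping.items():
            key = KEY_ALIASES.get(raw_key, str(raw_key).replace(".", "_"))
            if key not in fields:
                raise ConfigError(f"unknown config key: {raw_key!r}")
            resolved[key] = value
        return cls(**resolved)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) if not path.endswith(".json") else json.load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
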