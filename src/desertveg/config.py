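"""Run configuration: nested parameter blocks, YAML round-trip.

A :class:`RunConfig` gathers every tunable of the pipeline (preprocessing,
feature extraction, training, post-processing, simulation) plus the global
seed. Pipeline entry points write the effective configuration alongside
their outputs so any run can be reproduced from its artifacts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classifier import C_GRID, GAMMA_GRID
from .exceptions import ParameterError
from .preprocess import PreprocessParams
from .simulate import SceneParams

__all__ = ["FeatureParams", "TrainParams", "PostprocessParams", "RunConfig"]


@dataclass(frozen=True)
class FeatureParams:
    """Dense GLCM extraction settings."""

    window: int = 7
    distance: int = 1
    gray_levels: int = 32
    angles: tuple[int, ...] = (0, 45, 90, 135)

    def __post_init__(self):
        if self.window % 2 == 0 or self.window < 3:
            raise ParameterError("window must be odd and >= 3")
        if self.distance < 1:
            raise ParameterError("distance must be >= 1")
        if self.gray_levels < 2:
            raise ParameterError("gray_levels must be >= 2")


@dataclass(frozen=True)
class TrainParams:
    """Grid-search and sampling settings for SVM training."""

    C_grid: tuple[float, ...] = C_GRID
    gamma_grid: tuple[float, ...] = GAMMA_GRID
    folds: int = 5
    seed: int = 0
    #: cap on labeled pixels drawn per class per training image (None = all)
    max_samples_per_class_per_image: int | None = None


@dataclass(frozen=True)
class PostprocessParams:
    """Stage switches for the morphological refinement (ablation support)."""

    opening: bool = True
    closing: bool = True
    median: bool = True


@dataclass(frozen=True)
class RunConfig:
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    train: TrainParams = field(default_factory=TrainParams)
    postprocess: PostprocessParams = field(default_factory=PostprocessParams)
    simulate: SceneParams = field(default_factory=SceneParams)
    #: compute spectral-index baselines on raw instead of preprocessed images
    baselines_on_raw: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(klass, block):
            block = {k: _tuplify(v) for k, v in (block or {}).items()}
            return klass(**block)

        return cls(
            preprocess=build(PreprocessParams, raw.get("preprocess")),
            features=build(FeatureParams, raw.get("features")),
            train=build(TrainParams, raw.get("train")),
            postprocess=build(PostprocessParams, raw.get("postprocess")),
            simulate=build(SceneParams, raw.get("simulate")),
            baselines_on_raw=raw.get("baselines_on_raw", False),
            seed=raw.get("seed", 0),
        )


def _tuplify(v):
    return tuple(v) if isinstance(v, list) else v


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj
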