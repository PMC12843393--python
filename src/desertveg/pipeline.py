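"""End-to-end orchestration: simulate, train, segment, evaluate, compare.

The workflow mirrors the method it implements: data preparation ->
preprocessing -> feature extraction -> model training -> prediction ->
morphological post-processing, plus the spectral-index baselines (ExG and
CIVE with Otsu) and the two SVM ablations (raw-RGB features, HSV-only
features) needed for a method comparison table.

Feature variants share one preprocessing pass per image:

* ``"full"`` — (H/360, S, V, contrast, homogeneity, energy, correlation),
* ``"hsv"``  — (H/360, S, V),
* ``"rgb"``  — plain (R, G, B) / 255 channels, the color-space ablation.

Baseline methods (the spectral indices and the RGB feature ablation) consume
the preprocessed image by default, making the comparison a controlled
ablation of the feature representation; ``RunConfig.baselines_on_raw``
switches them to the untouched input image instead.

Training pixels are taken only from images in the ``train`` partition of the
dataset manifest; the test partition never contributes a pixel to training
or model selection.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("desertveg")

from . import imgio as dio
from .classifier import (
    TrainedModel,
    TrainingSet,
    grid_search_cv,
    predict_mask,
    save_model,
    train_svm,
)
from .color import cive_index, excess_green, otsu_threshold
from .config import RunConfig
from .exceptions import InputError
from .metrics import ConfusionCounts, confusion_counts, evaluate_masks, metrics
from .morphology import postprocess_mask
from .preprocess import preprocess
from .simulate import generate_benchmark
from .texture import assemble_features, dense_texture

__all__ = [
    "FEATURE_VARIANTS",
    "simulate_dataset",
    "image_feature_stacks",
    "extract_training_sets",
    "train_pipeline",
    "segment_image",
    "evaluate_dataset",
    "compare_methods",
]

FEATURE_VARIANTS = ("full", "hsv", "rgb")


def simulate_dataset(
    out_dir: str | Path,
    n_scenes: int,
    config: RunConfig | None = None,
) -> dict:
    """Generate a benchmark dataset from the config's scene parameters."""
    config = config or RunConfig()
    logger.info("simulate: n_scenes=%d seed=%d params=%s", n_scenes, config.seed, config.simulate)
    manifest = generate_benchmark(
        n_scenes, params=config.simulate, seed=config.seed, out_dir=out_dir
    )
    config.to_yaml(Path(out_dir) / "config.yaml")
    return manifest


def image_feature_stacks(
    rgb: np.ndarray,
    config: RunConfig | None = None,
    variants: tuple[str, ...] = FEATURE_VARIANTS,
) -> dict[str, np.ndarray]:
    """Preprocess once and build the per-pixel stacks for each variant.

    The returned dict also carries the preprocessed RGB image under
    ``"_preprocessed"`` so baselines can reuse it.
    """
    config = config or RunConfig()
    unknown = set(variants) - set(FEATURE_VARIANTS)
    if unknown:
        raise InputError(f"unknown feature variants: {sorted(unknown)}")
    rgb = np.asarray(rgb)
    rgb_p, hsv_p = preprocess(rgb, config.preprocess)
    stacks: dict[str, np.ndarray] = {"_preprocessed": rgb_p}
    if "rgb" in variants:
        src = rgb if config.baselines_on_raw else rgb_p
        stacks["rgb"] = src.astype(np.float64) / 255.0
    if "hsv" in variants or "full" in variants:
        hsv_scaled = hsv_p.copy()
        hsv_scaled[..., 0] /= 360.0
        if "hsv" in variants:
            stacks["hsv"] = hsv_scaled
        if "full" in variants:
            fp = config.features
            texture = dense_texture(
                hsv_p[..., 2],
                window=fp.window,
                d=fp.distance,
                G=fp.gray_levels,
                angles=fp.angles,
            )
            stacks["full"] = assemble_features(hsv_p, texture)
    return stacks


def _load_manifest(dataset_dir: str | Path) -> dict:
    path = Path(dataset_dir) / "manifest.json"
    if not path.exists():
        raise InputError(f"no manifest.json in {dataset_dir}")
    with open(path) as fh:
        manifest = json.load(fh)
    if set(manifest["train"]) & set(manifest["test"]):
        raise InputError("manifest partitions are not disjoint")
    return manifest


def _scene_paths(dataset_dir: str | Path, sid: str) -> tuple[Path, Path]:
    d = Path(dataset_dir)
    return d / "images" / f"{sid}.png", d / "masks" / f"{sid}.png"


def extract_training_sets(
    dataset_dir: str | Path,
    config: RunConfig | None = None,
    variants: tuple[str, ...] = ("full",),
) -> dict[str, TrainingSet]:
    """Labeled pixel features from the train partition, one set per variant.

    Every labeled pixel of every training image is used unless
    ``config.train.max_samples_per_class_per_image`` caps the draw (a seeded,
    class-balanced subsample per image).
    """
    config = config or RunConfig()
    manifest = _load_manifest(dataset_dir)
    if not manifest["train"]:
        raise InputError("empty training partition")

    cap = config.train.max_samples_per_class_per_image
    feats: dict[str, list[np.ndarray]] = {v: [] for v in variants}
    labels: list[np.ndarray] = []
    ids: list[np.ndarray] = []
    for img_idx, sid in enumerate(manifest["train"]):
        img_path, mask_path = _scene_paths(dataset_dir, sid)
        rgb = dio.read_rgb(img_path)
        mask = dio.read_mask(mask_path)
        stacks = image_feature_stacks(rgb, config, variants)

        flat_mask = mask.ravel()
        idx = np.arange(flat_mask.size)
        if cap is not None:
            rng = np.random.default_rng([config.train.seed, img_idx])
            chosen = []
            for cls in (True, False):
                cls_idx = idx[flat_mask == cls]
                take = min(cap, cls_idx.size)
                if take:
                    chosen.append(rng.choice(cls_idx, size=take, replace=False))
            idx = np.sort(np.concatenate(chosen))
        for v in variants:
            nf = stacks[v].shape[2]
            feats[v].append(stacks[v].reshape(-1, nf)[idx])
        labels.append(flat_mask[idx].astype(np.int64))
        ids.append(np.full(idx.size, sid))

    y = np.concatenate(labels)
    prov = np.concatenate(ids)
    return {
        v: TrainingSet(np.concatenate(feats[v]), y, prov) for v in variants
    }


def train_pipeline(
    dataset_dir: str | Path,
    config: RunConfig | None = None,
    variant: str = "full",
    out_dir: str | Path | None = None,
) -> TrainedModel:
    """Grid-search (C, gamma) on the train partition, then fit the final model.

    With ``out_dir`` set, writes the model bundle, the 25-row CV table and
    the effective config next to each other.
    """
    config = config or RunConfig()
    logger.info(
        "train: variant=%s preprocess=%s features=%s train=%s",
        variant, config.preprocess, config.features, config.train,
    )
    ts = extract_training_sets(dataset_dir, config, (variant,))[variant]
    gs = grid_search_cv(
        ts,
        C_grid=config.train.C_grid,
        gamma_grid=config.train.gamma_grid,
        k=config.train.folds,
        seed=config.train.seed,
    )
    model = train_svm(
        ts,
        C=gs.best_C,
        gamma=gs.best_gamma,
        feature_variant=variant,
        cv_table=gs.table,
        seed=config.train.seed,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_model(model, out / f"model_{variant}.joblib")
        gs.table.to_csv(out / f"cv_table_{variant}.csv", index=False)
        config.to_yaml(out / "config.yaml")
    return model


def segment_image(
    model: TrainedModel,
    rgb: np.ndarray,
    config: RunConfig | None = None,
) -> np.ndarray:
    """Full inference path: preprocess -> features -> SVM -> morphology."""
    config = config or RunConfig()
    stacks = image_feature_stacks(rgb, config, (model.feature_variant,))
    raw = predict_mask(model, stacks[model.feature_variant])
    pp = config.postprocess
    return postprocess_mask(
        raw, opening=pp.opening, closing=pp.closing, median=pp.median
    )


def evaluate_dataset(
    pred_dir: str | Path, truth_dir: str | Path
) -> pd.DataFrame:
    """Per-image + pooled metrics for matching mask PNGs in two directories."""
    preds = {p.stem: dio.read_mask(p) for p in sorted(Path(pred_dir).glob("*.png"))}
    truths = {p.stem: dio.read_mask(p) for p in sorted(Path(truth_dir).glob("*.png"))}
    return evaluate_masks(preds, truths)


def compare_methods(
    dataset_dir: str | Path,
    config: RunConfig | None = None,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Method-comparison table on the test partition (pooled metrics).

    Rows: ExG + Otsu, CIVE + Otsu, RGB SVM, HSV-only SVM, and the full
    HSV+GLCM SVM. All SVM variants share the same folds, seed, grids and
    training pixels; morphological post-processing applies to the SVM
    methods (it is part of the method), not to the index baselines.
    """
    config = config or RunConfig()
    manifest = _load_manifest(dataset_dir)
    if not manifest["test"]:
        raise InputError("empty test partition")

    train_sets = extract_training_sets(dataset_dir, config, FEATURE_VARIANTS)
    models = {}
    for variant in FEATURE_VARIANTS:
        gs = grid_search_cv(
            train_sets[variant],
            C_grid=config.train.C_grid,
            gamma_grid=config.train.gamma_grid,
            k=config.train.folds,
            seed=config.train.seed,
        )
        models[variant] = train_svm(
            train_sets[variant],
            C=gs.best_C,
            gamma=gs.best_gamma,
            feature_variant=variant,
            cv_table=gs.table,
            seed=config.train.seed,
        )

    method_rows = ("ExG", "CIVE", "RGB SVM", "HSV-only SVM", "HSV+GLCM SVM")
    counts = {m: ConfusionCounts(0, 0, 0, 0) for m in method_rows}
    pp = config.postprocess
    for sid in manifest["test"]:
        img_path, mask_path = _scene_paths(dataset_dir, sid)
        rgb = dio.read_rgb(img_path)
        truth = dio.read_mask(mask_path)
        stacks = image_feature_stacks(rgb, config, FEATURE_VARIANTS)
        base_img = rgb if config.baselines_on_raw else stacks["_preprocessed"]

        preds = {}
        _, preds["ExG"] = otsu_threshold(excess_green(base_img))
        _, preds["CIVE"] = otsu_threshold(cive_index(base_img))
        for variant, row in (
            ("rgb", "RGB SVM"),
            ("hsv", "HSV-only SVM"),
            ("full", "HSV+GLCM SVM"),
        ):
            raw = predict_mask(models[variant], stacks[variant])
            preds[row] = postprocess_mask(
                raw, opening=pp.opening, closing=pp.closing, median=pp.median
            )
        for m, pred in preds.items():
            counts[m] = counts[m] + confusion_counts(pred, truth)

    table = pd.DataFrame.from_dict(
        {m: metrics(c).as_dict() for m, c in counts.items()}, orient="index"
    )
    table.index.name = "method"
    if out_csv is not None:
        table.to_csv(out_csv)
    return table
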