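"""Soft-margin RBF-SVM training, grid search, and dense mask prediction.

The classifier solves the usual soft-margin problem

    min_{w,b,xi}  ||w||^2 / 2 + C * sum_i xi_i
    s.t.          y_i (w . phi(x_i) + b) >= 1 - xi_i,   xi_i >= 0

with the radial-basis kernel ``K(x, y) = exp(-gamma ||x - y||^2)``. The
optimization itself is delegated to scikit-learn's ``SVC`` (libsvm); this
module owns everything around it: mandatory feature standardization (the
kernel distance is meaningless across mixed units such as hue fractions and
GLCM probabilities), the (C, gamma) grid search with stratified 5-fold
cross-validation selecting the highest mean F1 (ties broken toward the
smallest C, then the smallest gamma — the smoothest model), and chunked
per-pixel prediction over feature stacks.

Default grids: C in {0.1, 1, 10, 100, 1000}, gamma in
{0.001, 0.01, 0.1, 1, 10}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .exceptions import InputError, ParameterError

__all__ = [
    "C_GRID",
    "GAMMA_GRID",
    "TrainingSet",
    "TrainedModel",
    "GridSearchResult",
    "standardize",
    "rbf_kernel",
    "train_svm",
    "grid_search_cv",
    "predict_mask",
    "save_model",
    "load_model",
]

C_GRID = (0.1, 1.0, 10.0, 100.0, 1000.0)
GAMMA_GRID = (0.001, 0.01, 0.1, 1.0, 10.0)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainingSet:
    """Labeled pixel features with per-sample image provenance."""

    features: np.ndarray  # N x F
    labels: np.ndarray  # N, 1 = green, 0 = non-green
    image_ids: np.ndarray  # N image identifiers

    def __post_init__(self):
        X = np.asarray(self.features, dtype=np.float64)
        y = np.asarray(self.labels)
        ids = np.asarray(self.image_ids)
        if X.ndim != 2 or X.shape[0] != y.shape[0] or y.shape[0] != ids.shape[0]:
            raise InputError(
                f"inconsistent training set shapes: {X.shape}, {y.shape}, {ids.shape}"
            )
        if X.shape[0] < 2 or len(np.unique(y)) != 2:
            raise InputError("training set must contain both classes")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y.astype(np.int64))
        object.__setattr__(self, "image_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]


@dataclass
class GridSearchResult:
    best_C: float
    best_gamma: float
    best_cv_f1: float
    table: pd.DataFrame  # columns C, gamma, mean_cv_f1
    seed: int


@dataclass
class TrainedModel:
    """Fitted SVC plus the statistics needed to reproduce its predictions."""

    svc: SVC
    means: np.ndarray
    scales: np.ndarray
    C: float
    gamma: float
    feature_variant: str = "full"  # which channels the model consumes
    cv_table: pd.DataFrame | None = None
    seed: int | None = None
    training_accuracy: float = field(default=float("nan"))

    @property
    def n_features(self) -> int:
        return self.means.shape[0]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=np.float64) - self.means) / self.scales
        return self.svc.decision_function(Xs)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=np.float64) - self.means) / self.scales
        return self.svc.predict(Xs).astype(np.int64)


def standardize(
    features: np.ndarray,
    means: np.ndarray | None = None,
    scales: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score columns (population SD); zero-variance columns get scale 1.

    With ``means``/``scales`` given, applies the stored statistics instead
    of refitting (the inference path).
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise InputError(f"expected an N x F matrix, got shape {X.shape}")
    if means is None:
        if X.shape[0] < 2:
            raise InputError("need at least 2 samples to fit standardization")
        means = X.mean(axis=0)
        scales = X.std(axis=0)  # population convention (ddof=0)
        scales = np.where(scales > 0, scales, 1.0)
    return (X - means) / scales, np.asarray(means), np.asarray(scales)


def rbf_kernel(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """exp(-gamma ||x - y||^2); 1 iff x == y."""
    if gamma <= 0:
        raise ParameterError(f"gamma must be positive, got {gamma}")
    d = np.asarray(x, dtype=np.float64) - np.asarray(y, dtype=np.float64)
    return float(np.exp(-gamma * np.dot(d.ravel(), d.ravel())))


def train_svm(
    ts: TrainingSet, C: float = 100.0, gamma: float = 0.1, **model_kwargs
) -> TrainedModel:
    """Fit the soft-margin RBF-SVM on standardized features."""
    if C <= 0 or gamma <= 0:
        raise ParameterError(f"C and gamma must be positive, got C={C}, gamma={gamma}")
    Xs, means, scales = standardize(ts.features)
    svc = SVC(C=C, kernel="rbf", gamma=gamma)
    svc.fit(Xs, ts.labels)
    train_acc = float(np.mean(svc.predict(Xs) == ts.labels))
    return TrainedModel(
        svc=svc,
        means=means,
        scales=scales,
        C=C,
        gamma=gamma,
        training_accuracy=train_acc,
        **model_kwargs,
    )


def grid_search_cv(
    ts: TrainingSet,
    C_grid: tuple[float, ...] = C_GRID,
    gamma_grid: tuple[float, ...] = GAMMA_GRID,
    k: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Mean validation F1 over k seeded stratified folds for every grid cell.

    The winning cell maximizes mean F1; ties go to the smallest C, then the
    smallest gamma. Fold assignment depends only on ``seed`` (and the data),
    so the score table is fully reproducible.
    """
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    if ts.n_samples < k:
        raise ParameterError(f"k={k} folds exceed {ts.n_samples} samples")
    if not C_grid or not gamma_grid:
        raise ParameterError("empty parameter grid")
    if min(C_grid) <= 0 or min(gamma_grid) <= 0:
        raise ParameterError("grid values must be positive")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(ts.features, ts.labels))

    rows = []
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            scores = []
            for tr_idx, va_idx in folds:
                Xs, means, scales = standardize(ts.features[tr_idx])
                svc = SVC(C=C, kernel="rbf", gamma=gamma)
                svc.fit(Xs, ts.labels[tr_idx])
                Xva = (ts.features[va_idx] - means) / scales
                pred = svc.predict(Xva)
                scores.append(f1_score(ts.labels[va_idx], pred, zero_division=0))
            rows.append({"C": C, "gamma": gamma, "mean_cv_f1": float(np.mean(scores))})

    table = pd.DataFrame(rows)
    best_idx = int(table["mean_cv_f1"].idxmax())  # first max: smallest C, gamma
    best = table.loc[best_idx]
    return GridSearchResult(
        best_C=float(best["C"]),
        best_gamma=float(best["gamma"]),
        best_cv_f1=float(best["mean_cv_f1"]),
        table=table,
        seed=seed,
    )


def predict_mask(
    model: TrainedModel, feature_stack: np.ndarray, chunk: int = 65536
) -> np.ndarray:
    """Classify every pixel of an ``H x W x F`` feature stack; True = green."""
    fs = np.asarray(feature_stack, dtype=np.float64)
    if fs.ndim != 3 or fs.shape[2] != model.n_features:
        raise InputError(
            f"feature stack shape {fs.shape} incompatible with a "
            f"{model.n_features}-feature model"
        )
    flat = fs.reshape(-1, model.n_features)
    out = np.empty(flat.shape[0], dtype=np.int64)
    for start in range(0, flat.shape[0], chunk):
        out[start : start + chunk] = model.predict(flat[start : start + chunk])
    return out.reshape(fs.shape[:2]).astype(bool)


def save_model(model: TrainedModel, path) -> None:
    """Serialize a model bundle (version-tagged) with joblib."""
    bundle = {
        "format_version": MODEL_FORMAT_VERSION,
        "svc": model.svc,
        "means": model.means,
        "scales": model.scales,
        "C": model.C,
        "gamma": model.gamma,
        "feature_variant": model.feature_variant,
        "cv_table": model.cv_table,
        "seed": model.seed,
        "training_accuracy": model.training_accuracy,
    }
    joblib.dump(bundle, path)


def load_model(path) -> TrainedModel:
    try:
        bundle = joblib.load(path)
        version = bundle["format_version"]
    except Exception as exc:  # corrupt or foreign file
        raise InputError(f"cannot read model bundle from {path}: {exc}") from exc
    if version != MODEL_FORMAT_VERSION:
        raise InputError(f"unsupported model format version {version}")
    return TrainedModel(
        svc=bundle["svc"],
        means=bundle["means"],
        scales=bundle["scales"],
        C=bundle["C"],
        gamma=bundle["gamma"],
        feature_variant=bundle["feature_variant"],
        cv_table=bundle["cv_table"],
        seed=bundle["seed"],
        training_accuracy=bundle["training_accuracy"],
    )
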