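"""RBF-SVM classification, cross-validation and hyper-parameter search.

The classifier stage is deliberately conventional: a one-vs-one multiclass
SVM with an RBF kernel on the fused feature vectors, evaluated by
stratified shuffled k-fold cross-validation.  What this module adds is the
bookkeeping the experiments need — deterministic fold construction,
aggregated confusion matrices, an exhaustive (C, γ, k, thickness) grid
with declared tie-breaking, and the cross-growth-stage transfer protocol.

Determinism contract: every entry point takes an integer ``seed`` that
fully determines fold shuffling; images are sorted by (label, stage,
rotation, content hash) before fold assignment so results are invariant
to input row order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn import metrics
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._exceptions import ConfigError, InvalidInputError
from .features import (
    FusionParams,
    LBPConfig,
    extract_cmask_features,
    extract_pass_features,
    fuse_features,
    mean_rgb_features,
)
from .imaging import MorphologyConfig, PlantImage

__all__ = [
    "SVMParams",
    "CVResult",
    "StageTransferResult",
    "GridSearchResult",
    "train_svm",
    "predict",
    "confusion_matrix",
    "cv_on_features",
    "cross_validate",
    "grid_search",
    "stage_transfer",
    "extract_feature_matrix",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# Parameters and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVMParams:
    """RBF-kernel SVM hyper-parameters.

    ``gamma`` may be a positive float or one of two adaptive rules:
    ``"median"`` (the default) sets ``γ = 1 / median ‖xᵢ − xⱼ‖²`` over the
    training rows — the median heuristic, which matches the kernel width
    to the scale of the L1-normalized histogram features — and ``"scale"``
    is the sklearn convention ``1 / (n_features · Var(X))``.  Both are
    deterministic functions of the training fold.
    """

    C: float = 30.0
    gamma: float | str = "median"
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigError(f"C must be > 0, got {self.C}")
        if isinstance(self.gamma, str):
            if self.gamma not in ("scale", "median"):
                raise ConfigError(
                    f"gamma must be a positive float, 'median' or 'scale', got {self.gamma!r}"
                )
        elif self.gamma <= 0:
            raise ConfigError(f"gamma must be > 0, got {self.gamma}")
        if self.kernel != "rbf":
            raise ConfigError(f"only the RBF kernel is supported, got {self.kernel!r}")


_MEDIAN_HEURISTIC_CAP = 500  # rows used for the pairwise-distance median


def _resolve_gamma(gamma: float | str, X: np.ndarray) -> float | str:
    if gamma != "median":
        return gamma
    n = X.shape[0]
    rows = X if n <= _MEDIAN_HEURISTIC_CAP else X[:: max(1, n // _MEDIAN_HEURISTIC_CAP)]
    sq = np.square(rows[:, None, :] - rows[None, :, :]).sum(axis=2)
    d2 = sq[np.triu_indices(rows.shape[0], k=1)]
    d2 = d2[d2 > 0]
    if d2.size == 0:
        return "scale"
    return float(1.0 / np.median(d2))


@dataclass
class CVResult:
    """k-fold cross-validation outcome.

    ``confusion`` aggregates the five test folds (rows = true class,
    columns = predicted, in ``class_order``); its row sums are the
    per-class test counts and its trace over its total is the overall
    accuracy.
    """

    fold_accuracies: list[float]
    mean_accuracy: float
    confusion: np.ndarray
    class_order: list[str]
    fold_sizes: list[int]
    params: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": float(self.mean_accuracy),
            "confusion": self.confusion.tolist(),
            "class_order": list(self.class_order),
            "fold_sizes": [int(n) for n in self.fold_sizes],
            "params": self.params,
            "seed": int(self.seed),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def fold_table(self) -> pd.DataFrame:
        """One-row table: Fold 1..k accuracies plus the average."""
        row = {f"Fold {i + 1}": a for i, a in enumerate(self.fold_accuracies)}
        row["Average Accuracy"] = self.mean_accuracy
        return pd.DataFrame([row])

    def confusion_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=self.class_order,
                            columns=self.class_order)


@dataclass
class StageTransferResult:
    """Outcome of training on one set of growth stages and testing on another."""

    accuracy: float
    per_class_accuracy: dict[str, float]
    confusion: np.ndarray
    class_order: list[str]
    n_train: int
    n_test: int
    train_stages: list[int]
    test_stages: list[int]
    params: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "accuracy": float(self.accuracy),
            "per_class_accuracy": {k: float(v) for k, v in self.per_class_accuracy.items()},
            "confusion": self.confusion.tolist(),
            "class_order": list(self.class_order),
            "n_train": int(self.n_train),
            "n_test": int(self.n_test),
            "train_stages": list(self.train_stages),
            "test_stages": list(self.test_stages),
            "params": self.params,
            "seed": int(self.seed),
        }


@dataclass
class GridSearchResult:
    best_params: dict
    best_result: CVResult
    table: pd.DataFrame


# ---------------------------------------------------------------------------
# SVM plumbing
# ---------------------------------------------------------------------------

def train_svm(X: np.ndarray, y: Sequence, params: SVMParams | None = None) -> SVC:
    """Fit a one-vs-one multiclass RBF-SVM; deterministic for fixed inputs."""
    params = params or SVMParams()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise InvalidInputError(f"X must be 2-D, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("X contains non-finite values")
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise InvalidInputError("training requires at least 2 classes")
    model = SVC(C=params.C, gamma=_resolve_gamma(params.gamma, X), kernel=params.kernel)
    model.fit(X, y)
    return model


def predict(model: SVC, X: np.ndarray) -> np.ndarray:
    """One label per row of X; empty X yields an empty label array."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise InvalidInputError(f"X must be 2-D, got shape {X.shape}")
    if X.shape[0] == 0:
        return np.empty(0, dtype=model.classes_.dtype)
    if X.shape[1] != model.n_features_in_:
        raise InvalidInputError(
            f"X has {X.shape[1]} features, model expects {model.n_features_in_}"
        )
    return model.predict(X)


def confusion_matrix(y_true: Sequence, y_pred: Sequence,
                     class_order: Sequence[str]) -> np.ndarray:
    """Confusion matrix with rows = true class, columns = predicted class."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InvalidInputError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    known = set(class_order)
    unknown = (set(np.unique(y_true)) | set(np.unique(y_pred))) - known
    if unknown:
        raise InvalidInputError(f"labels not in class_order: {sorted(unknown)}")
    return metrics.confusion_matrix(y_true, y_pred, labels=list(class_order))


# ---------------------------------------------------------------------------
# Feature extraction over datasets
# ---------------------------------------------------------------------------

def _sort_key(image: PlantImage) -> tuple:
    digest = hashlib.sha1(image.pixels.tobytes()).hexdigest()
    return (image.label, image.stage, image.rotation_deg, digest)


def sort_dataset(images: Sequence[PlantImage]) -> list[PlantImage]:
    """Canonical content-based ordering; makes folds row-order invariant."""
    return sorted(images, key=_sort_key)


def extract_feature_matrix(images: Sequence[PlantImage],
                           lbp: LBPConfig | None = None,
                           morph: MorphologyConfig | None = None,
                           fusion: FusionParams | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Combined k-FLBPCM features for a list of images → (X, y)."""
    lbp = lbp or LBPConfig()
    fusion = fusion or FusionParams()
    morph = morph or MorphologyConfig()
    if morph.thickness != fusion.thickness:
        morph = MorphologyConfig(morph.se_size, fusion.thickness, morph.band_style)
    rows = []
    for im in images:
        p = extract_pass_features(im, lbp)
        c = extract_cmask_features(im, lbp, morph)
        rows.append(fuse_features(p, c, fusion).values)
    X = np.vstack(rows) if rows else np.empty((0, lbp.dim))
    y = np.asarray([im.label for im in images])
    return X, y


def _branch_matrices(images: Sequence[PlantImage], lbp: LBPConfig,
                     morph: MorphologyConfig) -> tuple[np.ndarray, np.ndarray]:
    """(pass, cmask) feature matrices, extracted once for reuse across k."""
    P = np.vstack([extract_pass_features(im, lbp).values for im in images])
    C = np.vstack([extract_cmask_features(im, lbp, morph).values for im in images])
    return P, C


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def cv_on_features(X: np.ndarray, y: np.ndarray, svm: SVMParams,
                   n_folds: int = 5, seed: int = 0,
                   standardize: bool = False,
                   params_record: dict | None = None) -> CVResult:
    """Stratified shuffled k-fold CV on a precomputed feature matrix.

    When ``standardize`` is on, the scaler is fit on each training fold
    only — the test fold never influences the standardization.
    """
    X, y = np.asarray(X, float), np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ConfigError(
            f"every class needs >= {n_folds} samples for {n_folds}-fold CV "
            f"(smallest class has {counts.min()})"
        )
    class_order = [str(c) for c in classes]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_acc, fold_sizes = [], []
    conf = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for train_idx, test_idx in skf.split(X, y):
        Xtr, Xte = X[train_idx], X[test_idx]
        if standardize:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        model = train_svm(Xtr, y[train_idx], svm)
        pred = predict(model, Xte)
        fold_acc.append(float(np.mean(pred == y[test_idx])))
        fold_sizes.append(len(test_idx))
        conf += confusion_matrix(y[test_idx], pred, class_order)
    return CVResult(
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        confusion=conf,
        class_order=class_order,
        fold_sizes=fold_sizes,
        params=params_record or {"svm": asdict(svm)},
        seed=seed,
    )


def cross_validate(images: Sequence[PlantImage],
                   lbp: LBPConfig | None = None,
                   morph: MorphologyConfig | None = None,
                   fusion: FusionParams | None = None,
                   svm: SVMParams | None = None,
                   n_folds: int = 5, seed: int = 0,
                   standardize: bool = False) -> CVResult:
    """End-to-end 5-fold CV: per-image feature extraction, then SVM folds.

    Features are extracted independently per image, so no information can
    leak between folds through the extraction stage.
    """
    lbp, svm = lbp or LBPConfig(), svm or SVMParams()
    fusion = fusion or FusionParams()
    morph = morph or MorphologyConfig()
    ordered = sort_dataset(images)
    X, y = extract_feature_matrix(ordered, lbp, morph, fusion)
    record = {"svm": asdict(svm), "fusion": asdict(fusion),
              "lbp_operators": list(lbp.operators)}
    return cv_on_features(X, y, svm, n_folds=n_folds, seed=seed,
                          standardize=standardize, params_record=record)


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

DEFAULT_C_GRID = (1.0, 10.0, 30.0, 100.0, 1000.0)
DEFAULT_GAMMA_GRID = tuple(10.0 ** e for e in range(-8, 0))
DEFAULT_K_GRID = (0.0, 0.1, 0.2, 0.5, 1.0)
DEFAULT_THICKNESS_GRID = (1, 2, 3)


def grid_search(images: Sequence[PlantImage],
                C_grid: Sequence[float] = DEFAULT_C_GRID,
                gamma_grid: Sequence = DEFAULT_GAMMA_GRID,
                k_grid: Sequence[float] = DEFAULT_K_GRID,
                thickness_grid: Sequence[int] = DEFAULT_THICKNESS_GRID,
                lbp: LBPConfig | None = None,
                morph: MorphologyConfig | None = None,
                n_folds: int = 5, seed: int = 0,
                standardize: bool = False) -> GridSearchResult:
    """Exhaustive CV over the (C, γ, k, thickness) grid.

    Branch features are extracted once per thickness and fused per k, so
    the image pipeline runs ``len(thickness_grid)`` times regardless of
    grid size.  The maximizer of mean accuracy is returned; ties break to
    the earlier cell in (C, γ, k, thickness) ascending iteration order.
    """
    for name, grid in [("C", C_grid), ("gamma", gamma_grid),
                       ("k", k_grid), ("thickness", thickness_grid)]:
        if len(list(grid)) == 0:
            raise ConfigError(f"empty {name} grid")
    lbp = lbp or LBPConfig()
    morph = morph or MorphologyConfig()
    ordered = sort_dataset(images)
    y = np.asarray([im.label for im in ordered])

    branch_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for t in sorted(set(int(t) for t in thickness_grid)):
        m = MorphologyConfig(morph.se_size, t, morph.band_style)
        branch_cache[t] = _branch_matrices(ordered, lbp, m)

    best: tuple[dict, CVResult] | None = None
    rows = []
    gamma_sorted = sorted(gamma_grid, key=lambda g: (isinstance(g, str), g if not isinstance(g, str) else 0))
    for C, gamma, k, t in product(sorted(C_grid), gamma_sorted,
                                  sorted(k_grid), sorted(thickness_grid)):
        t = int(t)
        Pm, Cm = branch_cache[t]
        X = k * Pm + Cm
        svm = SVMParams(C=C, gamma=gamma)
        record = {"svm": asdict(svm), "fusion": {"k": k, "thickness": t},
                  "lbp_operators": list(lbp.operators)}
        res = cv_on_features(X, y, svm, n_folds=n_folds, seed=seed,
                             standardize=standardize, params_record=record)
        rows.append({"C": C, "gamma": gamma, "k": k, "thickness": t,
                     "mean_accuracy": res.mean_accuracy})
        # strict > keeps the first cell on ties
        if best is None or res.mean_accuracy > best[1].mean_accuracy:
            best = ({"C": C, "gamma": gamma, "k": k, "thickness": t}, res)
    assert best is not None
    return GridSearchResult(best_params=best[0], best_result=best[1],
                            table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Stage-transfer protocol
# ---------------------------------------------------------------------------

def stage_transfer(images: Sequence[PlantImage],
                   train_stages: Sequence[int],
                   test_stages: Sequence[int],
                   lbp: LBPConfig | None = None,
                   morph: MorphologyConfig | None = None,
                   fusion: FusionParams | None = None,
                   svm: SVMParams | None = None,
                   seed: int = 0,
                   holdout: float = 0.2,
                   feature_kind: str = "kflbpcm") -> StageTransferResult:
    """Train on some growth stages, test on others.

    Two modes mirror the experimental designs:

    * identical stage sets — a stratified 80:20 split within those stages
      (``holdout`` is the test fraction);
    * different stage sets — train on every image of the training stages,
      test on every image of the testing stages.

    ``feature_kind="mean_rgb"`` swaps in the color-only control
    descriptor, keeping the split and classifier identical.
    """
    train_set, test_set = set(map(int, train_stages)), set(map(int, test_stages))
    if not train_set or not test_set:
        raise ConfigError("train and test stage selections must be non-empty")
    if feature_kind not in ("kflbpcm", "mean_rgb"):
        raise ConfigError(f"unknown feature_kind {feature_kind!r}")
    ordered = sort_dataset(images)
    train_imgs = [im for im in ordered if im.stage in train_set]
    test_imgs = [im for im in ordered if im.stage in test_set]
    if not train_imgs:
        raise ConfigError(f"no images in training stages {sorted(train_set)}")
    if not test_imgs:
        raise ConfigError(f"no images in testing stages {sorted(test_set)}")

    if train_set == test_set:
        labels = [im.label for im in train_imgs]
        tr, te = train_test_split(train_imgs, test_size=holdout,
                                  random_state=seed, stratify=labels)
        train_imgs, test_imgs = list(tr), list(te)

    if feature_kind == "kflbpcm":
        Xtr, ytr = extract_feature_matrix(train_imgs, lbp, morph, fusion)
        Xte, yte = extract_feature_matrix(test_imgs, lbp, morph, fusion)
    else:
        Xtr = np.vstack([mean_rgb_features(im) for im in train_imgs])
        Xte = np.vstack([mean_rgb_features(im) for im in test_imgs])
        ytr = np.asarray([im.label for im in train_imgs])
        yte = np.asarray([im.label for im in test_imgs])

    svm = svm or SVMParams()
    fusion = fusion or FusionParams()
    model = train_svm(Xtr, ytr, svm)
    pred = predict(model, Xte)
    class_order = sorted(set(ytr) | set(yte))
    conf = confusion_matrix(yte, pred, class_order)
    per_class = {}
    for i, c in enumerate(class_order):
        n = conf[i].sum()
        per_class[c] = float(conf[i, i] / n) if n else float("nan")
    return StageTransferResult(
        accuracy=float(np.mean(pred == yte)),
        per_class_accuracy=per_class,
        confusion=conf,
        class_order=class_order,
        n_train=len(train_imgs),
        n_test=len(test_imgs),
        train_stages=sorted(train_set),
        test_stages=sorted(test_set),
        params={"svm": asdict(svm), "fusion": asdict(fusion),
                "feature_kind": feature_kind},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def save_model(path: str | Path, model: SVC, metadata: dict) -> None:
    """Serialize the model plus a JSON sidecar of parameters and class order."""
    path = Path(path)
    joblib.dump(model, path)
    sidecar = dict(metadata)
    sidecar.setdefault("classes", [str(c) for c in model.classes_])
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> tuple[SVC, dict]:
    path = Path(path)
    model = joblib.load(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    metadata = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return model, metadata
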