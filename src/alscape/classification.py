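"""Topology classifiers: CNN, SVM and random forest under a class-disjoint split.

Activity classes are split half/half into training and test classes, so no
image of a held-out class can leak into training or cross-validation. The
SVM (one-against-one, grid over cost and kernel) and random forest (grid
over tree count, minimum split and leaf sizes) consume flattened 79,200-
feature vectors; hyperparameters are selected by ten-fold cross-validation
on the training images. The CNN consumes image tensors directly and selects
its hyperparameters on an internal 80/20 validation split.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._cnn import DivergenceError, TinyCNN
from .compound_data import VARIANT_LABELS

__all__ = [
    "ClassSplit",
    "CNNConfig",
    "SVMConfig",
    "RFConfig",
    "TrainedClassifier",
    "split_classes",
    "train_cnn",
    "train_svm",
    "train_rf",
    "predict",
]


@dataclass(frozen=True)
class ClassSplit:
    """Disjoint activity-class partition; all images of a class stay together."""

    train_classes: tuple[str, ...]
    test_classes: tuple[str, ...]
    trial_seed: int

    def __post_init__(self) -> None:
        if set(self.train_classes) & set(self.test_classes):
            raise ValueError("train and test classes overlap")


def split_classes(names: list[str], seed: int, train_fraction: float | None = None) -> ClassSplit:
    """Uniform seeded half/half split of activity classes (19/19 at full scale).

    An odd class count is an error unless an explicit ``train_fraction`` is
    given.
    """
    names = list(names)
    if len(set(names)) != len(names):
        raise ValueError("class names must be unique")
    if train_fraction is None:
        if len(names) % 2:
            raise ValueError("odd class count: pass train_fraction explicitly")
        n_train = len(names) // 2
    else:
        n_train = int(round(train_fraction * len(names)))
        if not (0 < n_train < len(names)):
            raise ValueError("train_fraction leaves an empty side")
    order = np.random.default_rng(seed).permutation(len(names))
    train = tuple(sorted(names[i] for i in order[:n_train]))
    test = tuple(sorted(names[i] for i in order[n_train:]))
    return ClassSplit(train_classes=train, test_classes=test, trial_seed=seed)


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

#: Adam learning rates searched at full scale (divergent points are skipped).
FULL_LR_GRID = (100.0, 10.0, 1.0, 0.1, 0.01, 0.001, 0.005, 0.00005, 0.000005)


@dataclass(frozen=True)
class CNNConfig:
    """CNN architecture plus hyperparameter search grids.

    The full-scale architecture uses three 3×3 convolution blocks with 32,
    64 and 128 kernels; :meth:`desk_scale` shrinks channel counts and the
    search budget for laptop-scale runs.
    """

    conv_channels: tuple[int, ...] = (32, 64, 128)
    kernel: int = 3
    pool: int = 2
    alphas: tuple[float, ...] = (0.0, 0.1, 0.3, 0.5)
    dropouts: tuple[float, ...] = (0.0, 0.1, 0.3)
    dense_sizes: tuple[int, ...] = (16, 32, 64, 128)
    learning_rates: tuple[float, ...] = FULL_LR_GRID
    epochs: int = 50
    batch_size: int = 32
    patience: int = 5
    val_fraction: float = 0.2
    max_grid_points: int = 6  # random budget over the full grid

    @classmethod
    def desk_scale(cls) -> "CNNConfig":
        return cls(
            conv_channels=(8, 16, 32),
            alphas=(0.1,),
            dropouts=(0.1,),
            dense_sizes=(32, 16),
            learning_rates=(0.001,),
            epochs=40,
            batch_size=16,
            patience=8,
            max_grid_points=1,
        )


@dataclass(frozen=True)
class SVMConfig:
    costs: tuple[float, ...] = (0.01, 0.1, 1.0)
    kernels: tuple[str, ...] = ("linear", "poly", "rbf")
    n_folds: int = 10

    @classmethod
    def desk_scale(cls) -> "SVMConfig":
        """Full C × kernel grid, selection CV reduced to 3 folds."""
        return cls(n_folds=3)


@dataclass(frozen=True)
class RFConfig:
    n_trees: tuple[int, ...] = (50, 100)
    min_samples_split: tuple[int, ...] = (2, 5)
    min_samples_leaf: tuple[int, ...] = (1, 3)
    n_folds: int = 10


@dataclass
class TrainedClassifier:
    """Fitted model plus the hyperparameters the search selected."""

    kind: str  # "cnn" | "svm" | "rf"
    model: object
    labels: tuple[str, ...]
    hyperparameters: dict = field(default_factory=dict)
    log: dict = field(default_factory=dict)

    def predict_proba(self, inputs: np.ndarray) -> np.ndarray:
        if self.kind == "cnn":
            x = _as_image_tensor(inputs)
            if x.shape[1:] != self.model.input_shape:
                raise ValueError(
                    f"input encoding {x.shape[1:]} does not match "
                    f"training encoding {self.model.input_shape}"
                )
            return self.model.predict_proba(x)
        inputs = np.asarray(inputs, dtype=float)
        if inputs.ndim != 2 or inputs.shape[1] != self.log.get("n_features", inputs.shape[1]):
            raise ValueError("feature matrix does not match the training encoding")
        return self.model.predict_proba(inputs)


def predict(clf: TrainedClassifier, inputs: np.ndarray):
    """Per-input probability distribution and hard label (argmax, first-wins)."""
    probs = clf.predict_proba(inputs)
    hard = np.array([clf.labels[i] for i in probs.argmax(axis=1)])
    return probs, hard


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _as_image_tensor(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:  # (N, H, W) grayscale
        x = x[..., None]
    if x.ndim != 4:
        raise ValueError("CNN input must be (N, H, W[, C])")
    return x


def _encode_labels(y, labels: tuple[str, ...] | None):
    y = np.asarray(y)
    if labels is None:
        present = set(y)
        labels = tuple(l for l in VARIANT_LABELS if l in present) or tuple(sorted(present))
    index = {lab: i for i, lab in enumerate(labels)}
    return np.array([index[v] for v in y]), labels


def _cv_folds(n_folds: int, y: np.ndarray, seed: int) -> StratifiedKFold:
    smallest = np.bincount(y).min()
    k = max(2, min(n_folds, smallest))
    if k < n_folds:
        warnings.warn(f"reducing CV folds from {n_folds} to {k} (smallest class has {smallest})")
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_svm(
    features: np.ndarray,
    y,
    config: SVMConfig = SVMConfig(),
    seed: int = 0,
    labels: tuple[str, ...] | None = None,
) -> TrainedClassifier:
    """One-against-one SVM with a C × kernel grid by ten-fold cross-validation.

    Features are standardized with statistics from the training folds only
    (the scaler sits inside the CV pipeline).
    """
    features = np.asarray(features, dtype=float)
    y_idx, labels = _encode_labels(y, labels)
    if len(set(y_idx)) < 2:
        raise ValueError("SVM training needs at least 2 labels")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(decision_function_shape="ovo", random_state=seed)),
    ])
    grid = {"svc__C": list(config.costs), "svc__kernel": list(config.kernels)}
    search = GridSearchCV(pipe, grid, cv=_cv_folds(config.n_folds, y_idx, seed), n_jobs=1)
    search.fit(features, y_idx)
    # refit the selected point once with Platt-scaled probabilities
    best = Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(C=search.best_params_["svc__C"],
                    kernel=search.best_params_["svc__kernel"],
                    probability=True, decision_function_shape="ovo",
                    random_state=seed)),
    ])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        best.fit(features, y_idx)
    return TrainedClassifier(
        kind="svm",
        model=best,
        labels=labels,
        hyperparameters={"C": search.best_params_["svc__C"],
                         "kernel": search.best_params_["svc__kernel"]},
        log={"cv_results": {k: list(v) for k, v in search.cv_results_.items()
                            if k in ("params", "mean_test_score")},
             "n_features": features.shape[1]},
    )


def train_rf(
    features: np.ndarray,
    y,
    config: RFConfig = RFConfig(),
    seed: int = 0,
    labels: tuple[str, ...] | None = None,
) -> TrainedClassifier:
    """Random forest with an 8-point grid by ten-fold cross-validation."""
    features = np.asarray(features, dtype=float)
    y_idx, labels = _encode_labels(y, labels)
    if len(set(y_idx)) < 2:
        raise ValueError("RF training needs at least 2 labels")
    rf = RandomForestClassifier(random_state=seed)
    grid = {
        "n_estimators": list(config.n_trees),
        "min_samples_split": list(config.min_samples_split),
        "min_samples_leaf": list(config.min_samples_leaf),
    }
    search = GridSearchCV(rf, grid, cv=_cv_folds(config.n_folds, y_idx, seed), n_jobs=1)
    search.fit(features, y_idx)
    return TrainedClassifier(
        kind="rf",
        model=search.best_estimator_,
        labels=labels,
        hyperparameters=search.best_params_,
        log={"cv_results": {k: list(v) for k, v in search.cv_results_.items()
                            if k in ("params", "mean_test_score")},
             "n_features": features.shape[1]},
    )


def train_cnn(
    images: np.ndarray,
    y,
    config: CNNConfig = CNNConfig.desk_scale(),
    seed: int = 0,
    labels: tuple[str, ...] | None = None,
) -> TrainedClassifier:
    """Train the CNN, selecting hyperparameters on an internal 80/20 split.

    Candidate (alpha, dropout, dense sizes, learning rate) combinations are
    drawn from the configured grids up to ``max_grid_points``; candidates
    whose training diverges are scored as failed and skipped. The best
    candidate by validation accuracy is refit on all training images.
    """
    x = _as_image_tensor(images)
    y_idx, labels = _encode_labels(y, labels)
    if len(set(y_idx)) < 3:
        raise ValueError("CNN topology training expects all 3 labels present")

    full_grid = list(itertools.product(
        config.alphas, config.dropouts,
        itertools.combinations_with_replacement(sorted(config.dense_sizes, reverse=True), 2),
        config.learning_rates,
    ))
    rng = np.random.default_rng(seed)
    if len(full_grid) > config.max_grid_points:
        pick = rng.choice(len(full_grid), size=config.max_grid_points, replace=False)
        grid = [full_grid[i] for i in pick]
    else:
        grid = full_grid

    xtr, xval, ytr, yval = train_test_split(
        x, y_idx, test_size=config.val_fraction, random_state=seed, stratify=y_idx,
    )
    results = []
    for alpha, dropout, dense, lr in grid:
        net = TinyCNN(
            input_shape=x.shape[1:], n_classes=len(labels),
            conv_channels=config.conv_channels, kernel=config.kernel,
            pool=config.pool, alpha=alpha, dropout=dropout,
            dense_sizes=dense, seed=seed,
        )
        try:
            net.fit(xtr, ytr, xval, yval, lr=lr, epochs=config.epochs,
                    batch_size=config.batch_size, patience=config.patience)
            val_acc = float(np.mean(net.predict_proba(xval).argmax(axis=1) == yval))
        except DivergenceError:
            val_acc = -1.0  # failed grid point; search continues
        results.append({"alpha": alpha, "dropout": dropout, "dense": dense,
                        "lr": lr, "val_accuracy": val_acc})
    best = max(results, key=lambda r: r["val_accuracy"])
    if best["val_accuracy"] < 0:
        raise DivergenceError("all CNN grid points diverged")

    final = TinyCNN(
        input_shape=x.shape[1:], n_classes=len(labels),
        conv_channels=config.conv_channels, kernel=config.kernel,
        pool=config.pool, alpha=best["alpha"], dropout=best["dropout"],
        dense_sizes=best["dense"], seed=seed,
    )
    log = final.fit(x, y_idx, xval, yval, lr=best["lr"], epochs=config.epochs,
                    batch_size=config.batch_size, patience=config.patience)
    return TrainedClassifier(
        kind="cnn", model=final, labels=labels,
        hyperparameters={k: best[k] for k in ("alpha", "dropout", "dense", "lr")},
        log={"grid": results, "training": log},
    )
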