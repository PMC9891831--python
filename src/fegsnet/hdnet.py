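"""Cascade deep-forest classifier (HDnet-style).

Each cascade layer is an ensemble of 18 tree learners — six gradient-boosted
tree models, six random forests and six extremely-randomized-tree forests,
each with 20 trees / boosting rounds by default. A layer's 18 x 2 class
probabilities are appended to the input features ("augmentation") and feed
the next layer; during training the appended probabilities are out-of-fold
(internal stratified 3-fold cross-fitting) so no layer sees probabilities
produced by models fitted on the same rows. Training stops as soon as the
layer validation score (out-of-fold accuracy of the layer's mean-probability
vote) fails to improve on the best so far, or at ``max_layers``; the model is
truncated at the best-scoring layer. Prediction propagates through the kept
layers and returns the arithmetic mean of the final layer's 18 probability
vectors (mean and sum give the same argmax); a tie goes to the positive
class.

Learner diversity within a layer comes from distinct seeds; forests draw
random feature subsets per split anyway, and the boosted learners use 80%
row/column subsampling so that their seeds matter too. Binary labels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from xgboost import XGBClassifier

__all__ = [
    "LayerSpec",
    "CascadeConfig",
    "CascadeLayer",
    "CascadeModel",
    "fit_layer",
    "augment",
    "fit_cascade",
    "predict_proba",
    "predict",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class LayerSpec:
    """Composition of one cascade layer (defaults: 6+6+6 learners, 20 trees)."""

    n_boosted: int = 6
    n_rf: int = 6
    n_ert: int = 6
    trees_per_learner: int = 20
    xgb_max_depth: int = 3
    xgb_learning_rate: float = 0.3

    @property
    def n_learners(self) -> int:
        return self.n_boosted + self.n_rf + self.n_ert


@dataclass(frozen=True)
class CascadeConfig:
    """Cascade hyperparameters: layer spec, depth cap, patience, seed."""

    layer_spec: LayerSpec = field(default_factory=LayerSpec)
    max_layers: int = 10
    patience: int = 1
    oof_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_layers < 1:
            raise ValueError("max_layers must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def _make_learners(spec: LayerSpec, seeds: np.ndarray) -> list:
    """18 unfitted learners, seeded in fixed order (XGB, RF, ERT)."""
    learners: list = []
    k = 0
    for _ in range(spec.n_boosted):
        learners.append(
            XGBClassifier(
                n_estimators=spec.trees_per_learner,
                max_depth=spec.xgb_max_depth,
                learning_rate=spec.xgb_learning_rate,
                subsample=0.8,
                colsample_bytree=0.8,
                tree_method="hist",
                n_jobs=1,
                random_state=int(seeds[k]),
                eval_metric="logloss",
            )
        )
        k += 1
    for _ in range(spec.n_rf):
        learners.append(
            RandomForestClassifier(
                n_estimators=spec.trees_per_learner,
                n_jobs=1,
                random_state=int(seeds[k]),
            )
        )
        k += 1
    for _ in range(spec.n_ert):
        learners.append(
            ExtraTreesClassifier(
                n_estimators=spec.trees_per_learner,
                n_jobs=1,
                random_state=int(seeds[k]),
            )
        )
        k += 1
    return learners


@dataclass
class CascadeLayer:
    """One fitted layer: 18 learners trained on the full (augmented) input."""

    learners: list
    input_dim: int

    def probability_matrix(self, X: np.ndarray) -> np.ndarray:
        """n x (2 * n_learners) class probabilities, learner-major, classes
        in label order (0, 1)."""
        if X.shape[0] == 0:
            return np.empty((0, 2 * len(self.learners)))
        return np.hstack([est.predict_proba(X) for est in self.learners])

    def mean_proba(self, X: np.ndarray) -> np.ndarray:
        probs = self.probability_matrix(X)
        return probs.reshape(X.shape[0], len(self.learners), 2).mean(axis=1)


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"labels must contain both classes 0 and 1, got {classes}")
    return y


def fit_layer(
    X: np.ndarray,
    y: np.ndarray,
    spec: LayerSpec,
    seed: int,
    oof_folds: int = 3,
) -> tuple[CascadeLayer, np.ndarray]:
    """Fit one layer; return it plus the out-of-fold probability matrix.

    Each learner is cross-fitted on ``oof_folds`` stratified folds to produce
    leak-free probabilities for augmentation, then refitted on all rows for
    prediction time.
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=spec.n_learners + 1)
    learners = _make_learners(spec, seeds)
    cv = StratifiedKFold(n_splits=oof_folds, shuffle=True, random_state=int(seeds[-1]))
    oof_blocks = []
    for est in learners:
        oof_blocks.append(
            cross_val_predict(clone(est), X, y, cv=cv, method="predict_proba", n_jobs=1)
        )
        est.fit(X, y)
    return CascadeLayer(learners=learners, input_dim=X.shape[1]), np.hstack(oof_blocks)


def augment(features: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Append the probability columns to the feature block (pure concatenation)."""
    features = np.asarray(features, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if features.shape[0] != probs.shape[0]:
        raise ValueError(
            f"row mismatch: {features.shape[0]} feature rows vs {probs.shape[0]}"
            " probability rows"
        )
    return np.hstack([features, probs])


@dataclass
class CascadeModel:
    """A trained cascade: kept layers, their validation history, and config."""

    layers: list[CascadeLayer]
    input_dim: int
    history: list[float]
    stop_layer: int
    config: CascadeConfig

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def _oof_vote_accuracy(oof_probs: np.ndarray, y: np.ndarray, n_learners: int) -> float:
    mean = oof_probs.reshape(len(y), n_learners, 2).mean(axis=1)
    pred = (mean[:, 1] >= mean[:, 0]).astype(int)
    return float(np.mean(pred == y))


def fit_cascade(X: np.ndarray, y: np.ndarray, config: CascadeConfig | None = None) -> CascadeModel:
    """Grow the cascade layer by layer until the validation score stops
    improving (patience layers without a new best) or ``max_layers`` is hit,
    then truncate at the best layer."""
    if config is None:
        config = CascadeConfig()
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    spec = config.layer_spec
    rng = np.random.default_rng(config.seed)
    layer_seeds = rng.integers(0, 2**31 - 1, size=config.max_layers)

    layers: list[CascadeLayer] = []
    history: list[float] = []
    current = X
    best = -np.inf
    stale = 0
    for depth in range(config.max_layers):
        layer, oof = fit_layer(
            current, y, spec, seed=int(layer_seeds[depth]), oof_folds=config.oof_folds
        )
        score = _oof_vote_accuracy(oof, y, spec.n_learners)
        layers.append(layer)
        history.append(score)
        if score > best:
            best = score
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
        current = augment(current, oof)
    stop_layer = int(np.argmax(history))
    return CascadeModel(
        layers=layers[: stop_layer + 1],
        input_dim=X.shape[1],
        history=history,
        stop_layer=stop_layer,
        config=config,
    )


def predict_proba(model: CascadeModel, X: np.ndarray) -> np.ndarray:
    """n x 2 class probabilities from the final kept layer (mean over its
    learners); rows sum to 1."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValueError(
            f"feature width mismatch: model expects {model.input_dim} columns,"
            f" got {X.shape[1] if X.ndim == 2 else X.shape}"
        )
    current = X
    for layer in model.layers[:-1]:
        current = augment(current, layer.probability_matrix(current))
    return model.layers[-1].mean_proba(current)


def predict(model: CascadeModel, X: np.ndarray) -> np.ndarray:
    """Predicted labels; a tie in probability goes to the positive class."""
    proba = predict_proba(model, X)
    return (proba[:, 1] >= proba[:, 0]).astype(int)


def save_model(model: CascadeModel, path: str | Path, layout=None) -> None:
    """Persist the cascade plus its feature layout in a joblib archive."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "model": model,
        "layout": layout,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path, expected_layout=None) -> tuple[CascadeModel, object]:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot load model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"{path}: not a recognised model archive")
    model, layout = payload["model"], payload.get("layout")
    if expected_layout is not None and layout is not None:
        if tuple(layout.columns) != tuple(expected_layout.columns):
            raise ValueError(
                "feature layout mismatch between model archive and requested"
                f" descriptor ({layout.descriptor!r} vs {expected_layout.descriptor!r})"
            )
    return model, layout


def single_layer_config(seed: int = 0, **kwargs) -> CascadeConfig:
    """Convenience: a one-layer cascade, i.e. a plain 18-learner ensemble."""
    return replace(CascadeConfig(seed=seed, **kwargs), max_layers=1)
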