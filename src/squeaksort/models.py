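"""The classifier zoo: CNN, MLPs, stacking/auto-context ensembles, SVM
one-vs-all / one-vs-one ensembles, and random forests.

Each model exists in two forms: a declarative, serializable spec dataclass
carrying the published hyperparameters, and an sklearn-style estimator
(``fit`` / ``predict`` / ``predict_proba``, ``get_params``/``set_params``,
fitted attributes with trailing underscores).  ``build_model`` turns a spec
into its estimator.  Numerical-feature models take the standardized
20-feature matrix; the CNN takes fixed-size spectrogram images (N, H, W).

The CNN: five stride-1 convolution blocks of 32/64/64/128/128 filters with
7x7, 5x5 then 3x3 kernels, each followed by 3x3 max pooling with stride 2;
dropout (rates 0.2-0.5) after every block but the first; a 1024-unit ReLU
dense layer with 0.5 dropout and batch normalization; a softmax output.
Trained with Adam (lr 1e-3, batch 32) under class-weighted categorical
cross-entropy.  MLPs use tanh hidden layers, softmax output, lr 1e-4, 500
epochs, full-batch updates.  SVM ensembles use RBF kernels with C=5000 and
gamma=5e-4 in the best setting; OVA decides by maximum confidence, OVO by
majority vote with ties going to the lowest class index.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import _nn
from .balance import compute_class_weights

__all__ = [
    "CnnSpec",
    "MlpSpec",
    "EnsembleSpec",
    "SvmEnsembleSpec",
    "RfSpec",
    "MLP_HIDDEN_CONFIGS",
    "CnnClassifier",
    "MlpClassifier",
    "StackingMlpClassifier",
    "AutoContextMlpClassifier",
    "SvmOvaClassifier",
    "SvmOvoClassifier",
    "build_model",
    "train_model",
    "spec_to_dict",
    "spec_from_dict",
    "predict_ova",
    "predict_ovo",
    "grid_search_svm",
    "default_search_space",
    "search_space_size",
]

#: The five tested MLP hidden-layer configurations.
MLP_HIDDEN_CONFIGS: tuple[tuple[int, ...], ...] = (
    (32, 64),
    (32, 64, 128),
    (32, 64, 128, 256),
    (32, 64, 128, 128, 64, 32),
    (16, 32, 128, 128, 32),
)


# ---------------------------------------------------------------------------
# declarative specs
# ---------------------------------------------------------------------------


@dataclass
class CnnSpec:
    """CNN topology and training hyperparameters."""

    input_shape: tuple[int, int] = (192, 834)
    filters: tuple[int, ...] = (32, 64, 64, 128, 128)
    kernels: tuple[tuple[int, int], ...] = ((7, 7), (5, 5), (3, 3), (3, 3), (3, 3))
    pool: int = 3
    pool_stride: int = 2
    conv_dropout: tuple[float, ...] = (0.0, 0.2, 0.3, 0.4, 0.5)
    dense_units: int = 1024
    dense_dropout: float = 0.5
    n_classes: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 200
    seed: int = 0

    def validate(self) -> None:
        if len(self.filters) != 5 or len(self.kernels) != 5:
            raise ValueError("the CNN has exactly 5 convolutional blocks")
        if len(self.conv_dropout) != len(self.filters):
            raise ValueError("one dropout rate per block (first must be 0)")
        if self.conv_dropout[0] != 0.0:
            raise ValueError("no dropout after the first block")


@dataclass
class MlpSpec:
    """One fully connected network on the 20 standard features."""

    hidden_layers: tuple[int, ...] = (32, 64, 128)
    n_features: int = 20
    n_classes: int = 10
    learning_rate: float = 1e-4
    epochs: int = 500
    seed: int = 0

    def validate(self) -> None:
        if not self.hidden_layers:
            raise ValueError("at least one hidden layer required")


@dataclass
class EnsembleSpec:
    """Stacking or auto-context ensemble of MLP base learners.

    Stacking feeds the concatenated base outputs (5 x 10 = 50 inputs) into a
    (1024, 128, 32) meta learner; auto-context feeds the outputs of base
    configurations 2-4 plus the original 20 features (3 x 10 + 20 = 50)
    into a (128, 128) meta learner.
    """

    kind: str = "stacking"  # or "auto_context"
    base: tuple[MlpSpec, ...] = ()
    meta_hidden: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("stacking", "auto_context"):
            raise ValueError(f"kind must be stacking or auto_context: {self.kind}")
        if not self.base:
            configs = (
                MLP_HIDDEN_CONFIGS
                if self.kind == "stacking"
                else MLP_HIDDEN_CONFIGS[1:4]
            )
            self.base = tuple(MlpSpec(hidden_layers=h) for h in configs)
        if not self.meta_hidden:
            self.meta_hidden = (
                (1024, 128, 32) if self.kind == "stacking" else (128, 128)
            )

    def validate(self) -> None:
        n_base = 5 if self.kind == "stacking" else 3
        if len(self.base) != n_base:
            raise ValueError(f"{self.kind} uses {n_base} base learners")


@dataclass
class SvmEnsembleSpec:
    """SVM multiclass ensemble (best published setting by default)."""

    scheme: str = "ova"  # or "ovo"
    kernel: str = "rbf"
    C: float = 5000.0
    gamma: float = 0.0005
    pca_components: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.scheme not in ("ova", "ovo"):
            raise ValueError(f"scheme must be ova or ovo: {self.scheme}")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


@dataclass
class RfSpec:
    """Random forest on the 20 standard features (no PCA)."""

    n_trees: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees <= 0:
            raise ValueError("n_trees must be > 0")


# ---------------------------------------------------------------------------
# neural estimators
# ---------------------------------------------------------------------------


class _NetClassifierBase(ClassifierMixin, BaseEstimator):
    """Shared fit/predict plumbing over the numpy network engine."""

    def _encode_y(self, y):
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        return y_idx

    def _class_weight_array(self, y_idx, n_classes):
        if getattr(self, "class_weight", None) is None:
            return None
        counts = np.bincount(y_idx, minlength=n_classes)
        weights = compute_class_weights(
            {i: int(c) for i, c in enumerate(counts) if c > 0}
        )
        arr = np.ones(n_classes)
        for i, w in weights.items():
            arr[i] = w
        return arr

    def predict_proba(self, X):
        X = self._prepare(np.asarray(X, dtype=np.float32))
        return self.network_.predict_proba(X)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def _prepare(self, X):
        return X


class MlpClassifier(_NetClassifierBase):
    """Tanh multilayer perceptron with softmax output.

    Trained with Adam at the configured learning rate, feeding the whole
    training set each epoch (full-batch) unless ``batch_size`` is set.
    """

    def __init__(
        self,
        hidden_layers: tuple[int, ...] = (32, 64, 128),
        learning_rate: float = 1e-4,
        epochs: int = 500,
        batch_size: int | None = None,
        class_weight: str | None = None,
        random_state: int = 0,
    ) -> None:
        self.hidden_layers = hidden_layers
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2:
            raise ValueError("MlpClassifier expects a 2-D feature matrix")
        y_idx = self._encode_y(y)
        n_classes = self.classes_.size
        rng = np.random.default_rng(self.random_state)
        layers: list[_nn.Layer] = []
        n_in = X.shape[1]
        for width in self.hidden_layers:
            layers += [_nn.Dense(n_in, width, rng), _nn.Tanh()]
            n_in = width
        layers.append(_nn.Dense(n_in, n_classes, rng))
        self.network_ = _nn.Network(layers)
        self.history_ = self.network_.fit(
            X,
            y_idx,
            epochs=self.epochs,
            batch_size=self.batch_size or X.shape[0],
            optimizer=_nn.Adam(lr=self.learning_rate),
            rng=rng,
            class_weight=self._class_weight_array(y_idx, n_classes),
        )
        return self


class CnnClassifier(_NetClassifierBase):
    """Convolutional classifier over fixed-size spectrogram images.

    ``X`` is (n, H, W) grayscale in [0, 1].  ``class_weight="balanced"``
    (the default) trains with inverse-frequency class weights.
    """

    def __init__(
        self,
        input_shape: tuple[int, int] = (192, 834),
        filters: tuple[int, ...] = (32, 64, 64, 128, 128),
        kernels: tuple[tuple[int, int], ...] = (
            (7, 7), (5, 5), (3, 3), (3, 3), (3, 3),
        ),
        pool: int = 3,
        pool_stride: int = 2,
        conv_dropout: tuple[float, ...] = (0.0, 0.2, 0.3, 0.4, 0.5),
        dense_units: int = 1024,
        dense_dropout: float = 0.5,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        epochs: int = 200,
        class_weight: str | None = "balanced",
        random_state: int = 0,
    ) -> None:
        self.input_shape = input_shape
        self.filters = filters
        self.kernels = kernels
        self.pool = pool
        self.pool_stride = pool_stride
        self.conv_dropout = conv_dropout
        self.dense_units = dense_units
        self.dense_dropout = dense_dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.class_weight = class_weight
        self.random_state = random_state

    def layer_table(self, n_classes: int = 10) -> list[dict]:
        """Static architecture description with output shapes (H, W, C)."""
        h, w = self.input_shape
        rows = []
        c_in = 1
        for i, (n_filt, kernel) in enumerate(zip(self.filters, self.kernels)):
            rows.append(
                {"layer": f"conv{i + 1}", "kernel": kernel, "filters": n_filt,
                 "out_shape": (h, w, n_filt)}
            )
            h = -(-h // self.pool_stride)
            w = -(-w // self.pool_stride)
            rows.append(
                {"layer": f"maxpool{i + 1}", "kernel": (self.pool, self.pool),
                 "out_shape": (h, w, n_filt)}
            )
            if self.conv_dropout[i] > 0:
                rows.append(
                    {"layer": f"dropout{i + 1}", "rate": self.conv_dropout[i],
                     "out_shape": (h, w, n_filt)}
                )
            c_in = n_filt
        flat = h * w * c_in
        rows.append({"layer": "flatten", "out_shape": (flat,)})
        rows.append({"layer": "dense1", "units": self.dense_units,
                     "out_shape": (self.dense_units,)})
        rows.append({"layer": "dropout_dense", "rate": self.dense_dropout,
                     "out_shape": (self.dense_units,)})
        rows.append({"layer": "batchnorm", "out_shape": (self.dense_units,)})
        rows.append({"layer": "dense2", "units": n_classes,
                     "out_shape": (n_classes,)})
        return rows

    def _build(self, n_classes: int, rng: np.random.Generator) -> _nn.Network:
        layers: list[_nn.Layer] = []
        c_in = 1
        for i, (n_filt, kernel) in enumerate(zip(self.filters, self.kernels)):
            layers += [
                _nn.Conv2D(kernel, c_in, n_filt, rng),
                _nn.ReLU(),
                _nn.MaxPool2D(self.pool, self.pool_stride),
            ]
            if self.conv_dropout[i] > 0:
                layers.append(_nn.Dropout(self.conv_dropout[i], rng))
            c_in = n_filt
        h, w = self.input_shape
        for _ in self.filters:
            h = -(-h // self.pool_stride)
            w = -(-w // self.pool_stride)
        layers += [
            _nn.Flatten(),
            _nn.Dense(h * w * c_in, self.dense_units, rng),
            _nn.ReLU(),
            _nn.Dropout(self.dense_dropout, rng),
            _nn.BatchNorm(self.dense_units),
            _nn.Dense(self.dense_units, n_classes, rng),
        ]
        layers[0].input_grad = False  # nothing upstream needs dx
        return _nn.Network(layers)

    def _prepare(self, X):
        if X.ndim == 4 and X.shape[-1] == 1:
            X = X[..., 0]
        if X.ndim != 3 or X.shape[1:] != tuple(self.input_shape):
            raise ValueError(
                f"expected images of shape {self.input_shape}, got {X.shape[1:]}"
            )
        return X[..., None]

    def fit(self, X, y):
        if len(self.conv_dropout) != len(self.filters) or self.conv_dropout[0] != 0:
            raise ValueError(
                "conv_dropout needs one rate per block, 0 for the first"
            )
        X = self._prepare(np.asarray(X, dtype=np.float32))
        y_idx = self._encode_y(y)
        n_classes = self.classes_.size
        rng = np.random.default_rng(self.random_state)
        self.network_ = self._build(n_classes, rng)
        self.history_ = self.network_.fit(
            X,
            y_idx,
            epochs=self.epochs,
            batch_size=self.batch_size,
            optimizer=_nn.Adam(lr=self.learning_rate),
            rng=rng,
            class_weight=self._class_weight_array(y_idx, n_classes),
        )
        return self


class _MetaEnsembleBase(ClassifierMixin, BaseEstimator):
    """Base-learner + meta-learner ensemble.

    The meta learner is trained on the base learners' out-of-fold
    predictions over the training set, so it never sees base outputs on
    data those learners were fitted on.
    """

    _with_features = False

    def _base_estimators(self):
        return [
            MlpClassifier(
                hidden_layers=h,
                learning_rate=self.learning_rate,
                epochs=self.epochs,
                random_state=self.random_state + i,
            )
            for i, h in enumerate(self.base_configs)
        ]

    def _meta_features(self, X, base_probas):
        parts = list(base_probas)
        if self._with_features:
            parts.append(np.asarray(X, dtype=float))
        return np.hstack(parts)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        self.classes_ = np.unique(y)
        n_classes = self.classes_.size
        bases = self._base_estimators()
        skf = StratifiedKFold(
            n_splits=self.n_oof_folds, shuffle=True,
            random_state=self.random_state,
        )
        oof = [np.zeros((X.shape[0], n_classes)) for _ in bases]
        for train_idx, val_idx in skf.split(X, y):
            for k, base in enumerate(bases):
                m = clone(base).fit(X[train_idx], np.asarray(y)[train_idx])
                proba = m.predict_proba(X[val_idx])
                cols = np.searchsorted(self.classes_, m.classes_)
                oof[k][np.ix_(val_idx, cols)] = proba
        meta_X = self._meta_features(X, oof)
        self.meta_ = MlpClassifier(
            hidden_layers=self.meta_hidden,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            random_state=self.random_state + 1000,
        ).fit(meta_X, y)
        # refit base learners on the full training set for inference
        self.base_ = [b.fit(X, y) for b in bases]
        return self

    def _meta_input(self, X):
        X = np.asarray(X, dtype=np.float32)
        probas = []
        for b in self.base_:
            proba = b.predict_proba(X)
            full = np.zeros((X.shape[0], self.classes_.size))
            cols = np.searchsorted(self.classes_, b.classes_)
            full[:, cols] = proba
            probas.append(full)
        return self._meta_features(X, probas)

    def predict_proba(self, X):
        return self.meta_.predict_proba(self._meta_input(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class StackingMlpClassifier(_MetaEnsembleBase):
    """Stacking: all five MLPs feed a (1024, 128, 32) meta learner."""

    _with_features = False

    def __init__(
        self,
        base_configs: tuple[tuple[int, ...], ...] = MLP_HIDDEN_CONFIGS,
        meta_hidden: tuple[int, ...] = (1024, 128, 32),
        learning_rate: float = 1e-4,
        epochs: int = 500,
        n_oof_folds: int = 5,
        random_state: int = 0,
    ) -> None:
        self.base_configs = base_configs
        self.meta_hidden = meta_hidden
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.n_oof_folds = n_oof_folds
        self.random_state = random_state


class AutoContextMlpClassifier(_MetaEnsembleBase):
    """Auto-context: base outputs of MLP configs 2-4 plus the original
    20 features feed a (128, 128) meta learner."""

    _with_features = True

    def __init__(
        self,
        base_configs: tuple[tuple[int, ...], ...] = MLP_HIDDEN_CONFIGS[1:4],
        meta_hidden: tuple[int, ...] = (128, 128),
        learning_rate: float = 1e-4,
        epochs: int = 500,
        n_oof_folds: int = 5,
        random_state: int = 0,
    ) -> None:
        self.base_configs = base_configs
        self.meta_hidden = meta_hidden
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.n_oof_folds = n_oof_folds
        self.random_state = random_state


# ---------------------------------------------------------------------------
# SVM ensembles
# ---------------------------------------------------------------------------

_KERNEL_ALIASES = {"polynomial": "poly", "gaussian": "rbf"}


def _svc(kernel: str, C: float, gamma: float, random_state: int) -> SVC:
    return SVC(
        kernel=_KERNEL_ALIASES.get(kernel, kernel),
        C=C,
        gamma=gamma,
        random_state=random_state,
    )


def predict_ova(confidences: np.ndarray) -> np.ndarray:
    """Maximum-confidence decision: argmax per row (ties -> lowest index)."""
    confidences = np.atleast_2d(confidences)
    return np.argmax(confidences, axis=1)


def predict_ovo(pairwise_winners, n_classes: int) -> int:
    """Majority vote over one winner per unordered class pair.

    ``pairwise_winners`` holds the winning class index of each of the
    ``n_classes * (n_classes - 1) / 2`` pairs; ties go to the lowest index.
    """
    votes = np.bincount(np.asarray(list(pairwise_winners)), minlength=n_classes)
    return int(np.argmax(votes))


class SvmOvaClassifier(ClassifierMixin, BaseEstimator):
    """One-vs-all SVM ensemble: one binary SVC per class, decision by
    maximum confidence (largest decision-function value)."""

    def __init__(
        self,
        kernel: str = "rbf",
        C: float = 5000.0,
        gamma: float = 0.0005,
        random_state: int = 0,
    ) -> None:
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.estimators_ = []
        for c in self.classes_:
            m = _svc(self.kernel, self.C, self.gamma, self.random_state)
            m.fit(X, (y == c).astype(int))
            self.estimators_.append(m)
        self.n_classifiers_ = len(self.estimators_)
        return self

    def decision_function(self, X):
        return np.column_stack([m.decision_function(X) for m in self.estimators_])

    def predict(self, X):
        return self.classes_[predict_ova(self.decision_function(X))]

    def predict_proba(self, X):
        """Softmax over per-class confidences (a convenience mapping; the
        decision rule itself is maximum confidence)."""
        return _nn.softmax(self.decision_function(X))


class SvmOvoClassifier(ClassifierMixin, BaseEstimator):
    """One-vs-one SVM ensemble: one binary SVC per unordered class pair,
    decision by majority vote (ties -> lowest class index)."""

    def __init__(
        self,
        kernel: str = "rbf",
        C: float = 5000.0,
        gamma: float = 0.0005,
        random_state: int = 0,
    ) -> None:
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.pairs_ = list(itertools.combinations(range(self.classes_.size), 2))
        self.estimators_ = []
        for i, j in self.pairs_:
            mask = (y == self.classes_[i]) | (y == self.classes_[j])
            m = _svc(self.kernel, self.C, self.gamma, self.random_state)
            m.fit(X[mask], (y[mask] == self.classes_[j]).astype(int))
            self.estimators_.append(m)
        self.n_classifiers_ = len(self.estimators_)
        return self

    def _votes(self, X):
        X = np.asarray(X)
        votes = np.zeros((X.shape[0], self.classes_.size), dtype=int)
        for (i, j), m in zip(self.pairs_, self.estimators_):
            pred = m.predict(X)
            votes[pred == 0, i] += 1
            votes[pred == 1, j] += 1
        return votes

    def predict(self, X):
        return self.classes_[np.argmax(self._votes(X), axis=1)]

    def predict_proba(self, X):
        """Vote shares per class (rows sum to 1)."""
        votes = self._votes(X)
        return votes / votes.sum(axis=1, keepdims=True)


def default_search_space() -> dict:
    """The full SVM grid: 4 kernels x 6 gammas x 8 Cs x 8 PCA options."""
    return {
        "kernel": ["rbf", "linear", "polynomial", "sigmoid"],
        "gamma": [0.0001, 0.0005, 0.001, 0.005, 0.01, 0.1],
        "C": [1, 10, 50, 100, 1000, 5000, 10000, 100000],
        "pca_components": [None, 15, 13, 11, 9, 7, 5, 3],
    }


def search_space_size(space: dict) -> int:
    size = 1
    for values in space.values():
        size *= len(values)
    return size


def grid_search_svm(
    X_train,
    y_train,
    space: dict | None = None,
    scheme: str = "ova",
    folds: int = 5,
    seed: int = 0,
) -> tuple[SvmEnsembleSpec, pd.DataFrame]:
    """Exhaustive SVM grid search with stratified k-fold CV.

    Run on the training split only.  Returns the best spec (highest mean CV
    accuracy; first in grid order on ties) and the full CV table.
    """
    space = space or default_search_space()
    if any(len(v) == 0 for v in space.values()) or not space:
        raise ValueError("search space must be non-empty")
    X_train = np.asarray(X_train)
    y_train = np.asarray(y_train)
    keys = list(space.keys())
    records = []
    best: tuple[float, SvmEnsembleSpec] | None = None
    cls = SvmOvaClassifier if scheme == "ova" else SvmOvoClassifier
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for combo in itertools.product(*(space[k] for k in keys)):
        params = dict(zip(keys, combo))
        pca_dim = params.pop("pca_components", None)
        accs = []
        for tr, va in skf.split(X_train, y_train):
            Xtr, Xva = X_train[tr], X_train[va]
            if pca_dim is not None:
                pca = PCA(n_components=pca_dim, random_state=seed)
                Xtr = pca.fit_transform(Xtr)
                Xva = pca.transform(Xva)
            model = cls(random_state=seed, **params).fit(Xtr, y_train[tr])
            accs.append(float(np.mean(model.predict(Xva) == y_train[va])))
        mean_acc = float(np.mean(accs))
        spec = SvmEnsembleSpec(
            scheme=scheme, pca_components=pca_dim, seed=seed, **params
        )
        records.append(
            {**dict(zip(keys, combo)), "mean_cv_accuracy": mean_acc}
        )
        if best is None or mean_acc > best[0]:
            best = (mean_acc, spec)
    return best[1], pd.DataFrame(records)


# ---------------------------------------------------------------------------
# spec -> estimator
# ---------------------------------------------------------------------------


def build_model(spec):
    """Instantiate the estimator described by a spec dataclass."""
    spec.validate() if hasattr(spec, "validate") else None
    if isinstance(spec, CnnSpec):
        return CnnClassifier(
            input_shape=spec.input_shape,
            filters=spec.filters,
            kernels=spec.kernels,
            pool=spec.pool,
            pool_stride=spec.pool_stride,
            conv_dropout=spec.conv_dropout,
            dense_units=spec.dense_units,
            dense_dropout=spec.dense_dropout,
            learning_rate=spec.learning_rate,
            batch_size=spec.batch_size,
            epochs=spec.epochs,
            random_state=spec.seed,
        )
    if isinstance(spec, MlpSpec):
        return MlpClassifier(
            hidden_layers=spec.hidden_layers,
            learning_rate=spec.learning_rate,
            epochs=spec.epochs,
            random_state=spec.seed,
        )
    if isinstance(spec, EnsembleSpec):
        cls = (
            StackingMlpClassifier
            if spec.kind == "stacking"
            else AutoContextMlpClassifier
        )
        return cls(
            base_configs=tuple(b.hidden_layers for b in spec.base),
            meta_hidden=spec.meta_hidden,
            random_state=spec.seed,
        )
    if isinstance(spec, SvmEnsembleSpec):
        cls = SvmOvaClassifier if spec.scheme == "ova" else SvmOvoClassifier
        return cls(
            kernel=spec.kernel, C=spec.C, gamma=spec.gamma,
            random_state=spec.seed,
        )
    if isinstance(spec, RfSpec):
        return RandomForestClassifier(
            n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1
        )
    raise TypeError(f"unknown model spec type {type(spec).__name__}")


_SPEC_TYPES = {}


def spec_to_dict(spec) -> dict:
    """Serialize a model spec to a plain dict (YAML/JSON friendly)."""
    from dataclasses import asdict

    payload = asdict(spec)
    payload["model_type"] = type(spec).__name__
    return payload


def spec_from_dict(payload: dict):
    """Inverse of :func:`spec_to_dict`."""
    payload = dict(payload)
    name = payload.pop("model_type")
    cls = _SPEC_TYPES[name]
    if cls is EnsembleSpec and payload.get("base"):
        payload["base"] = tuple(
            MlpSpec(**{**b, "hidden_layers": tuple(b["hidden_layers"])})
            for b in payload["base"]
        )
    for key in ("input_shape", "filters", "kernels", "conv_dropout",
                "hidden_layers", "meta_hidden"):
        if key in payload and isinstance(payload[key], list):
            payload[key] = tuple(
                tuple(v) if isinstance(v, list) else v for v in payload[key]
            )
    return cls(**payload)


_SPEC_TYPES.update(
    {c.__name__: c for c in (CnnSpec, MlpSpec, EnsembleSpec, SvmEnsembleSpec,
                             RfSpec)}
)


def train_model(model, X_train, y_train, balance: str = "none", seed: int = 0):
    """Fit ``model`` on the training split under a balance strategy.

    ``balance``: "none", "oversample", "downsample" (resample the training
    rows) or "class_weights" (set inverse-frequency weights on estimators
    that support them).  Resampling never touches anything but the given
    training split.
    """
    from .balance import random_downsample, random_oversample

    X_train = np.asarray(X_train)
    y_train = np.asarray(y_train)
    if balance == "oversample":
        X_train, y_train = random_oversample(X_train, y_train, seed)
    elif balance == "downsample":
        X_train, y_train = random_downsample(X_train, y_train, seed)
    elif balance == "class_weights":
        if hasattr(model, "class_weight"):
            model.set_params(class_weight="balanced")
    elif balance != "none":
        raise ValueError(f"unknown balance strategy {balance!r}")
    return model.fit(X_train, y_train)
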