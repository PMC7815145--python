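"""Cross-validated evaluation with per-class precision/recall and
row-normalized confusion matrices.

The evaluation protocol: 10-fold cross-validation for the test sets, with
the remaining data of each fold split 80/20 into training and validation
(the validation part is held out for monitoring; the models here train
without early stopping).  A literal repeated-80/20-holdout scheme is
available via ``SplitPlan(scheme="holdout")``.  Folds are stratified by
class by default — the defensible choice for strongly imbalanced data.

Metric conventions: confusion rows are ground truth, columns predictions;
per-class precision = diagonal / column sum, recall = diagonal / row sum,
accuracy = trace / total.  Headline precision/recall are macro averages
over classes with a nonzero denominator.  Row-normalized confusion rows sum
to 1 for every class present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import (
    KFold,
    StratifiedKFold,
    StratifiedShuffleSplit,
    train_test_split,
)

from .balance import random_downsample, random_oversample
from .features import FEATURE_NAMES, FeatureStandardizer
from .models import CnnSpec, build_model
from .synth import CLASS_NAMES

__all__ = [
    "SplitPlan",
    "Fold",
    "Metrics",
    "EvaluationReport",
    "make_folds",
    "compute_metrics",
    "normalize_confusion",
    "run_experiment",
]


@dataclass(frozen=True)
class SplitPlan:
    """How to split data for evaluation."""

    n_folds: int = 10
    val_fraction: float = 0.2
    stratified: bool = True
    seed: int = 0
    scheme: str = "cv"  # "cv" (k-fold) or "holdout" (repeated 80/20)

    def __post_init__(self) -> None:
        if self.scheme not in ("cv", "holdout"):
            raise ValueError("scheme must be 'cv' or 'holdout'")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must be in [0, 1)")


class Fold(NamedTuple):
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def make_folds(labels: Sequence, plan: SplitPlan | None = None) -> list[Fold]:
    """Index triples (train, val, test) for each fold.

    In "cv" mode the test sets partition the data; in "holdout" mode each
    fold is an independent stratified 80/20 split.  Deterministic given the
    plan seed.
    """
    plan = plan or SplitPlan()
    labels = np.asarray(labels)
    n = labels.size
    if plan.stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < plan.n_folds:
            raise ValueError(
                f"smallest class has {counts.min()} samples; stratified "
                f"splitting needs at least n_folds={plan.n_folds}"
            )
    if plan.scheme == "cv":
        splitter = (
            StratifiedKFold(plan.n_folds, shuffle=True, random_state=plan.seed)
            if plan.stratified
            else KFold(plan.n_folds, shuffle=True, random_state=plan.seed)
        )
        outer = splitter.split(np.zeros(n), labels)
    else:
        splitter = StratifiedShuffleSplit(
            n_splits=plan.n_folds, test_size=0.2, random_state=plan.seed
        )
        outer = splitter.split(np.zeros(n), labels)
    folds = []
    for k, (rest_idx, test_idx) in enumerate(outer):
        if plan.val_fraction > 0:
            train_idx, val_idx = train_test_split(
                rest_idx,
                test_size=plan.val_fraction,
                random_state=plan.seed + k,
                stratify=labels[rest_idx] if plan.stratified else None,
            )
        else:
            train_idx, val_idx = rest_idx, np.array([], dtype=int)
        folds.append(
            Fold(np.sort(train_idx), np.sort(val_idx), np.sort(test_idx))
        )
    return folds


@dataclass
class Metrics:
    """Macro precision/recall and accuracy of one confusion matrix."""

    precision: float
    recall: float
    accuracy: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray


def compute_metrics(confusion: np.ndarray) -> Metrics:
    """Metrics from a K x K count matrix (rows truth, columns predictions).

    Macro means skip classes whose denominator is zero (never observed for
    precision's column sums, or never present for recall's row sums).
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion must be square")
    if np.any(confusion < 0):
        raise ValueError("confusion counts must be nonnegative")
    total = confusion.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zeros")
    diag = np.diag(confusion)
    col = confusion.sum(axis=0)
    row = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / np.where(col > 0, col, 1), np.nan)
        recall = np.where(row > 0, diag / np.where(row > 0, row, 1), np.nan)
    return Metrics(
        precision=float(np.nanmean(precision)),
        recall=float(np.nanmean(recall)),
        accuracy=float(diag.sum() / total),
        per_class_precision=precision,
        per_class_recall=recall,
    )


def normalize_confusion(confusion: np.ndarray) -> np.ndarray:
    """Row-normalize counts so each present class's row sums to 1
    (rows of absent classes stay all zero)."""
    confusion = np.asarray(confusion, dtype=float)
    row = confusion.sum(axis=1, keepdims=True)
    return np.divide(confusion, row, out=np.zeros_like(confusion), where=row > 0)


@dataclass
class EvaluationReport:
    """Per-fold and aggregate results of one cross-validated run."""

    scope: str
    class_names: tuple[str, ...]
    fold_metrics: list[Metrics]
    confusion: np.ndarray  # counts, summed over folds
    val_accuracy: list[float] = field(default_factory=list)

    @property
    def confusion_normalized(self) -> np.ndarray:
        return normalize_confusion(self.confusion)

    def _agg(self, attr: str) -> tuple[float, float]:
        vals = np.array([getattr(m, attr) for m in self.fold_metrics])
        return float(vals.mean()), float(vals.std())

    @property
    def accuracy(self) -> tuple[float, float]:
        """(mean, sd) over folds."""
        return self._agg("accuracy")

    @property
    def precision(self) -> tuple[float, float]:
        return self._agg("precision")

    @property
    def recall(self) -> tuple[float, float]:
        return self._agg("recall")

    @property
    def per_class_recall(self) -> np.ndarray:
        """Recall per class from the pooled confusion counts."""
        return compute_metrics(self.confusion).per_class_recall

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "classes": list(self.class_names),
            "n_folds": len(self.fold_metrics),
            "accuracy_mean": self.accuracy[0],
            "accuracy_sd": self.accuracy[1],
            "precision_mean": self.precision[0],
            "precision_sd": self.precision[1],
            "recall_mean": self.recall[0],
            "recall_sd": self.recall[1],
            "fold_accuracy": [m.accuracy for m in self.fold_metrics],
            "fold_precision": [m.precision for m in self.fold_metrics],
            "fold_recall": [m.recall for m in self.fold_metrics],
            "val_accuracy": self.val_accuracy,
            "confusion_counts": self.confusion.tolist(),
            "confusion_row_normalized": self.confusion_normalized.tolist(),
        }


def run_experiment(
    table: pd.DataFrame,
    model_spec,
    *,
    images: np.ndarray | None = None,
    plan: SplitPlan | None = None,
    balance: str = "oversample",
    scopes: Sequence[str] = ("entire",),
    drop_classes: Sequence[str] = (),
) -> dict[str, EvaluationReport]:
    """Cross-validated evaluation of one model over one or more scopes.

    ``table`` holds the 20 feature columns plus ``class`` and ``strain``;
    ``images`` (n, H, W) replaces the features when the model is a CNN.
    ``scopes``: "entire" uses all rows, "KO"/"WT" restrict to one genotype.
    ``drop_classes`` removes classes before splitting (e.g. ("harmonics",)
    for the 9-class variant).  Standardizer and resampling are fitted on
    each fold's training portion only.
    """
    plan = plan or SplitPlan()
    if not set(("class", "strain")) <= set(table.columns):
        raise ValueError("table must have 'class' and 'strain' columns")
    use_images = isinstance(model_spec, CnnSpec) or (
        hasattr(model_spec, "input_shape") and images is not None
    )
    if use_images and images is None:
        raise ValueError("a CNN experiment needs images")

    reports: dict[str, EvaluationReport] = {}
    for scope in scopes:
        if scope == "entire":
            mask = np.ones(len(table), dtype=bool)
        elif scope in ("KO", "WT"):
            mask = (table["strain"] == scope).to_numpy()
        else:
            raise ValueError(f"unknown scope {scope!r}")
        if drop_classes:
            mask &= ~table["class"].isin(drop_classes).to_numpy()
        if not mask.any():
            raise ValueError(f"scope {scope!r} selects no samples")

        sub = table.loc[mask]
        y = sub["class"].to_numpy()
        class_names = tuple(c for c in CLASS_NAMES if c in set(y))
        if use_images:
            X = np.asarray(images)[mask]
        else:
            X = sub[list(FEATURE_NAMES)].to_numpy(dtype=float)

        folds = make_folds(y, plan)
        fold_metrics: list[Metrics] = []
        val_accs: list[float] = []
        confusion = np.zeros((len(class_names), len(class_names)))
        for k, fold in enumerate(folds):
            Xtr, ytr = X[fold.train], y[fold.train]
            Xte, yte = X[fold.test], y[fold.test]
            Xva, yva = X[fold.val], y[fold.val]
            if not use_images:
                scaler = FeatureStandardizer().fit(Xtr)
                Xtr = scaler.transform(Xtr)
                Xte = scaler.transform(Xte)
                Xva = scaler.transform(Xva) if len(yva) else Xva
            model = build_model(model_spec)
            if hasattr(model, "random_state"):
                model.set_params(random_state=plan.seed + k)
            seed_k = plan.seed * 1000 + k
            if balance == "oversample":
                Xtr, ytr = random_oversample(Xtr, ytr, seed_k)
            elif balance == "downsample":
                Xtr, ytr = random_downsample(Xtr, ytr, seed_k)
            elif balance == "class_weights":
                if hasattr(model, "class_weight"):
                    model.set_params(class_weight="balanced")
            elif balance != "none":
                raise ValueError(f"unknown balance strategy {balance!r}")
            model.fit(Xtr, ytr)
            pred = model.predict(Xte)
            cm = _sk_confusion(yte, pred, labels=list(class_names))
            fold_metrics.append(compute_metrics(cm))
            confusion += cm
            if len(yva):
                val_accs.append(float(np.mean(model.predict(Xva) == yva)))
        reports[scope] = EvaluationReport(
            scope=scope,
            class_names=class_names,
            fold_metrics=fold_metrics,
            confusion=confusion,
            val_accuracy=val_accs,
        )
    return reports
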