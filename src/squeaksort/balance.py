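"""Class-imbalance strategies.

Two families, matching the two input types of the classifiers: the CNN
(image input) trains with a class-weighted loss, while the numerical-feature
learners use random oversampling (duplicate minority rows up to the majority
count) or random downsampling (drop majority rows down to the minority
count).  Resampling is only ever applied to the training split — the API
takes the training rows explicitly and never sees validation or test data.

Class weights follow inverse frequency, ``w_c = N / (K * n_c)``, then are
normalized to average 1, so smaller classes get strictly larger weights.
"""

from __future__ import annotations

from typing import Hashable, Mapping

import numpy as np

__all__ = [
    "compute_class_weights",
    "random_oversample",
    "random_downsample",
    "random_shift_crop",
]


def compute_class_weights(counts: Mapping[Hashable, int]) -> dict:
    """Inverse-frequency class weights, mean-normalized to 1.

    ``w_c = N / (K * n_c)`` with N the total count and K the number of
    classes, then divided by the mean weight.  Raises on zero counts.
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    if any(n <= 0 for n in counts.values()):
        raise ValueError("all class counts must be > 0")
    total = sum(counts.values())
    k = len(counts)
    weights = {c: total / (k * n) for c, n in counts.items()}
    mean = sum(weights.values()) / k
    return {c: w / mean for c, w in weights.items()}


def _class_indices(labels: np.ndarray) -> dict:
    classes, inverse = np.unique(labels, return_inverse=True)
    return {c: np.flatnonzero(inverse == i) for i, c in enumerate(classes)}


def random_oversample(
    train_rows: np.ndarray, labels: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate random minority-class rows until all classes match the
    majority count.

    Returns resampled ``(rows, labels)``; the added rows are exact copies of
    existing rows of the same class, drawn uniformly with replacement.
    Deterministic given ``seed``.  Apply to the training split only.
    """
    train_rows = np.asarray(train_rows)
    labels = np.asarray(labels)
    if train_rows.shape[0] != labels.shape[0]:
        raise ValueError("rows and labels must have equal length")
    if labels.size == 0:
        raise ValueError("cannot resample an empty training set")
    rng = np.random.default_rng(seed)
    by_class = _class_indices(labels)
    target = max(idx.size for idx in by_class.values())
    keep = [np.arange(labels.size)]
    for c in sorted(by_class, key=str):
        idx = by_class[c]
        deficit = target - idx.size
        if deficit > 0:
            keep.append(rng.choice(idx, size=deficit, replace=True))
    sel = np.concatenate(keep)
    return train_rows[sel], labels[sel]


def random_downsample(
    train_rows: np.ndarray, labels: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly drop majority-class rows until all classes match the
    minority count.

    Retained rows are a subset of the input; deterministic given ``seed``.
    Apply to the training split only.
    """
    train_rows = np.asarray(train_rows)
    labels = np.asarray(labels)
    if train_rows.shape[0] != labels.shape[0]:
        raise ValueError("rows and labels must have equal length")
    if labels.size == 0:
        raise ValueError("cannot resample an empty training set")
    rng = np.random.default_rng(seed)
    by_class = _class_indices(labels)
    target = min(idx.size for idx in by_class.values())
    keep = []
    for c in sorted(by_class, key=str):
        idx = by_class[c]
        if idx.size > target:
            idx = np.sort(rng.choice(idx, size=target, replace=False))
        keep.append(idx)
    sel = np.sort(np.concatenate(keep))
    return train_rows[sel], labels[sel]


def random_shift_crop(
    images: np.ndarray,
    seed: int = 0,
    max_shift: tuple[int, int] = (6, 26),
) -> np.ndarray:
    """Augment spectrogram images by random shifts with edge padding.

    Optional training-time augmentation for the CNN; off by default in the
    training pipelines, since class weighting handles imbalance and
    augmentation was not found to change performance appreciably.
    """
    images = np.asarray(images)
    rng = np.random.default_rng(seed)
    out = np.empty_like(images)
    for i, img in enumerate(images):
        dy = int(rng.integers(-max_shift[0], max_shift[0] + 1))
        dx = int(rng.integers(-max_shift[1], max_shift[1] + 1))
        shifted = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
        out[i] = shifted
    return out
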