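"""K-means intensity clustering and confusion-matrix mask evaluation.

Clustering is one-dimensional (intensity only) Lloyd iteration with
deterministic quantile initialization; centroids are reported sorted
ascending with labels remapped accordingly.  ``evaluate_mask`` returns the
specificity / sensitivity / accuracy triple used for segmentation scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .imgio import validate_image

__all__ = [
    "ClusterResult",
    "ConfusionCounts",
    "MaskScores",
    "kmeans_intensity",
    "mask_from_clusters",
    "confusion_counts",
    "evaluate_mask",
    "dice",
]


@dataclass
class ClusterResult:
    labels: np.ndarray      # per-pixel cluster id in [0, k)
    centroids: np.ndarray   # k intensity values, sorted ascending
    k: int
    inertia: float          # within-cluster sum of squares


class ConfusionCounts(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int


class MaskScores(NamedTuple):
    specificity: float
    sensitivity: float
    accuracy: float


def _assign(values: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels; in 1-D this is thresholding at midpoints."""
    midpoints = 0.5 * (centroids[:-1] + centroids[1:])
    return np.searchsorted(midpoints, values, side="right")


def kmeans_intensity(
    img: np.ndarray, k: int, seed: int | None = None, max_iters: int = 300, tol: float = 1e-6
) -> ClusterResult:
    """Lloyd iteration on the 1-D intensity values.

    Initialization is deterministic by default (k evenly spaced quantiles);
    pass ``seed`` for random initialization from the observed values.
    """
    img = validate_image(img).astype(np.float64)
    if not 2 <= k <= 8:
        raise ValueError(f"k must be in [2, 8], got {k}")
    values = img.ravel()
    distinct = np.unique(values)
    if distinct.size < k:
        raise ValueError(f"image has {distinct.size} distinct values, fewer than k={k}")
    if seed is None:
        centroids = np.quantile(values, (np.arange(k) + 0.5) / k)
        # quantile ties would collapse centroids; nudge onto distinct values
        if np.unique(centroids).size < k:
            centroids = distinct[np.linspace(0, distinct.size - 1, k).round().astype(int)]
    else:
        centroids = np.sort(np.random.default_rng(seed).choice(distinct, size=k, replace=False))
    centroids = np.sort(centroids.astype(np.float64))

    for _ in range(max_iters):
        labels = _assign(values, centroids)
        new = centroids.copy()
        for i in range(k):
            members = values[labels == i]
            if members.size:
                new[i] = members.mean()
        new = np.sort(new)
        if np.max(np.abs(new - centroids)) < tol:
            centroids = new
            break
        centroids = new

    labels = _assign(values, centroids)
    inertia = float(np.sum((values - centroids[labels]) ** 2))
    return ClusterResult(labels=labels.reshape(img.shape), centroids=centroids, k=k, inertia=inertia)


def mask_from_clusters(res: ClusterResult, which: Iterable[int] | None = None) -> np.ndarray:
    """Mask of pixels whose label is in ``which`` (default: brightest cluster)."""
    ids = set(range(res.k)) & set(which) if which is not None else {res.k - 1}
    if which is not None:
        bad = set(which) - set(range(res.k))
        if bad:
            raise ValueError(f"cluster ids {sorted(bad)} outside [0, {res.k})")
    if not ids:
        warnings.warn("empty cluster selection: returning an empty mask")
        return np.zeros_like(res.labels, dtype=bool)
    return np.isin(res.labels, sorted(ids))


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def evaluate_mask(pred: np.ndarray, truth: np.ndarray) -> MaskScores:
    """(specificity, sensitivity, accuracy); NaN with a warning on 0/0."""
    tp, fp, tn, fn = confusion_counts(pred, truth)

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator), returning NaN")
            return float("nan")
        return num / den

    return MaskScores(
        specificity=_ratio(tn, tn + fp, "specificity"),
        sensitivity=_ratio(tp, tp + fn, "sensitivity"),
        accuracy=_ratio(tp + tn, tp + fp + tn + fn, "accuracy"),
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Overlap score 2|A n B| / (|A| + |B|); 1.0 for two empty masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.sum(a & b)) / denom
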