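"""Global structure preservation metrics.

Four metrics compare large-scale geometry between a high-dimensional space
X and an embedding Y:

* **random triplet accuracy** — fraction of sampled anchored triplets
  (i; j, k) whose relative distance order, sign(d(i,j) - d(i,k)), agrees
  between the spaces; 0.5 is chance, 1.0 perfect order preservation;
* **distance Spearman correlation** — Spearman rank correlation between
  pairwise distances in X and the same pairs' distances in Y, over a
  seeded sample of pairs;
* **k-nearest-class (KNC) preservation** — fraction of each class's k
  nearest classes (by centroid distance) shared between spaces, with the
  class-count-adaptive k = max(1, floor((C + 2) / 4));
* **centroid distance correlation** — Spearman correlation of all
  inter-class centroid distances across spaces.

All four are invariant under independent similarity transforms
(rotation + translation + positive scaling) of X and of Y. Exact distance
ties in the triplet metric count as agreement only when tied in both
spaces; Spearman uses average ranks for ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.stats import spearmanr

from .core import (
    MetricReport,
    ParameterError,
    ValidationError,
    _as_labels,
    _as_matrix,
)

__all__ = [
    "GlobalEvalConfig",
    "CentroidSet",
    "random_triplet_accuracy",
    "exhaustive_triplet_accuracy",
    "distance_spearman",
    "dynamic_k",
    "knc_preservation",
    "centroid_distance_correlation",
]

EXHAUSTIVE_TRIPLET_MAX_N = 500


@dataclass
class GlobalEvalConfig:
    triplets_per_point: int = 5
    pairs_sample_size: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.triplets_per_point < 1 or self.pairs_sample_size < 1:
            raise ParameterError(
                "triplets_per_point and pairs_sample_size must be >= 1"
            )


def _check_paired(X, Y):
    X = _as_matrix(X)
    Y = _as_matrix(Y, "Y")
    if X.shape[0] != Y.shape[0]:
        raise ValidationError(
            f"X and Y must have equal point counts, got {X.shape[0]} vs {Y.shape[0]}"
        )
    return X, Y


def _row_dist(A, i, j):
    return np.linalg.norm(A[i] - A[j], axis=-1)


# ---------------------------------------------------------------------------
# Triplet accuracy
# ---------------------------------------------------------------------------


def random_triplet_accuracy(X, Y, config: GlobalEvalConfig | None = None) -> MetricReport:
    """Sampled anchored triplet accuracy.

    For every anchor i, ``triplets_per_point`` pairs (j, k) of distinct
    other points are drawn (seeded, without replacement within a triplet);
    a triplet agrees when sign(dX(i,j) - dX(i,k)) == sign(dY(i,j) - dY(i,k)).
    Exact ties (sign 0) agree only when tied in both spaces.
    """
    config = config or GlobalEvalConfig()
    X, Y = _check_paired(X, Y)
    n = X.shape[0]
    if n < 3:
        raise ValidationError("need n >= 3 for triplets")
    rng = np.random.default_rng(config.seed)
    t = config.triplets_per_point
    anchors = np.repeat(np.arange(n), t)
    m = anchors.size
    j = rng.integers(0, n, size=m)
    k = rng.integers(0, n, size=m)
    bad = (j == anchors) | (k == anchors) | (j == k)
    while np.any(bad):
        idx = np.flatnonzero(bad)
        j[idx] = rng.integers(0, n, size=idx.size)
        k[idx] = rng.integers(0, n, size=idx.size)
        bad = (j == anchors) | (k == anchors) | (j == k)
    sx = np.sign(_row_dist(X, anchors, j) - _row_dist(X, anchors, k))
    sy = np.sign(_row_dist(Y, anchors, j) - _row_dist(Y, anchors, k))
    value = float(np.mean(sx == sy))
    return MetricReport(
        metric="random_triplet_accuracy",
        value=value,
        params={"triplets_per_point": t, "seed": config.seed, "n_triplets": m},
    )


def exhaustive_triplet_accuracy(X, Y) -> float:
    """Exact triplet accuracy over all n(n-1)(n-2)/2 anchored triplets.

    Oracle for the sampled estimator; refuses n > 500 (enumeration cost).
    """
    X, Y = _check_paired(X, Y)
    n = X.shape[0]
    if n < 3:
        raise ValidationError("need n >= 3 for triplets")
    if n > EXHAUSTIVE_TRIPLET_MAX_N:
        raise ParameterError(
            f"exhaustive enumeration is limited to n <= {EXHAUSTIVE_TRIPLET_MAX_N} "
            f"(got n={n}); use random_triplet_accuracy for larger inputs"
        )
    DX = cdist(X, X)
    DY = cdist(Y, Y)
    others = np.arange(n)
    agree = total = 0
    iu = np.triu_indices(n - 1, k=1)
    for i in range(n):
        o = np.delete(others, i)
        dx = DX[i, o]
        dy = DY[i, o]
        sx = np.sign(dx[:, None] - dx[None, :])[iu]
        sy = np.sign(dy[:, None] - dy[None, :])[iu]
        agree += int(np.sum(sx == sy))
        total += sx.size
    return agree / total


# ---------------------------------------------------------------------------
# Distance Spearman correlation
# ---------------------------------------------------------------------------


def _condensed_to_pair(idx, n):
    """Map condensed (pdist-order) pair indices to (i, j) with i < j."""
    idx = np.asarray(idx, dtype=np.int64)
    b = 1 - 2 * n
    i = np.floor((-b - np.sqrt(b * b - 8.0 * idx)) / 2.0).astype(np.int64)
    j = idx + i * (b + i + 2) // 2 + 1
    return i, j


def distance_spearman(X, Y, config: GlobalEvalConfig | None = None) -> MetricReport:
    """Spearman correlation between pairwise distances in X and in Y.

    All n(n-1)/2 pairs are used when that count does not exceed
    ``pairs_sample_size``; otherwise a seeded sample of pairs without
    replacement. Average ranks handle ties. Constant distances in either
    space leave the correlation undefined: the report carries value NaN
    and an ``undefined`` reason.
    """
    config = config or GlobalEvalConfig()
    X, Y = _check_paired(X, Y)
    n = X.shape[0]
    if n < 3:
        raise ValidationError("need n >= 3 for distance correlation")
    total = n * (n - 1) // 2
    if total <= config.pairs_sample_size:
        dx = pdist(X)
        dy = pdist(Y)
        used = total
    else:
        rng = np.random.default_rng(config.seed)
        sel = rng.choice(total, size=config.pairs_sample_size, replace=False)
        i, j = _condensed_to_pair(sel, n)
        dx = _row_dist(X, i, j)
        dy = _row_dist(Y, i, j)
        used = config.pairs_sample_size
    params = {"pairs_used": int(used), "seed": config.seed}
    if np.ptp(dx) == 0 or np.ptp(dy) == 0:
        params["undefined"] = "constant pairwise distances"
        return MetricReport(metric="distance_spearman", value=float("nan"), params=params)
    rho = spearmanr(dx, dy).statistic
    return MetricReport(metric="distance_spearman", value=float(rho), params=params)


# ---------------------------------------------------------------------------
# Centroid-based metrics
# ---------------------------------------------------------------------------


def dynamic_k(C: int) -> int:
    """Class-count-adaptive neighbor count for KNC: max(1, floor((C+2)/4))."""
    if C < 2:
        raise ValidationError("dynamic_k requires at least 2 classes")
    return max(1, (C + 2) // 4)


@dataclass
class CentroidSet:
    """Per-class arithmetic-mean centroids in both spaces."""

    classes: np.ndarray  # (C,) sorted class ids
    high: np.ndarray  # (C, d)
    low: np.ndarray  # (C, e)

    @classmethod
    def from_data(cls, X, Y, labels) -> "CentroidSet":
        X, Y = _check_paired(X, Y)
        y = _as_labels(labels, X.shape[0])
        classes = np.unique(y)
        high = np.stack([X[y == c].mean(axis=0) for c in classes])
        low = np.stack([Y[y == c].mean(axis=0) for c in classes])
        return cls(classes=classes, high=high, low=low)

    @property
    def C(self) -> int:
        return self.classes.size


def _nearest_classes(centroids: np.ndarray, k: int) -> np.ndarray:
    """Each class's k nearest other classes; ties by lower class position."""
    D = cdist(centroids, centroids)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, :k]


def knc_preservation(X, Y, labels) -> MetricReport:
    """Fraction of k-nearest classes (by centroid distance) preserved.

    k = dynamic_k(C). For each class the sets of its k nearest classes in
    X and in Y are intersected; the value averages |∩| / k over classes.
    """
    cs = CentroidSet.from_data(X, Y, labels)
    if cs.C < 2:
        raise ValidationError("knc_preservation requires at least 2 classes")
    k = dynamic_k(cs.C)
    nn_high = _nearest_classes(cs.high, k)
    nn_low = _nearest_classes(cs.low, k)
    shared = sum(
        np.intersect1d(h, l, assume_unique=True).size
        for h, l in zip(nn_high, nn_low)
    )
    value = shared / (k * cs.C)
    return MetricReport(metric="knc_preservation", value=float(value),
                        params={"k": k, "n_classes": int(cs.C)})


def centroid_distance_correlation(X, Y, labels) -> MetricReport:
    """Spearman correlation of inter-class centroid distances across spaces."""
    cs = CentroidSet.from_data(X, Y, labels)
    if cs.C < 3:
        raise ValidationError(
            "centroid_distance_correlation requires at least 3 classes"
        )
    dh = pdist(cs.high)
    dl = pdist(cs.low)
    params = {"n_classes": int(cs.C), "n_pairs": int(dh.size)}
    if np.ptp(dh) == 0 or np.ptp(dl) == 0:
        params["undefined"] = "constant centroid distances"
        return MetricReport(metric="centroid_distance_correlation",
                            value=float("nan"), params=params)
    rho = spearmanr(dh, dl).statistic
    return MetricReport(metric="centroid_distance_correlation",
                        value=float(rho), params=params)
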