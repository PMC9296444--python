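"""Local structure preservation metrics.

Two complementary views of whether an embedding keeps small-scale
structure intact:

* **supervised accuracy** — train a classifier (RBF-kernel SVM or a k=5
  nearest-neighbor vote) on the 2-D coordinates of 90% of labeled points
  and report test accuracy on the remaining 10%; well-separated classes
  that stay separated in the embedding give high accuracy;
* **neighborhood preservation** — the average fraction of each point's
  k = 5 nearest neighbors in the original space that are also among its
  k nearest neighbors in the embedding; label-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .core import (
    EmbeddingResult,
    MetricReport,
    ParameterError,
    ValidationError,
    _as_labels,
    _as_matrix,
    nearest_neighbors,
)

__all__ = [
    "SupervisedEvalConfig",
    "supervised_accuracy",
    "neighborhood_preservation",
]


@dataclass
class SupervisedEvalConfig:
    classifier: str = "knn"  # "svm-rbf" | "knn"
    k: int = 5
    train_fraction: float = 0.9
    seed: int = 0
    stratify: bool = True
    svm_subsample: int | None = 10_000  # training-point cap for the SVM

    def __post_init__(self):
        if self.classifier not in ("svm-rbf", "knn"):
            raise ParameterError(f"unknown classifier {self.classifier!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ParameterError("train_fraction must be in (0, 1)")
        if self.k < 1:
            raise ParameterError("k must be >= 1")


def _knn_predict(train_X, train_y, test_X, k: int) -> np.ndarray:
    """Deterministic k-NN majority vote.

    Neighbor ties are broken by lower training index (stable sort); vote
    ties go to the label of the nearest neighbor among the tied classes,
    then to the lower class id.
    """
    k = min(k, train_X.shape[0])
    D = cdist(test_X, train_X)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    votes = train_y[order]  # (n_test, k), nearest first
    pred = np.empty(test_X.shape[0], dtype=train_y.dtype)
    for i, row in enumerate(votes):
        classes, counts = np.unique(row, return_counts=True)
        tied = classes[counts == counts.max()]
        if tied.size == 1:
            pred[i] = tied[0]
        else:
            nearest_tied = next(lab for lab in row if lab in set(tied.tolist()))
            pred[i] = nearest_tied
    return pred


def supervised_accuracy(embedding, labels, config: SupervisedEvalConfig | None = None) -> MetricReport:
    """Classification accuracy of a classifier trained on the embedding.

    The data are split into train/test by a seeded (by default stratified)
    random split; the classifier sees only the low-dimensional coordinates.
    Returns accuracy in [0, 1]. With a single class the score is degenerate
    and reported as 1.0 with a ``degenerate`` flag.
    """
    config = config or SupervisedEvalConfig()
    Y = embedding.Y if isinstance(embedding, EmbeddingResult) else _as_matrix(embedding, "Y")
    y = _as_labels(labels, Y.shape[0])
    params = {
        "classifier": config.classifier,
        "k": config.k,
        "train_fraction": config.train_fraction,
        "seed": config.seed,
        "stratify": config.stratify,
    }
    classes = np.unique(y)
    if classes.size == 1:
        params["degenerate"] = "single class"
        return MetricReport(metric=f"supervised_{config.classifier}", value=1.0, params=params)

    stratify = y if config.stratify else None
    if stratify is not None and np.min(np.bincount(np.searchsorted(classes, y))) < 2:
        warnings.warn(
            "a class has fewer than 2 members; falling back to unstratified split",
            stacklevel=2,
        )
        params["stratify"] = False
        stratify = None
    tr_X, te_X, tr_y, te_y = train_test_split(
        Y, y,
        train_size=config.train_fraction,
        random_state=config.seed % (2**32),
        stratify=stratify,
    )
    if config.classifier == "knn":
        pred = _knn_predict(tr_X, tr_y, te_X, config.k)
    else:
        if config.svm_subsample is not None and tr_X.shape[0] > config.svm_subsample:
            rng = np.random.default_rng(config.seed)
            keep = rng.choice(tr_X.shape[0], config.svm_subsample, replace=False)
            tr_X, tr_y = tr_X[keep], tr_y[keep]
            params["svm_subsample"] = config.svm_subsample
        clf = SVC(kernel="rbf")  # library-default C and gamma
        clf.fit(tr_X, tr_y)
        pred = clf.predict(te_X)
    value = float(np.mean(pred == te_y))
    return MetricReport(metric=f"supervised_{config.classifier}", value=value, params=params)


def neighborhood_preservation(X, Y, k: int = 5) -> MetricReport:
    """Average fraction of k-nearest neighbors shared between spaces.

    ``value = (1/n) * sum_i |N(i) ∩ N'(i)| / k`` with N from X and N' from
    Y, both exact Euclidean neighbor sets (self excluded). Invariant to
    similarity transforms of either space; 1.0 when Y preserves every
    neighborhood.
    """
    X = _as_matrix(X)
    Y = _as_matrix(Y, "Y")
    if X.shape[0] != Y.shape[0]:
        raise ValidationError(
            f"X and Y must have equal point counts, got {X.shape[0]} vs {Y.shape[0]}"
        )
    high = nearest_neighbors(X, k, space="high").neighbors
    low = nearest_neighbors(Y, k, space="low").neighbors
    shared = sum(
        np.intersect1d(h, l, assume_unique=True).size for h, l in zip(high, low)
    )
    value = shared / (k * X.shape[0])
    return MetricReport(metric="neighborhood_preservation", value=float(value),
                        params={"k": k})
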