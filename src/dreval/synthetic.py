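"""Synthetic benchmark generators with ground-truth structure annotations.

Two benchmark families probe global-structure preservation:

* **Gaussian Linear** — isotropic Gaussian clusters whose means are exactly
  collinear, equally spaced along a random line in high-dimensional space.
  A good embedding keeps the chain ordering visible.
* **Hierarchical Gaussians** — a three-stage hierarchy (macro > meso >
  micro) built by additive offsets: each macro center is a random direction
  scaled by ``scale_macro``; meso centers add a ``scale_meso`` offset;
  micro centers add a ``scale_micro`` offset; points are the micro center
  plus isotropic noise. With the defaults this yields 5 macro, 25 meso and
  125 micro clusters, i.e. structure at three well-separated length scales.

A third generator, well-separated blobs, is a fixture for supervised-metric
tests (clusters trivially separable in the original space).

All generators are pure functions of their config: the same config (seed
included) reproduces the output bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core import DatasetBundle, ParameterError

__all__ = [
    "LinearGaussianConfig",
    "HierarchicalGaussianConfig",
    "generate_gaussian_linear",
    "generate_hierarchical_gaussians",
    "generate_blobs",
]


def _random_unit_vector(rng, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    norm = np.linalg.norm(v)
    while norm == 0.0:  # measure-zero, but keep the contract total
        v = rng.standard_normal(dim)
        norm = np.linalg.norm(v)
    return v / norm


@dataclass
class LinearGaussianConfig:
    """Gaussian clusters along a line.

    ``spacing`` is the distance between consecutive cluster means;
    ``sigma`` the isotropic within-cluster standard deviation. The line
    direction is a random unit vector drawn from the seed.
    """

    n_clusters: int = 20
    dim: int = 50
    points_per_cluster: int = 100
    spacing: float = 5.0
    sigma: float = 1.0
    seed: int = 0

    def validate(self):
        if self.n_clusters < 1 or self.dim < 1 or self.points_per_cluster < 1:
            raise ParameterError("n_clusters, dim and points_per_cluster must be >= 1")
        if self.spacing <= 0:
            raise ParameterError("spacing must be positive")
        if self.sigma < 0:
            raise ParameterError("sigma must be non-negative")


def generate_gaussian_linear(config: LinearGaussianConfig | None = None) -> DatasetBundle:
    """Generate the Gaussian-Linear benchmark (default: 20 clusters in 50-D).

    Cluster mean j sits at ``j * spacing * u`` for a fixed random unit
    vector u, so the population means are exactly collinear. Labels are
    1-based cluster indices in chain order.
    """
    config = config or LinearGaussianConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    u = _random_unit_vector(rng, config.dim)
    means = np.arange(config.n_clusters)[:, None] * config.spacing * u[None, :]
    n = config.n_clusters * config.points_per_cluster
    X = np.repeat(means, config.points_per_cluster, axis=0)
    if config.sigma > 0:
        X = X + config.sigma * rng.standard_normal((n, config.dim))
    labels = np.repeat(np.arange(1, config.n_clusters + 1), config.points_per_cluster)
    meta = {"generator": "gaussian_linear", **asdict(config)}
    return DatasetBundle(X=X, labels=labels, name="gaussian_linear", meta=meta)


@dataclass
class HierarchicalGaussianConfig:
    """Three-stage hierarchy of Gaussian clusters.

    Offset magnitudes must be strictly ordered ``scale_macro > scale_meso >
    scale_micro`` so that the three length scales are distinguishable.
    """

    n_macro: int = 5
    n_meso_per_macro: int = 5
    n_micro_per_meso: int = 5
    points_per_micro: int = 40
    dim: int = 50
    scale_macro: float = 30.0
    scale_meso: float = 8.0
    scale_micro: float = 2.0
    sigma: float = 0.5
    seed: int = 0

    def validate(self):
        counts = (self.n_macro, self.n_meso_per_macro, self.n_micro_per_meso,
                  self.points_per_micro, self.dim)
        if any(c < 1 for c in counts):
            raise ParameterError("all counts and dim must be >= 1")
        if not (self.scale_macro > self.scale_meso > self.scale_micro > 0):
            raise ParameterError(
                "scales must satisfy scale_macro > scale_meso > scale_micro > 0"
            )
        if self.sigma < 0:
            raise ParameterError("sigma must be non-negative")


def generate_hierarchical_gaussians(
    config: HierarchicalGaussianConfig | None = None,
) -> DatasetBundle:
    """Generate the Hierarchical-Gaussians benchmark (default: 125 micro,
    25 meso, 5 macro clusters of 50-D points).

    Micro-cluster centers are built additively:
    ``macro_dir * scale_macro + meso_dir * scale_meso + micro_dir * scale_micro``
    with independent random unit directions per level. Points add isotropic
    Gaussian noise of std ``sigma``. Level labels ("micro", "meso", "macro")
    are nested by construction and attached both as ``level_labels`` and,
    for the finest level, as ``labels``.
    """
    config = config or HierarchicalGaussianConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    centers, micro_lab, meso_lab, macro_lab = [], [], [], []
    micro_id = meso_id = 0
    for ma in range(config.n_macro):
        macro_center = _random_unit_vector(rng, config.dim) * config.scale_macro
        for _ in range(config.n_meso_per_macro):
            meso_id += 1
            meso_center = macro_center + (
                _random_unit_vector(rng, config.dim) * config.scale_meso
            )
            for _ in range(config.n_micro_per_meso):
                micro_id += 1
                centers.append(meso_center + (
                    _random_unit_vector(rng, config.dim) * config.scale_micro
                ))
                micro_lab.append(micro_id)
                meso_lab.append(meso_id)
                macro_lab.append(ma + 1)

    centers = np.asarray(centers)
    ppm = config.points_per_micro
    X = np.repeat(centers, ppm, axis=0)
    if config.sigma > 0:
        X = X + config.sigma * rng.standard_normal(X.shape)
    level_labels = {
        "micro": np.repeat(micro_lab, ppm),
        "meso": np.repeat(meso_lab, ppm),
        "macro": np.repeat(macro_lab, ppm),
    }
    meta = {"generator": "hierarchical_gaussians", **asdict(config)}
    return DatasetBundle(
        X=X,
        labels=level_labels["micro"].copy(),
        level_labels=level_labels,
        name="hierarchical_gaussians",
        meta=meta,
    )


def generate_blobs(
    n_clusters: int = 5,
    dim: int = 10,
    points_per_cluster: int = 50,
    separation: float = 10.0,
    sigma: float = 1.0,
    seed: int = 0,
    max_tries: int = 1000,
) -> DatasetBundle:
    """Well-separated isotropic Gaussian blobs.

    Cluster means are rejection-sampled (from a wide isotropic Gaussian)
    until all pairwise mean distances are >= ``separation``; raises after
    ``max_tries`` failed proposals per cluster.
    """
    if separation <= 0 or sigma <= 0:
        raise ParameterError("separation and sigma must be positive")
    if n_clusters < 1 or dim < 1 or points_per_cluster < 1:
        raise ParameterError("n_clusters, dim and points_per_cluster must be >= 1")
    rng = np.random.default_rng(seed)
    proposal_scale = 2.0 * separation * max(1.0, n_clusters ** (1.0 / dim))
    means: list = []
    for _ in range(n_clusters):
        for attempt in range(max_tries):
            cand = rng.standard_normal(dim) * proposal_scale
            if all(np.linalg.norm(cand - m) >= separation for m in means):
                means.append(cand)
                break
        else:
            raise ParameterError(
                f"could not place {n_clusters} means at separation {separation} "
                f"within {max_tries} tries; reduce separation or n_clusters"
            )
    means = np.asarray(means)
    X = np.repeat(means, points_per_cluster, axis=0)
    X = X + sigma * rng.standard_normal(X.shape)
    labels = np.repeat(np.arange(1, n_clusters + 1), points_per_cluster)
    meta = {
        "generator": "blobs", "n_clusters": n_clusters, "dim": dim,
        "points_per_cluster": points_per_cluster, "separation": separation,
        "sigma": sigma, "seed": seed,
    }
    return DatasetBundle(X=X, labels=labels, name="blobs", meta=meta)
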