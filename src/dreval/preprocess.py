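"""scRNA-seq style pre-processing: log-normalization, highly-variable-gene
selection, scaling/centering, and PCA.

The chain mirrors the standard count-matrix workflow: per-cell depth
normalization to a common scale factor followed by ``log1p``; variance-
stabilized HVG ranking (standardized variance against a smoothed
mean-variance trend); per-feature centering to mean 0 / unit sample
variance with optional clipping; PCA to at most 100 components.

Conventions pinned here (and asserted by tests):

* natural log with pseudocount 1 (``log1p``);
* HVG trend: lowess of log10(variance) on log10(mean) with span 0.3,
  standardized values clipped symmetrically at ``±sqrt(n)``;
* ``scale_center`` uses the sample (1/(n-1)) standard deviation;
* PCA component signs are fixed so the largest-magnitude loading of each
  component is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import ParameterError, ValidationError, _as_matrix

__all__ = [
    "PreprocessConfig",
    "log_normalize",
    "select_hvg",
    "scale_center",
    "pca_reduce",
    "run_chain",
]

HVG_LOWESS_SPAN = 0.3
MAX_PCS = 100


@dataclass
class PreprocessConfig:
    """Configuration of the full pre-processing chain."""

    do_log_normalize: bool = True
    scale_factor: float = 10_000.0
    n_hvg: int = 2000
    clip_max: float | None = None
    n_pcs: int = 70
    seed: int = 0

    def __post_init__(self):
        if self.scale_factor <= 0:
            raise ParameterError("scale_factor must be positive")
        if self.n_hvg < 1:
            raise ParameterError("n_hvg must be >= 1")
        if not 1 <= self.n_pcs <= MAX_PCS:
            raise ParameterError(f"n_pcs must be in 1..{MAX_PCS}")
        if self.clip_max is not None and self.clip_max <= 0:
            raise ParameterError("clip_max must be positive when given")


def log_normalize(counts, scale_factor: float = 10_000.0) -> np.ndarray:
    """Depth-normalize each cell (row) and log-transform.

    ``out[i, j] = log(1 + counts[i, j] / rowsum(i) * scale_factor)``.

    Raises :class:`ValidationError` naming the first offending row if any
    cell has zero total counts, and on negative entries.
    """
    counts = _as_matrix(counts, "counts")
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"cell (row) {zero[0]} has zero total counts; remove empty cells first"
        )
    return np.log1p(counts / totals[:, None] * scale_factor)


def select_hvg(log_matrix, n_hvg: int = 2000) -> np.ndarray:
    """Rank features by variance-stabilized standardized variance.

    Per feature the observed mean and variance are computed; an expected
    variance as a function of the mean is obtained by lowess regression of
    log10(variance) on log10(mean) over features with positive mean and
    variance (span 0.3). Each value is standardized by
    ``(x - mean) / sqrt(expected variance)`` and clipped at ``±sqrt(n)``;
    features are ranked by the sample variance of the standardized values,
    descending, ties broken by lower feature index. Zero-variance features
    have standardized variance 0 and therefore rank last.

    Returns the top ``min(n_hvg, d)`` feature indices in rank order.
    """
    X = _as_matrix(log_matrix, "log_matrix")
    n, d = X.shape
    if n < 2:
        raise ValidationError("need at least 2 points to estimate variances")
    mu = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    usable = (mu > 0) & (var > 0)
    expected = np.zeros(d)
    if usable.sum() >= 2:
        fitted = lowess(np.log10(var[usable]), np.log10(mu[usable]),
                        frac=HVG_LOWESS_SPAN, return_sorted=False)
        expected[usable] = 10.0 ** fitted
    elif usable.sum() == 1:
        expected[usable] = var[usable]
    std_var = np.zeros(d)
    ok = expected > 0
    if np.any(ok):
        clip = np.sqrt(n)
        Z = (X[:, ok] - mu[ok]) / np.sqrt(expected[ok])
        np.clip(Z, -clip, clip, out=Z)
        std_var[ok] = Z.var(axis=0, ddof=1)
    order = np.lexsort((np.arange(d), -std_var))
    return order[: min(n_hvg, d)]


def scale_center(matrix, clip_max: float | None = None) -> np.ndarray:
    """Center each feature to mean 0 and scale to unit sample variance.

    Zero-variance features map to all-zeros. When ``clip_max`` is given,
    standardized values are clipped to ``±clip_max``.
    """
    X = _as_matrix(matrix)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 points to scale")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    out = np.zeros_like(X)
    nz = sd > 0
    out[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
    if clip_max is not None:
        np.clip(out, -clip_max, clip_max, out=out)
    return out


def pca_reduce(matrix, n_pcs: int, seed: int = 0):
    """Project onto the top principal axes of the centered matrix.

    Returns ``(scores, explained_variance)`` where ``scores`` is
    ``(n, n_pcs)`` and ``explained_variance`` is non-increasing. The sign
    of each component is fixed so that its largest-magnitude loading is
    positive, making the scores deterministic across solvers.
    """
    X = _as_matrix(matrix)
    n, d = X.shape
    if not 1 <= n_pcs <= min(n - 1, d):
        raise ParameterError(
            f"n_pcs must be in 1..min(n-1, d) = {min(n - 1, d)}, got {n_pcs}"
        )
    # full SVD is deterministic and affordable at these sizes; fall back to
    # the seeded randomized solver for very wide problems
    solver = "full" if min(n, d) <= 3000 else "randomized"
    pca = PCA(n_components=n_pcs, svd_solver=solver, random_state=seed)
    scores = pca.fit_transform(X)
    comp = pca.components_
    lead = np.argmax(np.abs(comp), axis=1)
    signs = np.sign(comp[np.arange(comp.shape[0]), lead])
    signs[signs == 0] = 1.0
    scores = scores * signs
    return scores, pca.explained_variance_.copy()


def run_chain(counts, config: PreprocessConfig | None = None):
    """Run the full chain on a raw count matrix.

    Returns ``(scores, info)`` where ``info`` records the HVG indices, the
    explained variance, and the applied configuration — the history entry
    appended to a dataset's provenance.
    """
    config = config or PreprocessConfig()
    X = np.asarray(counts, dtype=float)
    if config.do_log_normalize:
        X = log_normalize(X, config.scale_factor)
    hvg = select_hvg(X, config.n_hvg)
    X = scale_center(X[:, hvg], config.clip_max)
    n_pcs = min(config.n_pcs, X.shape[0] - 1, X.shape[1])
    scores, ev = pca_reduce(X, n_pcs, config.seed)
    info = {
        "hvg_indices": hvg.tolist(),
        "explained_variance": ev.tolist(),
        "n_pcs": n_pcs,
        "config": {
            "do_log_normalize": config.do_log_normalize,
            "scale_factor": config.scale_factor,
            "n_hvg": config.n_hvg,
            "clip_max": config.clip_max,
            "n_pcs": config.n_pcs,
            "seed": config.seed,
        },
    }
    return scores, info
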