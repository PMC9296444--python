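"""Benchmark harness: DR backend adapters, timing, repetition, sweeps.

An *adapter* is a callable ``(X, params, seed) -> (n, 2) array`` wrapping
one dimension-reduction backend. Two adapters ship built-in (``identity2d``
and ``pca``); backends that are importable at runtime (sklearn t-SNE,
umap-learn) are registered lazily. Backends are never re-implemented here.

On top of adapters the harness provides:

* :func:`run_method` / :func:`time_method` — single timed run; the
  wall-clock (monotonic) runtime spans the adapter's full transform,
  including any internal graph construction, so graph-based methods are
  timed fairly;
* :func:`fa2_protocol` — the ForceAtlas2 input protocol: an undirected
  union k=5 nearest-neighbor graph (edge iff either endpoint is among the
  other's 5 nearest neighbors), a PCA-2 initialization rescaled to the
  layout's native coordinate scale, and a fixed iteration count (default
  750) at backend defaults;
* :func:`repeat_evaluate` — the 5-run protocol: run with consecutive
  seeds, evaluate each requested metric per run, aggregate mean and
  sample std;
* :func:`run_sweep` — sensitivity sweeps over a parameter grid, PC count,
  or named pre-processing variants, reporting per-metric dispersion
  (max - min of the per-setting means) and pooled std.

Timing numbers are reported for information only; no correctness assertion
depends on them (they are hardware-dependent).
"""

from __future__ import annotations

import importlib
import time
import traceback
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import sparse

from .core import (
    DatasetBundle,
    EmbeddingResult,
    MetricReport,
    ParameterError,
    ValidationError,
    _as_matrix,
    nearest_neighbors,
    read_matrix,
)
from .metrics_local import SupervisedEvalConfig, neighborhood_preservation, supervised_accuracy
from .metrics_global import (
    GlobalEvalConfig,
    centroid_distance_correlation,
    distance_spearman,
    knc_preservation,
    random_triplet_accuracy,
)
from .preprocess import log_normalize, pca_reduce

__all__ = [
    "AdapterError",
    "register_adapter",
    "available_adapters",
    "get_adapter",
    "run_method",
    "time_method",
    "build_fa2_graph",
    "fa2_protocol",
    "evaluate_metric",
    "repeat_evaluate",
    "SweepSpec",
    "SensitivityReport",
    "run_sweep",
    "METRIC_IDS",
]

FA2_INIT_SCALE = 100.0  # std of PC1 after rescaling the FA2 initialization


class AdapterError(RuntimeError):
    """Raised for unknown adapters or backend failures."""


# ---------------------------------------------------------------------------
# Adapter registry
# ---------------------------------------------------------------------------

_ADAPTERS: dict[str, Callable] = {}


def register_adapter(name: str, fn: Optional[Callable] = None):
    """Register ``fn(X, params, seed) -> (n, 2) array`` under ``name``.

    Usable as a decorator: ``@register_adapter("mymethod")``.
    """
    if fn is None:
        return lambda f: register_adapter(name, f)
    _ADAPTERS[name] = fn
    return fn


@register_adapter("identity2d")
def _identity2d(X, params, seed):
    X = np.asarray(X, dtype=float)
    if X.shape[1] != 2:
        raise ValidationError("identity2d requires 2-D input")
    return X.copy()


@register_adapter("pca")
def _pca2d(X, params, seed):
    scores, _ = pca_reduce(X, 2, seed=seed)
    return scores


def _try_register_optional():
    if "tsne" not in _ADAPTERS and importlib.util.find_spec("sklearn") is not None:
        from sklearn.manifold import TSNE

        def _tsne(X, params, seed):
            kw = dict(params)
            kw.setdefault("init", "pca")
            return TSNE(n_components=2, random_state=seed, **kw).fit_transform(X)

        _ADAPTERS["tsne"] = _tsne
    if "umap" not in _ADAPTERS and importlib.util.find_spec("umap") is not None:
        def _umap(X, params, seed):
            import umap

            return umap.UMAP(n_components=2, random_state=seed, **params).fit_transform(X)

        _ADAPTERS["umap"] = _umap


def available_adapters() -> list:
    _try_register_optional()
    return sorted(_ADAPTERS)


def get_adapter(name: str) -> Callable:
    _try_register_optional()
    try:
        return _ADAPTERS[name]
    except KeyError:
        raise AdapterError(
            f"unknown adapter {name!r}; available: {', '.join(sorted(_ADAPTERS))}. "
            "External backends register automatically when their package is "
            "importable (e.g. `pip install umap-learn`)."
        ) from None


# ---------------------------------------------------------------------------
# Single runs and timing
# ---------------------------------------------------------------------------


def run_method(adapter_name: str, X, params: Optional[dict] = None,
               seed: int = 0, source_dataset: str = "") -> EmbeddingResult:
    """Run one DR backend and time its full transform.

    The wall clock spans the whole adapter call, so any nearest-neighbor
    graph construction the backend performs is included in the runtime.
    Backend failures are wrapped in :class:`AdapterError` with a traceback
    excerpt.
    """
    adapter = get_adapter(adapter_name)
    X = _as_matrix(X)
    params = dict(params or {})
    t0 = time.perf_counter()
    try:
        Y = adapter(X, params, seed)
    except (ValidationError, ParameterError):
        raise
    except Exception as exc:
        tail = traceback.format_exc().strip().splitlines()[-3:]
        raise AdapterError(
            f"backend {adapter_name!r} failed: {exc}\n" + "\n".join(tail)
        ) from exc
    runtime = time.perf_counter() - t0
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape != (X.shape[0], 2):
        raise AdapterError(
            f"adapter {adapter_name!r} returned shape {Y.shape}, "
            f"expected ({X.shape[0]}, 2)"
        )
    return EmbeddingResult(Y=Y, method=adapter_name, params=params, seed=seed,
                           runtime_seconds=runtime, source_dataset=source_dataset)


def time_method(adapter_name: str, X, params: Optional[dict] = None,
                seed: int = 0) -> float:
    """Wall-clock seconds for one full transform (informational only)."""
    return run_method(adapter_name, X, params, seed).runtime_seconds


# ---------------------------------------------------------------------------
# ForceAtlas2 protocol
# ---------------------------------------------------------------------------


def build_fa2_graph(X, k: int = 5) -> sparse.csr_matrix:
    """Undirected union-kNN graph: edge iff i is among j's k nearest
    neighbors or vice versa (Euclidean). Symmetric 0/1 CSR, zero diagonal."""
    X = _as_matrix(X)
    n = X.shape[0]
    nn = nearest_neighbors(X, k).neighbors
    rows = np.repeat(np.arange(n), k)
    cols = nn.ravel()
    A = sparse.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    A = A.maximum(A.T).tocsr()
    A.data[:] = 1.0
    return A


def _scaled_pca_init(X, seed: int) -> np.ndarray:
    init, _ = pca_reduce(X, 2, seed=seed)
    sd = init[:, 0].std()
    if sd > 0:
        init = init * (FA2_INIT_SCALE / sd)
    return init


def fa2_protocol(X, iterations: int = 750, seed: int = 0, k: int = 5) -> EmbeddingResult:
    """Run ForceAtlas2 under the standard input protocol.

    Builds the union k=5 nearest-neighbor graph, initializes with the first
    two principal components rescaled to the layout's native coordinate
    scale (PC1 std = 100), and optimizes for exactly ``iterations``
    iterations at backend defaults. ``iterations=0`` returns the scaled
    initialization itself (no backend required). Graph construction is
    inside the timed region.
    """
    X = _as_matrix(X)
    if iterations < 0:
        raise ParameterError("iterations must be >= 0")
    t0 = time.perf_counter()
    graph = build_fa2_graph(X, k=k)
    init = _scaled_pca_init(X, seed)
    if iterations == 0:
        Y = init
    else:
        Y = _run_fa2_backend(graph, init, iterations, seed)
    runtime = time.perf_counter() - t0
    return EmbeddingResult(
        Y=Y, method="forceatlas2",
        params={"iterations": iterations, "k": k, "init": "pca-scaled"},
        seed=seed, runtime_seconds=runtime,
    )


def _run_fa2_backend(graph, init, iterations, seed):
    for modname in ("fa2", "fa2_modified"):
        if importlib.util.find_spec(modname) is not None:
            mod = importlib.import_module(modname)
            layout = mod.ForceAtlas2(verbose=False)
            pos = layout.forceatlas2(graph, pos=np.asarray(init, dtype=np.float64),
                                     iterations=iterations)
            return np.asarray(pos, dtype=float)
    raise AdapterError(
        "no ForceAtlas2 backend importable (tried fa2, fa2_modified); "
        "install one, or use iterations=0 for the initialization only"
    )


# ---------------------------------------------------------------------------
# Metric dispatch and the 5-run protocol
# ---------------------------------------------------------------------------

METRIC_IDS = ("svm", "knn", "neighborhood", "triplet", "spearman", "knc", "centroid")


def evaluate_metric(metric_id: str, X, Y, labels=None, seed: int = 0,
                    k: int = 5, global_config: Optional[GlobalEvalConfig] = None) -> float:
    """Compute one metric by id on a (X, Y, labels) triple."""
    if metric_id in ("svm", "knn"):
        if labels is None:
            raise ValidationError(f"metric {metric_id!r} requires labels")
        cfg = SupervisedEvalConfig(
            classifier="svm-rbf" if metric_id == "svm" else "knn", k=k, seed=seed
        )
        return supervised_accuracy(Y, labels, cfg).value
    if metric_id == "neighborhood":
        return neighborhood_preservation(X, Y, k=k).value
    gcfg = global_config or GlobalEvalConfig(seed=seed)
    if metric_id == "triplet":
        return random_triplet_accuracy(X, Y, gcfg).value
    if metric_id == "spearman":
        return distance_spearman(X, Y, gcfg).value
    if metric_id == "knc":
        if labels is None:
            raise ValidationError("metric 'knc' requires labels")
        return knc_preservation(X, Y, labels).value
    if metric_id == "centroid":
        if labels is None:
            raise ValidationError("metric 'centroid' requires labels")
        return centroid_distance_correlation(X, Y, labels).value
    raise ParameterError(f"unknown metric id {metric_id!r}; known: {METRIC_IDS}")


def repeat_evaluate(adapter_name: str, dataset: DatasetBundle,
                    params: Optional[dict] = None, metrics=("triplet",),
                    repeats: int = 5, base_seed: int = 0, k: int = 5) -> list:
    """Run a method ``repeats`` times (seeds base_seed..base_seed+repeats-1)
    and aggregate each metric's per-run values into mean and sample std.

    Only the method seed varies across repeats; the metric-evaluation seed
    (triplet/pair sampling, train/test split) is held at ``base_seed`` so
    that run-to-run spread measures the backend's stochasticity alone — a
    deterministic backend gives std exactly 0 on every metric.

    A failing run is recorded in the reports' ``params['failures']`` and the
    surviving runs are aggregated; with a single run std is 0.0 by
    convention.
    """
    if repeats < 1:
        raise ParameterError("repeats must be >= 1")
    per_metric: dict = {m: [] for m in metrics}
    failures = []
    for r in range(repeats):
        seed = base_seed + r
        try:
            emb = run_method(adapter_name, dataset.X, params, seed,
                             source_dataset=dataset.name)
        except AdapterError as exc:
            failures.append({"seed": seed, "error": str(exc).splitlines()[0]})
            continue
        for m in metrics:
            per_metric[m].append(
                evaluate_metric(m, dataset.X, emb.Y, dataset.labels,
                                seed=base_seed, k=k)
            )
    reports = []
    for m in metrics:
        base = {"method": adapter_name, "repeats": repeats, "base_seed": base_seed}
        if failures:
            base["failures"] = failures
        if per_metric[m]:
            rep = MetricReport.from_runs(m, per_metric[m], base)
        else:
            rep = MetricReport(metric=m, value=float("nan"), params=base)
        reports.append(rep)
    return reports


# ---------------------------------------------------------------------------
# Sensitivity sweeps
# ---------------------------------------------------------------------------


@dataclass
class SweepSpec:
    """Declarative description of one sensitivity experiment.

    ``axis`` selects what varies across the grid:

    * ``"parameter"`` — grid entries are parameter dicts merged over
      ``base_params`` and passed to the adapter;
    * ``"n_pcs"`` — grid entries are PC counts; the dataset matrix is
      re-reduced to that many PCs before embedding;
    * ``"preprocessing"`` — grid entries are named variants:
      ``"raw+pca"``, ``"lognorm+pca"``, or ``"external:<path>"`` (a
      pre-computed matrix, e.g. a GLM-PCA factor matrix, read from disk).
    """

    method: str
    axis: str  # "parameter" | "n_pcs" | "preprocessing"
    grid: list
    repeats: int = 5
    base_seed: int = 0
    metrics: tuple = ("triplet",)
    base_params: dict = field(default_factory=dict)
    n_pcs: int = 50  # PC count used by the preprocessing-axis variants

    def __post_init__(self):
        if self.axis not in ("parameter", "n_pcs", "preprocessing"):
            raise ParameterError(f"unknown sweep axis {self.axis!r}")
        if not self.grid:
            raise ParameterError("sweep grid must be non-empty")
        if self.repeats < 1:
            raise ParameterError("repeats must be >= 1")


@dataclass
class SensitivityReport:
    """Per-setting aggregated metrics plus per-metric dispersion.

    ``dispersion[m]`` is max - min of the per-setting means of metric m
    across settings that succeeded; ``pooled_std[m]`` is the square root
    of the mean per-setting variance. Dispersion is 0 for a single-setting
    grid by construction.
    """

    spec: SweepSpec
    settings: list
    reports: list  # list (per setting) of lists of MetricReport; None = failed
    failed: dict = field(default_factory=dict)  # setting index -> message

    @property
    def dispersion(self) -> dict:
        out = {}
        for m in self.spec.metrics:
            means = [
                next(r.value for r in reps if r.metric == m)
                for reps in self.reports if reps is not None
            ]
            means = [v for v in means if np.isfinite(v)]
            out[m] = float(max(means) - min(means)) if means else float("nan")
        return out

    @property
    def pooled_std(self) -> dict:
        out = {}
        for m in self.spec.metrics:
            stds = [
                next(r.std for r in reps if r.metric == m) or 0.0
                for reps in self.reports if reps is not None
            ]
            out[m] = float(np.sqrt(np.mean(np.square(stds)))) if stds else float("nan")
        return out


def _setting_inputs(spec: SweepSpec, dataset: DatasetBundle, setting):
    """Resolve one grid setting to (matrix, adapter params)."""
    if spec.axis == "parameter":
        return dataset.X, {**spec.base_params, **setting}
    if spec.axis == "n_pcs":
        scores, _ = pca_reduce(dataset.X, int(setting), seed=spec.base_seed)
        return scores, dict(spec.base_params)
    # preprocessing axis
    if setting == "raw+pca":
        M = dataset.X
    elif setting == "lognorm+pca":
        M = log_normalize(dataset.X)
    elif isinstance(setting, str) and setting.startswith("external:"):
        M = read_matrix(setting.split(":", 1)[1])
        if M.shape[0] != dataset.n:
            raise ValidationError(
                f"external matrix has {M.shape[0]} rows, dataset has {dataset.n}"
            )
        return M, dict(spec.base_params)
    else:
        raise ParameterError(f"unknown preprocessing variant {setting!r}")
    n_pcs = min(spec.n_pcs, dataset.n - 1, M.shape[1])
    scores, _ = pca_reduce(M, n_pcs, seed=spec.base_seed)
    return scores, dict(spec.base_params)


def run_sweep(spec: SweepSpec, dataset: DatasetBundle) -> SensitivityReport:
    """Execute a sensitivity sweep: repeat-evaluate every grid setting.

    Invalid settings are recorded as failed cells and the sweep continues.
    All seeds derive from ``spec.base_seed`` so the sweep is reproducible
    from its spec alone (for deterministic backends, bitwise).
    """
    reports: list = []
    failed: dict = {}
    for idx, setting in enumerate(spec.grid):
        try:
            M, params = _setting_inputs(spec, dataset, setting)
            sub = DatasetBundle(X=M, labels=dataset.labels,
                                name=f"{dataset.name}[{setting!r}]",
                                meta=dict(dataset.meta))
            reps = repeat_evaluate(spec.method, sub, params, spec.metrics,
                                   repeats=spec.repeats, base_seed=spec.base_seed)
        except (ValidationError, ParameterError, AdapterError) as exc:
            failed[idx] = str(exc)
            reports.append(None)
            continue
        reports.append(reps)
    return SensitivityReport(spec=spec, settings=list(spec.grid),
                             reports=reports, failed=failed)
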