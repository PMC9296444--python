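"""Shared data model, exact nearest-neighbor computation, and file I/O.

Conventions used throughout the package:

* matrices are point-major — rows are cells/points, columns are features;
* distances are Euclidean;
* point indices are 0-based in memory; class labels are dense integers
  ``1..M`` (as produced by :func:`read_labels`);
* nearest-neighbor ties are broken by the lower point index, which makes
  every downstream metric deterministic.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import io as spio
from scipy import sparse
from scipy.spatial.distance import cdist

__all__ = [
    "ValidationError",
    "ParameterError",
    "DatasetBundle",
    "EmbeddingResult",
    "NeighborIndex",
    "MetricReport",
    "nearest_neighbors",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "write_report",
    "read_report",
]

# Rows processed per block when building distance matrices; bounds peak
# memory at ~chunk * n doubles without changing any result.
NN_CHUNK_ROWS = 512


class ValidationError(ValueError):
    """Raised when input data violates a structural precondition."""


class ParameterError(ValueError):
    """Raised when a parameter is out of its valid range."""


def _as_matrix(X, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError(f"{name} must be a 2-D matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValidationError(f"{name} contains NaN or Inf values")
    return X


def _as_labels(labels, n: int, name: str = "labels") -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.shape[0] != n:
        raise ValidationError(
            f"{name} must be a length-{n} vector, got shape {labels.shape}"
        )
    return labels.astype(int)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class DatasetBundle:
    """A high-dimensional dataset with optional (possibly multi-level) labels.

    Parameters
    ----------
    X : ndarray of shape (n, d)
        Data matrix, rows are points. Must be finite, n >= 2, d >= 1.
    labels : ndarray of shape (n,), optional
        Integer class labels (any integer coding; dense 1..M by convention).
    level_labels : dict of str -> ndarray, optional
        Per-level labels for hierarchical data, e.g. keys "micro", "meso",
        "macro". Levels listed fine-to-coarse must nest: every micro cluster
        belongs to exactly one meso cluster, every meso to one macro.
    name : str
        Human-readable dataset name.
    meta : dict
        Provenance: generator parameters, seed, pre-processing history.
    """

    X: np.ndarray
    labels: Optional[np.ndarray] = None
    level_labels: Optional[dict] = None
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = _as_matrix(self.X)
        n, d = self.X.shape
        if n < 2 or d < 1:
            raise ValidationError(f"need n >= 2 and d >= 1, got n={n}, d={d}")
        if self.labels is not None:
            self.labels = _as_labels(self.labels, n)
        if self.level_labels is not None:
            self.level_labels = {
                lvl: _as_labels(v, n, f"level_labels[{lvl!r}]")
                for lvl, v in self.level_labels.items()
            }
            self._check_nesting()

    def _check_nesting(self):
        # fine-to-coarse in insertion order: each finer label must map to a
        # single coarser label
        levels = list(self.level_labels.items())
        for (fine_name, fine), (coarse_name, coarse) in zip(levels, levels[1:]):
            for lab in np.unique(fine):
                parents = np.unique(coarse[fine == lab])
                if parents.size != 1:
                    raise ValidationError(
                        f"label nesting violated: {fine_name} cluster {lab} maps "
                        f"to {parents.size} {coarse_name} clusters"
                    )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass
class EmbeddingResult:
    """A 2-D embedding plus the provenance needed to reproduce it."""

    Y: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    runtime_seconds: float = 0.0
    source_dataset: str = ""

    def __post_init__(self):
        self.Y = _as_matrix(self.Y, "Y")
        if self.runtime_seconds < 0:
            raise ValidationError("runtime_seconds must be non-negative")


@dataclass
class NeighborIndex:
    """Per-point ordered k-nearest-neighbor ids (nearest first, self excluded)."""

    k: int
    neighbors: np.ndarray  # (n, k) int array
    space: str = "high"  # "high" | "low"

    def __post_init__(self):
        self.neighbors = np.asarray(self.neighbors, dtype=int)
        n, k = self.neighbors.shape
        if k != self.k:
            raise ValidationError(f"neighbor lists have {k} entries, expected {self.k}")
        if np.any(self.neighbors == np.arange(n)[:, None]):
            raise ValidationError("a point appears in its own neighbor list")

    def as_sets(self) -> list:
        return [set(row) for row in self.neighbors]


@dataclass
class MetricReport:
    """One metric value with its parameters; aggregates over repeated runs."""

    metric: str
    value: float
    params: dict = field(default_factory=dict)
    per_run: Optional[list] = None
    mean: Optional[float] = None
    std: Optional[float] = None

    @classmethod
    def from_runs(cls, metric: str, per_run, params: Optional[dict] = None) -> "MetricReport":
        """Aggregate repeated runs: value/mean = sample mean, std = sample std.

        With a single run the standard deviation is reported as 0.0 by
        convention.
        """
        per_run = [float(v) for v in per_run]
        mean = float(np.mean(per_run))
        std = float(np.std(per_run, ddof=1)) if len(per_run) > 1 else 0.0
        return cls(metric=metric, value=mean, params=dict(params or {}),
                   per_run=per_run, mean=mean, std=std)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "value": self.value,
            "params": self.params,
            "per_run": self.per_run,
            "mean": self.mean,
            "std": self.std,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricReport":
        return cls(metric=d["metric"], value=d["value"], params=d.get("params") or {},
                   per_run=d.get("per_run"), mean=d.get("mean"), std=d.get("std"))


# ---------------------------------------------------------------------------
# Nearest neighbors
# ---------------------------------------------------------------------------


def nearest_neighbors(X, k: int, space: str = "high") -> NeighborIndex:
    """Exact Euclidean k-nearest neighbors of every point, self excluded.

    Ties are broken by the lower point index (stable sort on distance), so
    the result is fully deterministic — a requirement for reproducible
    metric values. Complexity is O(n^2 d) time, O(chunk * n) memory.

    Parameters
    ----------
    X : ndarray (n, d)
        Finite data matrix.
    k : int
        Number of neighbors, 1 <= k <= n - 1.
    space : {"high", "low"}
        Tag recorded on the returned index.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    if not 1 <= k <= n - 1:
        raise ParameterError(f"k must satisfy 1 <= k <= n-1 = {n - 1}, got {k}")
    out = np.empty((n, k), dtype=int)
    for start in range(0, n, NN_CHUNK_ROWS):
        stop = min(start + NN_CHUNK_ROWS, n)
        D = cdist(X[start:stop], X)
        D[np.arange(stop - start), np.arange(start, stop)] = np.inf
        order = np.argsort(D, axis=1, kind="stable")
        out[start:stop] = order[:, :k]
    return NeighborIndex(k=k, neighbors=out, space=space)


# ---------------------------------------------------------------------------
# Matrix / label / report I/O
# ---------------------------------------------------------------------------

_FORMAT_SUFFIXES = {".mtx": "mtx", ".npy": "npy", ".csv": "delim",
                    ".tsv": "delim", ".txt": "delim"}


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    return _FORMAT_SUFFIXES.get(path.suffix.lower(), "delim")


def read_matrix(path, fmt: Optional[str] = None) -> np.ndarray:
    """Read a dense matrix from delimited text, Matrix Market, or .npy.

    The format is inferred from the suffix unless ``fmt`` is given
    ("delim" | "mtx" | "npy"). Sparse inputs are densified. Delimited text
    is sniffed for comma vs tab vs whitespace; ragged rows and non-numeric
    cells raise :class:`ValidationError` with the 1-based row/column
    position.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        M = spio.mmread(path)
        if sparse.issparse(M):
            M = M.toarray()
        return np.asarray(M, dtype=float)
    if fmt == "npy":
        return np.asarray(np.load(path), dtype=float)
    return _read_delim(path)


def _read_delim(path: Path) -> np.ndarray:
    text = path.read_text()
    first = text.splitlines()[0] if text.strip() else ""
    delim = "," if "," in first else ("\t" if "\t" in first else None)
    rows = []
    for r, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        cells = line.split(delim) if delim else line.split()
        row = []
        for c, cell in enumerate(cells, start=1):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric cell {cell!r} at row {r}, column {c}"
                ) from None
        if rows and len(row) != len(rows[0]):
            raise ValidationError(
                f"{path}: ragged row {r} has {len(row)} cells, expected {len(rows[0])}"
            )
        rows.append(row)
    if not rows:
        raise ValidationError(f"{path}: empty matrix file")
    return np.asarray(rows, dtype=float)


def write_matrix(M, path, fmt: Optional[str] = None) -> None:
    """Write a matrix as delimited text (.csv/.tsv), Matrix Market, or .npy.

    Binary (.npy) round-trips to full precision; delimited text to the
    printed precision (%.12g).
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    M = np.asarray(M)
    if fmt == "mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(M))
    elif fmt == "npy":
        np.save(path, M)
    else:
        delim = "\t" if path.suffix.lower() == ".tsv" else ","
        np.savetxt(path, M, fmt="%.12g", delimiter=delim)


def read_labels(path):
    """Read one label token per line; return (codes, mapping).

    Tokens are re-coded to dense integers ``1..M`` in first-appearance
    order; ``mapping`` is the list of original tokens such that
    ``mapping[code - 1]`` recovers the token.
    """
    path = Path(path)
    tokens = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    if not tokens:
        raise ValidationError(f"{path}: empty label file")
    mapping: list = []
    index: dict = {}
    codes = np.empty(len(tokens), dtype=int)
    for i, tok in enumerate(tokens):
        if tok not in index:
            index[tok] = len(mapping) + 1
            mapping.append(tok)
        codes[i] = index[tok]
    return codes, mapping


def write_labels(labels, path) -> None:
    Path(path).write_text("\n".join(str(v) for v in np.asarray(labels)) + "\n")


def write_report(reports, path, fmt: Optional[str] = None) -> None:
    """Serialize MetricReports to CSV or JSON (one row/object per report)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        path.write_text(json.dumps([r.to_dict() for r in reports], indent=1))
        return
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["metric", "value", "mean", "std", "params", "per_run"])
        for r in reports:
            w.writerow([
                r.metric,
                repr(float(r.value)),
                "" if r.mean is None else repr(float(r.mean)),
                "" if r.std is None else repr(float(r.std)),
                json.dumps(r.params),
                "" if r.per_run is None else json.dumps(r.per_run),
            ])


def read_report(path, fmt: Optional[str] = None):
    """Inverse of :func:`write_report`."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        return [MetricReport.from_dict(d) for d in json.loads(path.read_text())]
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(MetricReport(
                metric=row["metric"],
                value=float(row["value"]),
                mean=float(row["mean"]) if row["mean"] else None,
                std=float(row["std"]) if row["std"] else None,
                params=json.loads(row["params"]) if row["params"] else {},
                per_run=json.loads(row["per_run"]) if row["per_run"] else None,
            ))
    return out
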