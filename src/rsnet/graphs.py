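"""Correlation matrices and sparsity-thresholded binary graphs.

A subject's cleaned ROI time series become a symmetric Pearson
correlation matrix; thresholding at a sparsity SP retains the
round(SP * R(R-1)/2) strongest off-diagonal entries as the edges of an
undirected, unweighted graph. Fixing sparsity rather than a raw
correlation cutoff equalizes wiring cost across subjects so group
comparisons probe relative topology, not overall correlation level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .preprocess import RoiTimeSeriesSet

__all__ = [
    "ConnectivityMatrix",
    "BinaryGraph",
    "SparsityGrid",
    "pearson_matrix",
    "threshold_by_sparsity",
    "threshold_series",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric R x R Pearson correlation matrix for one subject."""

    r: np.ndarray
    subject_id: str = "subject"
    group: str | None = None
    node_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.ndim != 2 or self.r.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-10:
            raise ValueError("correlation entries must lie in [-1, 1]")
        # canonicalize tiny numerical asymmetries
        self.r = np.clip((self.r + self.r.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(self.r, 1.0)
        if not self.node_names:
            self.node_names = [f"ROI_{i + 1:03d}" for i in range(n)]
        elif len(self.node_names) != n:
            raise ValueError("node_names length must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]


@dataclass
class BinaryGraph:
    """Undirected, unweighted adjacency at a given sparsity."""

    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        if not 0.0 < self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in (0, 1]")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def edges(self) -> np.ndarray:
        """Upper-triangle edge list, shape (m, 2), i < j."""
        return np.argwhere(np.triu(self.adjacency, 1) > 0)


@dataclass(frozen=True)
class SparsityGrid:
    """Ordered sparsity thresholds over which metrics are profiled."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError("sparsity grid is empty")
        if np.any(v <= 0) or np.any(v > 1):
            raise ValueError("sparsity values must lie in (0, 1]")
        if v.size > 1 and np.any(np.diff(v) <= 0):
            raise ValueError("sparsity values must be strictly increasing")
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    @classmethod
    def default(cls) -> "SparsityGrid":
        return cls.from_range(0.05, 0.50, 0.05)

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "SparsityGrid":
        if step <= 0:
            raise ValueError("sparsity step must be positive")
        n = int(round((stop - start) / step)) + 1
        return cls(tuple(round(start + i * step, 10) for i in range(n)))

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values)


def pearson_matrix(ts: RoiTimeSeriesSet) -> ConnectivityMatrix:
    """Pairwise Pearson correlations across all ROI time courses."""
    if ts.n_volumes < 3:
        raise ValueError("need at least 3 volumes to estimate correlations")
    spread = np.ptp(ts.data, axis=0)
    if np.any(spread == 0):
        bad = [ts.node_names[i] for i in np.flatnonzero(spread == 0)]
        raise ValueError(f"constant ROI column(s), correlation undefined: {bad}")
    r = np.corrcoef(ts.data, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(
        r=np.clip(r, -1.0, 1.0),
        subject_id=ts.subject_id,
        group=ts.group,
        node_names=list(ts.node_names),
    )


def edge_budget(n_nodes: int, sparsity: float) -> int:
    """Edges retained at a sparsity: round-half-away-from-zero of SP*R(R-1)/2."""
    total = n_nodes * (n_nodes - 1) // 2
    return int(math.floor(sparsity * total + 0.5))


def _ranked_edge_order(c: ConnectivityMatrix, edge_rank: str) -> tuple[np.ndarray, np.ndarray]:
    n = c.n_nodes
    ii, jj = np.triu_indices(n, 1)
    vals = c.r[ii, jj]
    key = np.abs(vals) if edge_rank == "absolute" else vals
    # primary: strongest first; ties broken lexicographically by (i, j)
    order = np.lexsort((jj, ii, -key))
    return ii[order], jj[order]


def threshold_by_sparsity(
    c: ConnectivityMatrix, sp: float, edge_rank: str = "signed"
) -> BinaryGraph:
    """Binary graph keeping the K = round(SP*R(R-1)/2) strongest correlations.

    ``edge_rank`` selects whether edges compete by signed correlation
    (strongest positive first, the default) or by absolute value. Ties at
    the K-th rank are broken lexicographically by node-index pair, so the
    retained edge set is deterministic and nested across thresholds.
    """
    if not 0.0 < sp <= 1.0:
        raise ValueError("sparsity must lie in (0, 1]")
    if edge_rank not in ("signed", "absolute"):
        raise ValueError("edge_rank must be 'signed' or 'absolute'")
    k = edge_budget(c.n_nodes, sp)
    if k == 0:
        raise ValueError(f"sparsity {sp} retains zero edges for R={c.n_nodes}")
    ii, jj = _ranked_edge_order(c, edge_rank)
    adj = np.zeros((c.n_nodes, c.n_nodes), dtype=np.int8)
    adj[ii[:k], jj[:k]] = 1
    adj = adj + adj.T
    return BinaryGraph(adjacency=adj, sparsity=sp)


def threshold_series(
    c: ConnectivityMatrix, grid: SparsityGrid, edge_rank: str = "signed"
) -> list[BinaryGraph]:
    """One thresholded graph per grid value; edge sets nested in SP."""
    ii, jj = _ranked_edge_order(c, edge_rank)
    graphs = []
    for sp in grid:
        k = edge_budget(c.n_nodes, sp)
        if k == 0:
            raise ValueError(f"sparsity {sp} retains zero edges for R={c.n_nodes}")
        adj = np.zeros((c.n_nodes, c.n_nodes), dtype=np.int8)
        adj[ii[:k], jj[:k]] = 1
        adj = adj + adj.T
        graphs.append(BinaryGraph(adjacency=adj, sparsity=sp))
    return graphs
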