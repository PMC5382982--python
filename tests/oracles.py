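"""Independent brute-force reference implementations used only by tests.

Deliberately naive: explicit loops and exhaustive enumeration, sharing no
code path with the package, so they can arbitrate correctness.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def degree_oracle(adj: np.ndarray) -> list[int]:
    n = adj.shape[0]
    return [sum(int(adj[i, j]) for j in range(n) if j != i) for i in range(n)]


def clustering_oracle(adj: np.ndarray) -> list[float]:
    n = adj.shape[0]
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and adj[i, j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b]
        )
        out.append(2.0 * links / (k * (k - 1)))
    return out


def floyd_warshall_oracle(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), math.inf)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def efficiency_oracle(adj: np.ndarray) -> tuple[float, float, list[float]]:
    """(char path length over reachable pairs, global efficiency, nodal efficiency)."""
    n = adj.shape[0]
    d = floyd_warshall_oracle(adj)
    e = []
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j != i and math.isfinite(d[i, j]) and d[i, j] > 0:
                acc += 1.0 / d[i, j]
        e.append(acc / (n - 1))
    finite = [d[i, j] for i in range(n) for j in range(n) if i != j and math.isfinite(d[i, j])]
    cpl = sum(finite) / len(finite) if finite else math.nan
    return cpl, sum(e) / n, e


def modularity_oracle(adj: np.ndarray, partition) -> float:
    """Newman Q = sum_c (e_cc - a_c^2) for a given node partition."""
    n = adj.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j]]
    m = len(edges)
    label = {}
    for c, nodes in enumerate(partition):
        for v in nodes:
            label[v] = c
    q = 0.0
    for c in range(len(partition)):
        within = sum(1 for i, j in edges if label[i] == c and label[j] == c)
        ends = sum((label[i] == c) + (label[j] == c) for i, j in edges)
        q += within / m - (ends / (2 * m)) ** 2
    return q


def _set_partitions(items):
    """All set partitions of a sequence (Bell-number enumeration)."""
    if len(items) == 1:
        yield [list(items)]
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def best_partition_oracle(adj: np.ndarray) -> tuple[float, list[list[int]]]:
    """Exhaustive maximal-Q partition; feasible for n <= 8."""
    n = adj.shape[0]
    best_q, best_p = -math.inf, None
    for part in _set_partitions(list(range(n))):
        q = modularity_oracle(adj, part)
        if q > best_q:
            best_q, best_p = q, part
    return best_q, best_p


def roi_means_oracle(voxels: np.ndarray, labels) -> np.ndarray:
    t = voxels.shape[0]
    n_rois = max(labels)
    out = np.zeros((t, n_rois))
    for vol in range(t):
        for r in range(1, n_rois + 1):
            vals = [voxels[vol, v] for v in range(len(labels)) if labels[v] == r]
            out[vol, r - 1] = sum(vals) / len(vals)
    return out


def random_adjacency(rng: np.random.Generator, n: int, p: float = None) -> np.ndarray:
    """Symmetric 0/1 adjacency with zero diagonal for oracle comparisons."""
    if p is None:
        p = rng.uniform(0.1, 0.6)
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1).astype(np.int8)
    return adj + adj.T
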