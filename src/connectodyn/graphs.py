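"""Density thresholding and clustering coefficients for connectivity matrices.

Weighted association matrices (functional z-score or structural similarity)
are binarized by keeping the strongest positive edges up to a target edge
density.  The cohort-common *minimum connection density* is the smallest
density at which every subject's thresholded network is a single connected
component; thresholding every subject at that common density makes clustering
comparable across subjects without sparsity confounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .functional import ConnectivityMatrix

__all__ = [
    "BinaryGraph",
    "ClusteringResult",
    "threshold_at_density",
    "connecting_density",
    "find_min_density",
    "clustering_coefficients",
]


@dataclass
class BinaryGraph:
    """Undirected unweighted graph at a stated edge density."""

    adjacency: np.ndarray
    density: float
    node_labels: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("self-loops are not allowed")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def is_connected(self) -> bool:
        n, _ = connected_components(coo_matrix(self.adjacency), directed=False)
        return n == 1


@dataclass
class ClusteringResult:
    """Local (per-node) and global clustering coefficients."""

    local: np.ndarray
    global_: float

    def __post_init__(self) -> None:
        self.local = np.asarray(self.local, dtype=float)
        if not np.isclose(self.global_, self.local.mean()):
            raise ValueError("global clustering must equal the mean of local values")


def _ranked_edges(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle positive edges sorted by descending weight.

    Ties are broken by (row, column) lexicographic order so thresholding is
    deterministic.  Negative and zero weights never enter the ranking.
    """
    iu, ju = np.triu_indices(weights.shape[0], k=1)
    w = weights[iu, ju]
    pos = w > 0
    iu, ju, w = iu[pos], ju[pos], w[pos]
    order = np.lexsort((ju, iu, -w))
    return np.stack([iu[order], ju[order]]), w[order]


def threshold_at_density(m: ConnectivityMatrix, density: float) -> BinaryGraph:
    """Keep the ``floor(density * N(N-1)/2)`` strongest positive edges."""
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = m.weights.shape[0]
    n_pairs = n * (n - 1) // 2
    k = int(np.floor(density * n_pairs))
    edges, _ = _ranked_edges(m.weights)
    if edges.shape[1] < k:
        raise ValueError(
            f"matrix has only {edges.shape[1]} positive edges; "
            f"density {density} requires {k} (short by {k - edges.shape[1]})"
        )
    adj = np.zeros((n, n), dtype=bool)
    i, j = edges[:, :k]
    adj[i, j] = adj[j, i] = True
    return BinaryGraph(
        adjacency=adj,
        density=k / n_pairs,
        node_labels=list(m.node_labels),
        subject_id=m.subject_id,
    )


def _connects_at(edges: np.ndarray, n: int, k: int) -> bool:
    i, j = edges[:, :k]
    g = coo_matrix((np.ones(k), (i, j)), shape=(n, n))
    n_comp, _ = connected_components(g, directed=False)
    return n_comp == 1


def connecting_density(m: ConnectivityMatrix) -> float:
    """Smallest edge density at which this subject's graph is fully connected.

    Edges enter by descending positive weight; connectivity is monotone in the
    edge count, so the minimal count is found by bisection.
    """
    n = m.weights.shape[0]
    n_pairs = n * (n - 1) // 2
    edges, _ = _ranked_edges(m.weights)
    total = edges.shape[1]
    if total < n - 1 or not _connects_at(edges, n, total):
        raise ValueError(
            f"subject {m.subject_id!r}: graph never becomes connected "
            "(insufficient positive weights)"
        )
    lo, hi = n - 1, total  # a spanning graph needs at least N-1 edges
    while lo < hi:
        mid = (lo + hi) // 2
        if _connects_at(edges, n, mid):
            hi = mid
        else:
            lo = mid + 1
    return lo / n_pairs


def find_min_density(matrices: list[ConnectivityMatrix]) -> float:
    """Cohort-common minimum connection density: max over subjects of the
    per-subject smallest connecting density."""
    if not matrices:
        raise ValueError("need at least one matrix")
    return max(connecting_density(m) for m in matrices)


def clustering_coefficients(g: BinaryGraph) -> ClusteringResult:
    """Binary local clustering (triangle density among neighbors) and its mean.

    Local value for node i is ``2 T_i / (k_i (k_i - 1))`` where ``T_i`` counts
    triangles through i and ``k_i`` its degree; nodes with degree < 2 get 0,
    keeping the global mean defined over all N nodes.
    """
    a = g.adjacency.astype(np.float64)
    if a.shape[0] < 3:
        raise ValueError("need at least 3 nodes")
    deg = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = deg * (deg - 1)
    local = np.where(denom > 0, 2.0 * triangles / np.where(denom > 0, denom, 1.0), 0.0)
    return ClusteringResult(local=local, global_=float(local.mean()))
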