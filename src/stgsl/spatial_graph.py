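"""Raw kNN cell graph, adaptive cutoff distance and cutoff-restricted distances.

The raw graph Gamma is a binary symmetric k-nearest-neighbor graph over the
cell coordinates (union symmetrization, ties broken by cell index).  The
cutoff distance d_c — the median over cells of the distance to the k-th
nearest neighbor — bounds the support of the learned adjacency: only pairs
with 0 < d_ij <= d_c can carry weight, which also sparsifies the cosine
similarity computation on large sections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import squareform, pdist

__all__ = ["RawGraph", "DistanceInfo", "knn_graph", "cutoff_distance",
           "sparse_distances"]


@dataclass
class RawGraph:
    """Symmetric cell graph; binary at construction, weighted in [0,1]
    after bootstrapping toward the learned adjacency."""

    adjacency: sp.csr_matrix
    k_gamma: int

    def dense(self) -> np.ndarray:
        return np.asarray(self.adjacency.todense(), dtype=float)


@dataclass
class DistanceInfo:
    """Pairwise distances restricted to the cutoff, plus the Gamma support.

    ``ii``, ``jj``, ``d`` list each stored unordered pair once (ii < jj);
    every pair satisfies d > 0, and pairs are stored when d <= d_c or when
    the pair is a Gamma edge.
    """

    ii: np.ndarray
    jj: np.ndarray
    d: np.ndarray
    d_c: float
    k: int
    n_cells: int

    def within_cutoff_mask(self) -> np.ndarray:
        """Dense boolean N x N support of the learned adjacency
        (0 < d <= d_c, symmetric, zero diagonal)."""
        m = np.zeros((self.n_cells, self.n_cells), dtype=bool)
        keep = self.d <= self.d_c
        m[self.ii[keep], self.jj[keep]] = True
        return m | m.T

    def decay_matrix(self, gamma_decay: float) -> np.ndarray:
        """Dense exp(-gamma (d/d_c)^2) on the within-cutoff support,
        zero elsewhere."""
        m = np.zeros((self.n_cells, self.n_cells))
        keep = self.d <= self.d_c
        vals = np.exp(-gamma_decay * (self.d[keep] / self.d_c) ** 2)
        m[self.ii[keep], self.jj[keep]] = vals
        return m + m.T

    def distance_matrix(self) -> np.ndarray:
        m = np.zeros((self.n_cells, self.n_cells))
        m[self.ii, self.jj] = self.d
        return m + m.T


def _pairwise(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be N x 2")
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    return squareform(pdist(coords))


def _knn_indices(dist: np.ndarray, k: int) -> np.ndarray:
    """Indices of each row's k nearest neighbors (self excluded),
    distance ties broken by ascending index."""
    n = dist.shape[0]
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    cols = np.broadcast_to(np.arange(n), (n, n))
    order = np.lexsort((cols, d), axis=1)  # by distance, then index
    return order[:, :k]


def knn_graph(coords: np.ndarray, k_gamma: int) -> RawGraph:
    """Binary symmetric (union) kNN graph under Euclidean distance.

    Default neighborhood sizes in practice: 5 for single-cell-resolution
    data, 6 for hexagonal-grid spot data.
    """
    dist = _pairwise(coords)
    n = dist.shape[0]
    if n <= k_gamma:
        raise ValueError("too few cells: N must exceed k_gamma")
    nn = _knn_indices(dist, k_gamma)
    rows = np.repeat(np.arange(n), k_gamma)
    a = sp.csr_matrix((np.ones(n * k_gamma), (rows, nn.ravel())), shape=(n, n))
    a = a.maximum(a.T)  # union symmetrization
    a.setdiag(0)
    a.eliminate_zeros()
    a.data[:] = 1.0
    return RawGraph(adjacency=a, k_gamma=k_gamma)


def cutoff_distance(coords: np.ndarray, k: int) -> float:
    """Median over cells of the distance to the k-th nearest neighbor."""
    dist = _pairwise(coords)
    n = dist.shape[0]
    if n <= k:
        raise ValueError("too few cells: N must exceed k")
    part = np.sort(dist, axis=1)  # column 0 is the self distance (0)
    return float(np.median(part[:, k]))


def sparse_distances(coords: np.ndarray, d_c: float,
                     graph: RawGraph | None = None,
                     k: int = 0) -> DistanceInfo:
    """All unordered pairs with 0 < d <= d_c, union the Gamma support.

    Coincident cells (d = 0) are never stored — the learned adjacency is
    defined only on strictly positive distances.
    """
    if d_c <= 0:
        raise ValueError("d_c must be positive")
    dist = _pairwise(coords)
    n = dist.shape[0]
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    within = upper & (dist > 0) & (dist <= d_c)
    if graph is not None:
        g = graph.adjacency.toarray() != 0
        within |= upper & (g | g.T) & (dist > 0)
        n_coincident = int((upper & (g | g.T) & (dist == 0)).sum())
        if n_coincident:
            import logging
            logging.getLogger("stgsl").warning(
                "%d coincident neighbor pairs excluded from the learned "
                "adjacency support", n_coincident)
    ii, jj = np.nonzero(within)
    return DistanceInfo(ii=ii, jj=jj, d=dist[ii, jj], d_c=float(d_c), k=k,
                        n_cells=n)
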