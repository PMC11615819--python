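"""Stochastic view construction: feature/edge masking, feature corruption,
three-view assembly, and bootstrapping of the raw graph.

Three graph views feed the shared encoder each training step:

* learner  — (masked features, masked learned adjacency A)
* positive — (masked features, masked raw graph Gamma)
* negative — (masked row-shuffled features, identity adjacency)

Feature masking zeroes whole feature dimensions (one Bernoulli draw per
dimension, replicated across cells); edge masking removes undirected edges
symmetrically.  The identity adjacency of the negative view is never
masked — with self-loop insertion and renormalization the encoder output
would be unchanged anyway, so masking it would be dead code.

Between steps the raw graph drifts toward the learned structure through
the convex bootstrap Gamma <- omega_Gamma * Gamma + (1 - omega_Gamma) * A
with a conservation rate of 0.999.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, as_tensor
from .gsl_model import NormalizedAdjacency
from .spatial_graph import RawGraph

__all__ = [
    "AugmentationConfig",
    "ViewBundle",
    "sample_feature_mask",
    "sample_edge_mask",
    "corrupt_features",
    "assemble_views",
    "update_raw_graph",
]


@dataclass
class AugmentationConfig:
    """Masking rates.  The negative view's feature rate always equals the
    positive view's (p_nr = p_pr); edge rates apply to learner/positive
    only."""

    p_lr: float = 0.6
    p_pr: float = 0.9
    p_le: float = 0.25
    p_pe: float = 0.25
    seed: int = 0

    @property
    def p_nr(self) -> float:
        return self.p_pr

    def validate(self) -> None:
        for name in ("p_lr", "p_pr", "p_le", "p_pe"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ViewBundle:
    """(features, adjacency) for the learner / positive / negative views."""

    learner: tuple
    positive: tuple
    negative: tuple


def sample_feature_mask(F: int, p_r: float, rng: np.random.Generator) -> np.ndarray:
    """Length-F 0/1 vector: each dimension kept with probability 1 - p_r.

    The same mask row is broadcast to every cell (column-wise masking).
    """
    if not 0.0 <= p_r <= 1.0:
        raise ValueError("p_r must lie in [0, 1]")
    return (rng.random(F) >= p_r).astype(float)


def sample_edge_mask(support: tuple[np.ndarray, np.ndarray], n: int,
                     p_e: float, rng: np.random.Generator) -> np.ndarray:
    """Dense 0/1 multiplier removing each undirected edge with prob p_e.

    ``support`` lists the upper-triangle edges (ii, jj); removal is applied
    to both orientations so masked adjacencies stay symmetric.
    """
    if not 0.0 <= p_e <= 1.0:
        raise ValueError("p_e must lie in [0, 1]")
    ii, jj = support
    keep = (rng.random(len(ii)) >= p_e).astype(float)
    m = np.ones((n, n))
    m[ii, jj] = keep
    m[jj, ii] = keep
    return m


def corrupt_features(X, rng: np.random.Generator):
    """Negative-view corruption: permute whole rows (cells) uniformly.

    The multiset of row vectors is preserved exactly; only the pairing of
    expression profile to node identity is destroyed.
    """
    n = X.shape[0]
    if n < 2:
        import warnings
        warnings.warn("corrupt_features is a no-op for a single cell")
        return X
    perm = rng.permutation(n)
    if isinstance(X, Tensor):
        return X.take_rows(perm)
    return np.asarray(X)[perm]


def _edge_support(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ii, jj = np.nonzero(np.triu(a, k=1))
    return ii, jj


def assemble_views(X, A: NormalizedAdjacency, gamma_graph: RawGraph,
                   cfg: AugmentationConfig, rng: np.random.Generator) -> ViewBundle:
    """Draw fresh masks and assemble the three (features, adjacency) views.

    Gradients flow through X and A into the surviving entries; masks and
    the raw graph are constants of the draw.
    """
    cfg.validate()
    x = as_tensor(X)
    n, F = x.shape
    a = A.A if isinstance(A, NormalizedAdjacency) else A
    a_t = as_tensor(a)
    gamma = gamma_graph.dense()

    m_lr = sample_feature_mask(F, cfg.p_lr, rng)
    m_pr = sample_feature_mask(F, cfg.p_pr, rng)
    m_nr = sample_feature_mask(F, cfg.p_nr, rng)
    m_le = sample_edge_mask(_edge_support(a_t.data), n, cfg.p_le, rng)
    m_pe = sample_edge_mask(_edge_support(gamma), n, cfg.p_pe, rng)

    learner = (x * m_lr, a_t * m_le)
    positive = (x * m_pr, gamma * m_pe)
    negative = (corrupt_features(x, rng) * m_nr, np.eye(n))
    return ViewBundle(learner=learner, positive=positive, negative=negative)


def update_raw_graph(gamma_graph: RawGraph, A: NormalizedAdjacency,
                     omega_gamma: float = 0.999) -> RawGraph:
    """Bootstrap Gamma toward the learned adjacency (convex combination).

    Computed on the union support with A detached from the gradient;
    values stay in [0, 1] since both operands live there.
    """
    if not 0.0 <= omega_gamma <= 1.0:
        raise ValueError("omega_gamma must lie in [0, 1]")
    a = A.dense() if isinstance(A, NormalizedAdjacency) else np.asarray(A)
    new = omega_gamma * gamma_graph.adjacency.toarray() + (1.0 - omega_gamma) * a
    out = sp.csr_matrix(new)
    out.eliminate_zeros()
    return RawGraph(adjacency=out, k_gamma=gamma_graph.k_gamma)
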