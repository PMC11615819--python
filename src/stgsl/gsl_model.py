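"""Trainable core: feature projector, structure encoder, adjacency
sketching / refinement / normalization, shared view encoder, projection head.

The model learns a continuous cell graph jointly with cell embeddings.
The flow, per forward pass:

1. f_p2: a two-layer MLP (ReLU after each linear, BatchNorm1d at the end)
   maps normalized expression to the working features X (N x F).
2. f_o: a two-layer GCN over the raw kNN graph Gamma produces structure
   embeddings H^o.
3. Sketch: A^o_ij = relu(cos(h_i^o, h_j^o)) on the cutoff-restricted pairs.
4. Refine: A'_ij = omega_o * A^o_ij + (1 - omega_o) * exp(-gamma (d_ij/d_c)^2)
   for 0 < d_ij <= d_c, else 0.  Gradient flows only through the sketch
   term; distances and the decay are data-derived constants.
5. Normalize: A = D'^{-1/2} A' D'^{-1/2}, confining edge weights to [0, 1].
6. A shared two-layer GCN encoder (one parameter set for the learner,
   positive and negative views) and a bias-free projection head
   Z = relu(H W1) W2 feed the contrastive objectives.

Every operation accepts plain ndarrays (returning ndarrays) or autodiff
Tensors (returning Tensors), so the same code path serves training and
closed-form tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import BatchNorm1d, Linear, Tensor, as_tensor
from .spatial_graph import DistanceInfo, RawGraph

__all__ = [
    "ModelConfig",
    "FeatureProjector",
    "StructureEncoder",
    "SharedEncoder",
    "ProjectionHead",
    "RefinedAdjacency",
    "NormalizedAdjacency",
    "gcn_layer_propagate",
    "encode_structure",
    "sketch_similarity",
    "refine_adjacency",
    "normalize_adjacency",
    "project_head",
]


@dataclass
class ModelConfig:
    """Architecture and adjacency hyperparameters.

    ``omega_o`` balances learned cosine similarity against the spatial
    decay (0.5 by default); ``gamma_decay`` sets the decay rate (2);
    ``k`` defines the cutoff distance (median 20th-NN distance) and
    ``k_gamma`` the raw-graph neighborhood (5 single-cell / 6 spot grids).
    """

    h_p: int = 512
    F: int = 512
    h_o: int = 256
    d_o: int = 64
    h: int = 256
    d_emb: int = 64
    h_phi: int = 64
    d_z: int = 32
    omega_o: float = 0.5
    gamma_decay: float = 2.0
    k: int = 20
    k_gamma: int = 5
    seed: int = 0

    def validate(self) -> None:
        dims = [self.h_p, self.F, self.h_o, self.d_o, self.h, self.d_emb,
                self.h_phi, self.d_z]
        if min(dims) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not 0.0 <= self.omega_o <= 1.0:
            raise ValueError("omega_o must lie in [0, 1]")
        if self.gamma_decay <= 0:
            raise ValueError("gamma_decay must be positive")


# ---------------------------------------------------------------------------
# parameterized components
# ---------------------------------------------------------------------------

class FeatureProjector:
    """f_p2: Linear-ReLU, Linear-ReLU, BatchNorm1d."""

    def __init__(self, in_dim: int, cfg: ModelConfig, rng: np.random.Generator):
        self.lin1 = Linear(in_dim, cfg.h_p, rng, bias=True)
        self.lin2 = Linear(cfg.h_p, cfg.F, rng, bias=True)
        self.bn = BatchNorm1d(cfg.F)

    def __call__(self, x) -> Tensor:
        h = self.lin1(as_tensor(x)).relu()
        h = self.lin2(h).relu()
        return self.bn(h)

    def parameters(self):
        return self.lin1.parameters() + self.lin2.parameters() + self.bn.parameters()

    def train(self, mode: bool = True):
        self.bn.training = mode


class _TwoLayerGCN:
    def __init__(self, in_dim: int, hidden: int, out_dim: int,
                 rng: np.random.Generator):
        self.lin1 = Linear(in_dim, hidden, rng, bias=False)
        self.lin2 = Linear(hidden, out_dim, rng, bias=False)

    def __call__(self, x, adjacency) -> Tensor:
        h = gcn_layer_propagate(x, adjacency, self.lin1.W, _checked=True).relu()
        return gcn_layer_propagate(h, adjacency, self.lin2.W, _checked=True)

    def parameters(self):
        return self.lin1.parameters() + self.lin2.parameters()


class StructureEncoder(_TwoLayerGCN):
    """f_o: two-layer GCN over the normalized raw graph (F -> h_o -> d_o)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__(cfg.F, cfg.h_o, cfg.d_o, rng)


class SharedEncoder(_TwoLayerGCN):
    """The view encoder f_l = f_+ = f_-: one parameter set, three views."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__(cfg.F, cfg.h, cfg.d_emb, rng)


class ProjectionHead:
    """phi: Z = relu(H W1) W2, bias-free, shared across views."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.lin1 = Linear(cfg.d_emb, cfg.h_phi, rng, bias=False)
        self.lin2 = Linear(cfg.h_phi, cfg.d_z, rng, bias=False)

    def __call__(self, h) -> Tensor:
        return self.lin2(self.lin1(as_tensor(h)).relu())

    def parameters(self):
        return self.lin1.parameters() + self.lin2.parameters()


@dataclass
class RefinedAdjacency:
    """The learned cell graph A' and its cosine sketch A^o."""

    A_sketch: np.ndarray | Tensor
    A_refined: np.ndarray | Tensor
    omega_o: float
    gamma_decay: float
    d_c: float

    def refined_dense(self) -> np.ndarray:
        a = self.A_refined
        return a.data if isinstance(a, Tensor) else np.asarray(a)


@dataclass
class NormalizedAdjacency:
    """A = D'^{-1/2} A' D'^{-1/2}; symmetric, entries in [0, 1]."""

    A: np.ndarray | Tensor

    def dense(self) -> np.ndarray:
        return self.A.data if isinstance(self.A, Tensor) else np.asarray(self.A)


# ---------------------------------------------------------------------------
# functional operations
# ---------------------------------------------------------------------------

def _ret(out: Tensor, *inputs):
    """Return an ndarray when no input carried gradients."""
    if any(isinstance(x, Tensor) for x in inputs):
        return out
    return out.data


def _check_symmetric(a: np.ndarray) -> None:
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")


def gcn_layer_propagate(features, weighted_adjacency, weights,
                        _checked: bool = False):
    """One GCN propagation: D^{-1/2}(W + I)D^{-1/2} (features @ weights).

    Self-loops are inserted internally regardless of the input diagonal;
    with an identity (or zero) adjacency the layer reduces to a per-node
    linear map, which is what makes the negative view a pure MLP pass.
    """
    adj_t = as_tensor(weighted_adjacency)
    a = adj_t.data
    if not _checked:
        _check_symmetric(a)
        if a.min() < -1e-12:
            raise ValueError("adjacency must be non-negative")
    n = a.shape[0]
    eye = np.eye(n)
    what = adj_t * (1.0 - eye) + eye  # W + I with the diagonal forced to 1
    deg = what.sum(axis=1, keepdims=True)
    dinv = deg ** -0.5
    norm = what * dinv * dinv.reshape(1, n)
    out = norm @ (as_tensor(features) @ as_tensor(weights))
    return _ret(out, features, weighted_adjacency, weights)


def encode_structure(X, gamma_graph: RawGraph | np.ndarray,
                     encoder: StructureEncoder):
    """H^o = f_o(X, Gamma): two GCN propagations over the normalized raw
    graph with a ReLU between them.  Rows of the result are the node
    features used for adjacency sketching."""
    adj = gamma_graph.dense() if isinstance(gamma_graph, RawGraph) \
        else np.asarray(gamma_graph, dtype=float)
    _check_symmetric(adj)
    return _ret(encoder(as_tensor(X), adj), X)


def sketch_similarity(H_o, pairs: DistanceInfo, support_mask: np.ndarray | None = None):
    """Rectified cosine similarity on the stored pairs.

    Returns a dense N x N symmetric matrix that is zero off the stored
    support.  Zero-norm embedding rows get cosine 0 by definition.
    """
    h = as_tensor(H_o)
    n = h.shape[0]
    if support_mask is None:
        support_mask = np.zeros((n, n), dtype=bool)
        support_mask[pairs.ii, pairs.jj] = True
        support_mask |= support_mask.T
    sq = (h * h).sum(axis=1, keepdims=True)
    norm = sq.sqrt_safe()
    nz = (norm.data > 0).astype(float)  # constant mask: zero-norm rows -> cos 0
    safe = norm + (1.0 - nz)  # avoid 0/0; masked out below
    hn = h / safe * nz
    cos = hn @ hn.T
    out = cos.relu() * support_mask.astype(float)
    return _ret(out, H_o)


def refine_adjacency(A_sketch, pairs: DistanceInfo, omega_o: float,
                     gamma_decay: float) -> RefinedAdjacency:
    """Blend the sketch with the spatial decay on the cutoff support.

    A'_ij = omega_o A^o_ij + (1 - omega_o) exp(-gamma (d_ij/d_c)^2) for
    0 < d_ij <= d_c, zero otherwise.  Only the sketch term carries
    gradient; the decay is a constant of the geometry.
    """
    if not 0.0 <= omega_o <= 1.0:
        raise ValueError("omega_o must lie in [0, 1]")
    mask = pairs.within_cutoff_mask().astype(float)
    decay = pairs.decay_matrix(gamma_decay)
    a = as_tensor(A_sketch) * mask * omega_o + (1.0 - omega_o) * decay
    return RefinedAdjacency(A_sketch=_ret(as_tensor(A_sketch), A_sketch),
                            A_refined=_ret(a, A_sketch),
                            omega_o=omega_o, gamma_decay=gamma_decay,
                            d_c=pairs.d_c)


def normalize_adjacency(A_refined: RefinedAdjacency | np.ndarray | Tensor) -> NormalizedAdjacency:
    """Symmetric normalization A = D'^{-1/2} A' D'^{-1/2}.

    Zero-degree rows map to zero rows rather than dividing by zero.
    """
    a_in = A_refined.A_refined if isinstance(A_refined, RefinedAdjacency) else A_refined
    a = as_tensor(a_in)
    deg = a.sum(axis=1, keepdims=True)
    pos = (deg.data > 0).astype(float)  # constant: which rows have degree
    dinv = (deg + (1.0 - pos)) ** -0.5 * pos
    out = a * dinv * dinv.reshape(1, a.shape[0])
    return NormalizedAdjacency(A=_ret(out, a_in))


def project_head(H_any, head: ProjectionHead):
    """Apply the shared projection head."""
    return _ret(head(H_any), H_any)
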