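"""Contrastive objectives: symmetric NT-Xent, triplet loss, their blend,
and the mini-batch NT-Xent used for scalability.

NT-Xent (normalized temperature-scaled cross entropy) pulls corresponding
rows of the learner and positive projections together:

    L_NT = (1/2N) sum_i [ l(z_i, z_i+) + l(z_i+, z_i) ]
    l(z_i, z_i+) = -log exp(cos(z_i, z_i+)/tau) / sum_k exp(cos(z_i, z_k+)/tau)

with the denominator ranging over the opposite view only (the k = i term
included).  The triplet loss enforces a margin between the anchor-positive
and anchor-negative Euclidean distances:

    L_triplet = (1/N) sum_i max(||z_i - z_i+|| - ||z_i - z_i-|| + eps, 0)

and the total objective is L = L_NT + omega_t * L_triplet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = ["LossConfig", "nt_xent", "nt_xent_minibatch", "triplet",
           "total_loss"]


@dataclass
class LossConfig:
    """tau: softmax temperature (small, e.g. 0.3); epsilon_margin: triplet
    safety margin (e.g. 0.5); omega_t: triplet weight; batch_size: "full"
    or an integer mini-batch size for NT-Xent."""

    tau: float = 0.3
    epsilon_margin: float = 0.5
    omega_t: float = 1.0
    batch_size: int | str = "full"

    def validate(self) -> None:
        if self.tau <= 0:
            raise ValueError("invalid temperature")
        if self.epsilon_margin < 0:
            raise ValueError("epsilon_margin must be non-negative")
        if self.omega_t < 0:
            raise ValueError("omega_t must be non-negative")


def _row_normalize(z: Tensor) -> Tensor:
    sq = (z * z).sum(axis=1, keepdims=True)
    norm = sq.sqrt_safe()
    nz = (norm.data > 0).astype(float)
    if not nz.all():
        warnings.warn("zero-norm projection rows: cosine defined as 0")
    return z / (norm + (1.0 - nz)) * nz


def _ret(out, *inputs):
    if any(isinstance(x, Tensor) for x in inputs):
        return out
    return out.item() if isinstance(out, Tensor) else out


def nt_xent(Z, Z_pos, tau: float):
    """Symmetric NT-Xent between paired views (full-batch).

    Numerically stabilized by subtracting the (detached) per-row and
    per-column maxima before exponentiation.
    """
    if tau <= 0:
        raise ValueError("invalid temperature")
    z = as_tensor(Z)
    zp = as_tensor(Z_pos)
    if z.shape != zp.shape:
        raise ValueError("shape mismatch between views")
    n = z.shape[0]
    s = (_row_normalize(z) @ _row_normalize(zp).T) * (1.0 / tau)
    eye = np.eye(n)
    diag = (s * eye).sum(axis=1, keepdims=True)

    mx_r = s.data.max(axis=1, keepdims=True)
    lse_r = ((s - mx_r).exp().sum(axis=1, keepdims=True)).log() + mx_r
    mx_c = s.data.max(axis=0, keepdims=True)
    lse_c = ((s - mx_c).exp().sum(axis=0, keepdims=True)).log() + mx_c

    loss = ((lse_r - diag).sum() + (lse_c - diag.reshape(1, n)).sum()) * (1.0 / (2 * n))
    return _ret(loss, Z, Z_pos)


def nt_xent_minibatch(Z, Z_pos, tau: float, batch_size: int,
                      rng: np.random.Generator):
    """NT-Xent restricted to one uniformly sampled batch of cells.

    The denominator ranges over batch members only; with batch_size = N
    this reduces exactly to the full loss (batch indices are kept in
    ascending order).
    """
    z = as_tensor(Z)
    n = z.shape[0]
    if batch_size < 2:
        raise ValueError("batch too small")
    if batch_size > n:
        raise ValueError("batch_size exceeds N")
    idx = np.sort(rng.choice(n, size=batch_size, replace=False))
    zb = z.take_rows(idx)
    zpb = as_tensor(Z_pos).take_rows(idx)
    out = nt_xent(zb, zpb, tau)
    return _ret(as_tensor(out), Z, Z_pos)


def triplet(Z, Z_pos, Z_neg, epsilon_margin: float):
    """Margin hinge on anchor-positive vs anchor-negative distances."""
    if epsilon_margin < 0:
        raise ValueError("epsilon_margin must be non-negative")
    z = as_tensor(Z)
    zp = as_tensor(Z_pos)
    zn = as_tensor(Z_neg)
    dp = ((z - zp) * (z - zp)).sum(axis=1, keepdims=True).sqrt_safe()
    dn = ((z - zn) * (z - zn)).sum(axis=1, keepdims=True).sqrt_safe()
    loss = (dp - dn + epsilon_margin).relu().mean()
    return _ret(loss, Z, Z_pos, Z_neg)


def total_loss(Z, Z_pos, Z_neg, cfg: LossConfig,
               rng: np.random.Generator | None = None):
    """L = L_NT + omega_t * L_triplet; returns (loss, breakdown dict)."""
    cfg.validate()
    if cfg.batch_size == "full" or cfg.batch_size >= as_tensor(Z).shape[0]:
        l_nt = nt_xent(Z, Z_pos, cfg.tau)
    else:
        if rng is None:
            raise ValueError("mini-batch NT-Xent needs an rng")
        l_nt = nt_xent_minibatch(Z, Z_pos, cfg.tau, int(cfg.batch_size), rng)
    l_tri = triplet(Z, Z_pos, Z_neg, cfg.epsilon_margin)
    total = as_tensor(l_nt) + as_tensor(l_tri) * cfg.omega_t
    breakdown = {
        "L_NT": float(as_tensor(l_nt).data),
        "L_triplet": float(as_tensor(l_tri).data),
        "L": float(total.data),
    }
    return _ret(total, Z, Z_pos, Z_neg), breakdown
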