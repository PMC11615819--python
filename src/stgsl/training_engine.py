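"""End-to-end optimization loop and the deterministic inference pass.

Each epoch performs one full-graph (transductive) forward pass:

    f_p2 -> f_o -> sketch/refine/normalize -> three augmented views
    -> shared encoder -> projection head -> L_NT + omega_t L_triplet

followed by one Adam step, and every ``gamma_update_every`` epochs the raw
graph is bootstrapped toward the learned adjacency.  All randomness
(parameter init, masks, mini-batches) derives from a single seed, so a
fixed seed gives bitwise-identical results on CPU.

Inference disables every stochastic element (no masking, no edge
dropping, no shuffling, batch normalization in evaluation mode) and
returns the learner embeddings H = f_l(X, A) together with the refined
adjacency A' — the quantity used for CCI analysis — and its normalized
form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .augmentation_views import AugmentationConfig, assemble_views, update_raw_graph
from .autodiff import Adam, Tensor
from .data_model_io import STDataset, fp1_normalize, select_hvg
from .gsl_model import (FeatureProjector, ModelConfig, ProjectionHead,
                        SharedEncoder, StructureEncoder, normalize_adjacency,
                        refine_adjacency, sketch_similarity)
from .objectives import LossConfig, total_loss
from .spatial_graph import (DistanceInfo, RawGraph, cutoff_distance, knn_graph,
                            sparse_distances)

logger = logging.getLogger("stgsl")

__all__ = ["TrainConfig", "TrainedModel", "InferenceOutput", "train", "infer",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    """Optimization settings plus the embedded module configs."""

    epochs: int = 500
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    seed: int = 0
    gamma_update_every: int = 1
    n_top_genes: int = 3000
    model: ModelConfig = field(default_factory=ModelConfig)
    aug: AugmentationConfig = field(default_factory=AugmentationConfig)
    loss: LossConfig = field(default_factory=LossConfig)

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("invalid optimizer settings")
        if self.gamma_update_every < 1:
            raise ValueError("gamma_update_every must be >= 1")
        self.model.validate()
        self.aug.validate()
        self.loss.validate()


@dataclass
class TrainedModel:
    """Trained parameters plus the frozen geometry they were fit on."""

    config: TrainConfig
    projector: FeatureProjector
    structure_encoder: StructureEncoder
    shared_encoder: SharedEncoder
    head: ProjectionHead
    gamma: RawGraph          # final bootstrapped raw graph
    pairs: DistanceInfo      # cutoff-restricted distances
    gene_names: list[str] | None
    n_input_genes: int
    kept_cells: np.ndarray   # mask over the training dataset's cells

    def parameters(self):
        return (self.projector.parameters()
                + self.structure_encoder.parameters()
                + self.shared_encoder.parameters()
                + self.head.parameters())

    def eval(self):
        self.projector.train(False)

    def train_mode(self):
        self.projector.train(True)


@dataclass
class InferenceOutput:
    """Deliverables of the trained model on one dataset."""

    embeddings: np.ndarray            # H, N x d_emb
    refined_adjacency: np.ndarray     # A', dense symmetric, zero off support
    normalized_adjacency: np.ndarray  # A
    pairs: DistanceInfo

    def edge_table(self) -> pd.DataFrame:
        """Undirected (i < j) edges of A' with distances and decay values."""
        keep = self.pairs.d <= self.pairs.d_c
        ii, jj, d = self.pairs.ii[keep], self.pairs.jj[keep], self.pairs.d[keep]
        return pd.DataFrame({
            "i": ii, "j": jj,
            "a_prime": self.refined_adjacency[ii, jj],
            "d": d,
        })


def _prepare(ds: STDataset, cfg: TrainConfig):
    ds = select_hvg(ds, cfg.n_top_genes)
    nf = fp1_normalize(ds)
    coords = ds.coords[nf.kept]
    return ds, nf, coords


def _forward_adjacency(Xn, projector, structure_encoder, gamma: RawGraph,
                       pairs: DistanceInfo, support_mask, mcfg: ModelConfig):
    X = projector(Xn)
    gamma_dense = gamma.dense()
    H_o = structure_encoder(X, gamma_dense)
    A_sketch = sketch_similarity(H_o, pairs, support_mask)
    refined = refine_adjacency(A_sketch, pairs, mcfg.omega_o, mcfg.gamma_decay)
    return X, refined, normalize_adjacency(refined)


def train(ds: STDataset, cfg: TrainConfig) -> tuple[TrainedModel, pd.DataFrame]:
    """Fit the model; returns the trained state and the per-epoch loss log."""
    cfg.validate()
    ds_hvg, nf, coords = _prepare(ds, cfg)
    n = nf.values.shape[0]
    if n <= max(cfg.model.k, cfg.model.k_gamma):
        raise ValueError("too few cells for the configured k / k_gamma")

    gamma = knn_graph(coords, cfg.model.k_gamma)
    d_c = cutoff_distance(coords, cfg.model.k)
    pairs = sparse_distances(coords, d_c, gamma, cfg.model.k)
    support = np.zeros((n, n), dtype=bool)
    support[pairs.ii, pairs.jj] = True
    support |= support.T

    init_rng, aug_rng, batch_rng = (np.random.default_rng(s)
                                    for s in np.random.SeedSequence(cfg.seed).spawn(3))
    projector = FeatureProjector(nf.values.shape[1], cfg.model, init_rng)
    structure_encoder = StructureEncoder(cfg.model, init_rng)
    shared = SharedEncoder(cfg.model, init_rng)
    head = ProjectionHead(cfg.model, init_rng)
    params = (projector.parameters() + structure_encoder.parameters()
              + shared.parameters() + head.parameters())
    opt = Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

    Xn = Tensor(nf.values)
    rows = []
    for epoch in range(cfg.epochs):
        projector.train(True)
        X, refined, a_norm = _forward_adjacency(
            Xn, projector, structure_encoder, gamma, pairs, support, cfg.model)
        views = assemble_views(X, a_norm, gamma, cfg.aug, aug_rng)
        H = shared(views.learner[0], views.learner[1])
        H_pos = shared(views.positive[0], views.positive[1])
        H_neg = shared(views.negative[0], views.negative[1])
        loss, breakdown = total_loss(head(H), head(H_pos), head(H_neg),
                                     cfg.loss, batch_rng)
        if not np.isfinite(breakdown["L"]):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch} "
                f"(lr={cfg.learning_rate}, breakdown={breakdown})")
        opt.zero_grad()
        loss.backward()
        opt.step()
        if (epoch + 1) % cfg.gamma_update_every == 0:
            gamma = update_raw_graph(gamma, a_norm.dense()
                                     if hasattr(a_norm, "dense")
                                     else a_norm)
        rows.append({"epoch": epoch, **breakdown})
        logger.info("epoch %d  L=%.5f  L_NT=%.5f  L_triplet=%.5f",
                    epoch, breakdown["L"], breakdown["L_NT"],
                    breakdown["L_triplet"])

    model = TrainedModel(config=cfg, projector=projector,
                         structure_encoder=structure_encoder,
                         shared_encoder=shared, head=head, gamma=gamma,
                         pairs=pairs, gene_names=ds_hvg.gene_names,
                         n_input_genes=ds_hvg.n_genes, kept_cells=nf.kept)
    return model, pd.DataFrame(rows)


def infer(model: TrainedModel, ds: STDataset) -> InferenceOutput:
    """Deterministic forward pass: no masking, no shuffling, BN in eval mode.

    The dataset must carry the gene set the model was trained on (the HVG
    subset is re-derived by name when names are available).
    """
    cfg = model.config
    if model.gene_names is not None and ds.gene_names is not None:
        if ds.gene_names != model.gene_names:
            name_to_idx = {g: i for i, g in enumerate(ds.gene_names)}
            try:
                idx = np.array([name_to_idx[g] for g in model.gene_names])
            except KeyError as e:
                raise ValueError(f"incompatible model: gene {e} missing") from e
            ds = ds.subset_genes(idx)
    elif ds.n_genes != model.n_input_genes:
        raise ValueError("incompatible model: gene count mismatch")

    nf = fp1_normalize(ds)
    if nf.values.shape[0] != model.pairs.n_cells:
        raise ValueError("incompatible model: cell count mismatch")
    n = model.pairs.n_cells
    support = np.zeros((n, n), dtype=bool)
    support[model.pairs.ii, model.pairs.jj] = True
    support |= support.T

    model.eval()
    X, refined, a_norm = _forward_adjacency(
        Tensor(nf.values), model.projector, model.structure_encoder,
        model.gamma, model.pairs, support, cfg.model)
    H = model.shared_encoder(X, a_norm.A)
    emb = H.data if isinstance(H, Tensor) else np.asarray(H)
    if not np.isfinite(emb).all():
        raise ArithmeticError("non-finite embeddings at inference")
    return InferenceOutput(embeddings=emb,
                           refined_adjacency=refined.refined_dense(),
                           normalized_adjacency=a_norm.dense(),
                           pairs=model.pairs)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def _named_arrays(model: TrainedModel) -> dict[str, np.ndarray]:
    out = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    out["bn_running_mean"] = model.projector.bn.running_mean
    out["bn_running_var"] = model.projector.bn.running_var
    out["gamma_dense"] = model.gamma.adjacency.toarray()
    for k in ("ii", "jj", "d"):
        out[f"pairs_{k}"] = getattr(model.pairs, k)
    out["kept_cells"] = model.kept_cells
    return out


def save_checkpoint(model: TrainedModel, path) -> None:
    """Serialize parameters (npz) plus the YAML config that produced them."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, format_version=1, **_named_arrays(model))
    meta = {
        "format_version": 1,
        "train": {k: getattr(model.config, k)
                  for k in ("epochs", "learning_rate", "weight_decay", "seed",
                            "gamma_update_every", "n_top_genes")},
        "model": vars(model.config.model),
        "aug": {k: getattr(model.config.aug, k)
                for k in ("p_lr", "p_pr", "p_le", "p_pe", "seed")},
        "loss": vars(model.config.loss),
        "pairs": {"d_c": model.pairs.d_c, "k": model.pairs.k,
                  "n_cells": model.pairs.n_cells},
        "gene_names": model.gene_names,
        "n_input_genes": model.n_input_genes,
        "k_gamma": model.gamma.k_gamma,
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def load_checkpoint(path) -> TrainedModel:
    import scipy.sparse as sp
    path = Path(path)
    with open(path.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    cfg = TrainConfig(**meta["train"], model=ModelConfig(**meta["model"]),
                      aug=AugmentationConfig(**meta["aug"]),
                      loss=LossConfig(**meta["loss"]))
    arrays = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    rng = np.random.default_rng(0)  # shapes only; overwritten below
    projector = FeatureProjector(meta["n_input_genes"], cfg.model, rng)
    structure_encoder = StructureEncoder(cfg.model, rng)
    shared = SharedEncoder(cfg.model, rng)
    head = ProjectionHead(cfg.model, rng)
    model = TrainedModel(config=cfg, projector=projector,
                         structure_encoder=structure_encoder,
                         shared_encoder=shared, head=head,
                         gamma=RawGraph(sp.csr_matrix(arrays["gamma_dense"]),
                                        meta["k_gamma"]),
                         pairs=DistanceInfo(ii=arrays["pairs_ii"],
                                            jj=arrays["pairs_jj"],
                                            d=arrays["pairs_d"],
                                            d_c=meta["pairs"]["d_c"],
                                            k=meta["pairs"]["k"],
                                            n_cells=meta["pairs"]["n_cells"]),
                         gene_names=meta["gene_names"],
                         n_input_genes=meta["n_input_genes"],
                         kept_cells=arrays["kept_cells"].astype(bool))
    for i, p in enumerate(model.parameters()):
        p.data = arrays[f"param_{i}"]
    projector.bn.running_mean = arrays["bn_running_mean"]
    projector.bn.running_var = arrays["bn_running_var"]
    return model
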