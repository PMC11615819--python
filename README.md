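# stgsl — graph structure learning for spatial transcriptomics

Spatial transcriptomics (ST) measures gene expression while preserving each
cell's (or spot's) position in the tissue. Most spatial clustering and
cell–cell interaction (CCI) tools fix the cell graph up front — usually a
k-nearest-neighbor graph over the coordinates — and everything downstream
inherits its noise. `stgsl` instead *learns* the graph: a continuous,
spatially regularized adjacency matrix is optimized jointly with
low-dimensional cell embeddings through three-view graph contrastive
learning. The embeddings drive spatial domain clustering; the learned
adjacency is a direct readout of CCI strength between neighboring cells and
supports gene-level sensitivity analysis.

It is aimed at computational biologists working with single-cell- or
spot-resolution ST data (H5AD, MatrixMarket, or plain CSV), and at method
developers who want a compact, fully deterministic CPU reference of this
model family.

## The model

Raw counts `X°` (N cells × F_g genes) are median-depth log-normalized,

    f_p1(X°)_ij = ln( median(X°) · X°_ij / Σ_j X°_ij + 1 ),

and projected by a two-layer MLP `f_p2` (ReLU + BatchNorm1d) into working
features `X`. A binary kNN graph `Γ` over the coordinates (k_Γ = 5
single-cell / 6 hexagonal spots) seeds a two-layer GCN `f_o` whose node
embeddings `H°` sketch a similarity graph

    A°_ij = ReLU( cos(h°_i, h°_j) ),

which is refined by an exponential spatial decay within a cutoff distance
`d_c` (the median distance to the k-th nearest neighbor, k ≈ 20):

    A'_ij = ω_o A°_ij + (1 − ω_o) exp(−γ (d_ij/d_c)²)   for 0 < d_ij ≤ d_c,

zero otherwise (ω_o = 0.5, γ = 2), then symmetrically normalized to
`A = D'^{-1/2} A' D'^{-1/2}`. Three augmented views — learner `(X, A)`,
positive `(X, Γ)`, negative (row-shuffled `X`, identity) — pass through one
shared two-layer GCN encoder and projection head, and the parameters
minimize

    L = L_NT + ω_t · L_triplet,

a symmetric NT-Xent loss (temperature τ = 0.3) plus a margin triplet loss
(ε = 0.5). Between epochs the raw graph drifts toward the learned one,
`Γ ← 0.999 Γ + 0.001 A`. After training, k-means on the embeddings gives
spatial domains (scored by ARI/AMI against annotations when present); `A'`
thresholded — optionally at an edge count matched to a reference method —
gives CCI edges, each classified against its pure-decay expectation
(`a < 0.7e`: weaker, `a > 0.7e + 0.3`: stronger); and per-gene sensitivity
scores rank genes by how much shuffling each one's expression across cells
rewires `A'`.

A layered synthetic tissue generator (contiguous bands with
negative-binomial marker programs and a binomial-thinning dropout protocol)
makes the whole pipeline testable without external data.

## Worked example

```python
import numpy as np
from stgsl import *

ds = generate_layered_tissue(TissueSimConfig(n_cells=600, seed=0))
cfg = TrainConfig(
    epochs=200, seed=0,
    model=ModelConfig(h_p=128, F=64, h_o=64, d_o=32, h=64,
                      d_emb=32, h_phi=32, d_z=16, k=20, k_gamma=5))
model, log = train(ds, cfg)
out = infer(model, ds)

part = kmeans_cluster(out.embeddings, n_clusters=3, seed=0)
print(f"ARI  {ari(part.labels, ds.labels):.3f}")
print(f"AMI  {ami(part.labels, ds.labels):.3f}")

edges = classify_strength(extract_cci_edges(out, threshold=0.5))
res = gene_sensitivity(model, ds,
                       genes=ds.gene_names[:6] + ds.gene_names[-3:], seed=0)
print(res.scores.head(3).to_string(index=False))
```

prints

```
ARI  0.990
AMI  0.981
       gene    score  rank
marker_L1_0 0.120737     1
marker_L0_4 0.111277     2
marker_L0_1 0.077670     3
```

The three simulated layers are recovered almost perfectly (ARI/AMI ≈ 0.99),
and every top-ranked sensitivity gene is a layer marker — shuffling a
marker's expression rewires ~8–12 % of the learned CCI edges, while
background genes barely move it. The `edges` table additionally labels each
CCI as stronger/weaker/neutral relative to pure spatial decay.

The same pipeline is available from the shell:

```bash
stgsl simulate --output-dir sim --seed 0
stgsl fit --input sim/counts.csv --output-dir fit --seed 0 --epochs 200
stgsl cluster --input sim/counts.csv --checkpoint fit/checkpoint.npz \
      --output-dir clusters --n-clusters 3 --truth sim/labels_true.csv
stgsl cci --input sim/counts.csv --checkpoint fit/checkpoint.npz \
      --output-dir cci --threshold 0.5
```

## Layout

- `src/stgsl/data_model_io.py` — dataset record, H5AD/MTX/CSV IO, HVG
  selection, normalization
- `src/stgsl/synthetic_tissue.py` — layered tissue simulator, dropout
  downsampling
- `src/stgsl/spatial_graph.py` — kNN graph, cutoff distance, sparse
  pairwise distances
- `src/stgsl/gsl_model.py` — projector, GCN encoders, adjacency
  sketch/refine/normalize, projection head
- `src/stgsl/augmentation_views.py` — masks, corruption, view assembly,
  graph bootstrap
- `src/stgsl/objectives.py` — NT-Xent (full and mini-batch), triplet,
  total loss
- `src/stgsl/training_engine.py` — training loop, inference, checkpoints
- `src/stgsl/downstream_analysis.py` — k-means, ARI/AMI, CCI edges,
  strength grouping, gene sensitivity
- `src/stgsl/autodiff.py` — the reverse-mode autodiff engine and layers
- `src/stgsl/cli.py` — `stgsl` command-line entry points

See `docs/methods.md` for the full methodological account.
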