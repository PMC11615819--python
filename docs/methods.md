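# Methods

## Model overview and assumptions

`stgsl` treats an ST section as a graph whose nodes are cells (or spots)
and whose edge weights are unknown. The working assumptions are:

1. **Homophily within a neighborhood** — cells that interact or share a
   domain have similar expression programs, so a similarity kernel over
   learned embeddings (here: rectified cosine) is a meaningful edge
   sketch.
2. **Spatial decay with exceptions** — interaction likelihood decays with
   distance roughly as exp(−γ(d/d_c)²), but expression can rectify this:
   some nearby pairs interact less, some farther pairs more, than the
   decay predicts. The refined adjacency A′ = ω_o·A° + (1−ω_o)·decay makes
   that rectification explicit and inspectable.
3. **Transduction** — the model is fit to one section; embeddings and the
   adjacency are only defined for the cells it was trained on.

The three contrastive views encode complementary signals: the learner view
uses the *learned* graph, the positive view the raw kNN graph (a noisy but
unbiased spatial prior), and the negative view destroys the
feature-to-position pairing by row-shuffling while using the identity
adjacency — propagation through the identity is a pure per-node MLP, so no
neighborhood smoothing leaks structure back into the negatives.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `k_gamma` | 5 (6 for hexagonal spot grids) | raw kNN graph degree; kept low to limit noise in Γ |
| `k` | 20 | neighbor rank defining the cutoff d_c (median k-th-NN distance, unitless in coordinate units); larger k widens the candidate neighborhood |
| `omega_o` | 0.5 | balance of learned cosine vs. spatial decay in A′; lower it for low-gene-coverage panels |
| `gamma_decay` | 2.0 | decay rate of exp(−γ(d/d_c)²) |
| `omega_gamma` | 0.999 | conservation rate of the Γ bootstrap; Γ drifts ~0.1 % per update toward A |
| `tau` | 0.3 | NT-Xent temperature; small values sharpen the softmax |
| `epsilon_margin` | 0.5 | triplet safety margin |
| `omega_t` | 1.0 | triplet weight; 1.0 treats the two objectives as co-equal |
| `p_lr` / `p_pr` (= `p_nr`) | 0.6 / 0.9 | feature-mask rates for learner / positive+negative views |
| `p_le`, `p_pe` | 0.25 | edge-removal rates (moderate sparsification; not fixed by the model family, configurable) |
| dims `h_p, F, h_o, d_o, h, d_emb, h_φ, d_z` | 512, 512, 256, 64, 256, 64, 64, 32 | typical widths for contrastive ST encoders; all configurable |
| optimizer | Adam, lr 1e-3, weight decay 1e-5, 500 epochs | standard for this model class |

Deviating defaults used by the test-bench and `scripts/acceptance.py`:
a compact architecture (128/64/64/32/64/32/32/16) and 200 epochs, chosen
as the package's desk-scale reference problem (600 cells, 60 genes); at
this size the full benchmark — five replicates — completes in minutes on
one CPU with no change in qualitative behavior.

## Numerical choices

- **Dense float64 throughout the model.** The method is transductive and
  the learned adjacency is N×N anyway; for the intended desk scale
  (≤ a few thousand cells) dense linear algebra is faster and exactly
  reproducible. Sparse matrices are kept at the IO boundary and for Γ.
- **Autodiff.** Gradients come from a small reverse-mode engine
  (`autodiff.py`) with exactly the primitives the model needs. Gradient
  flows through the learner adjacency into the GCN normalization
  (degrees included); the spatial decay, distances, d_c, masks and Γ are
  constants.
- **Zero-norm rows in cosines** are defined as similarity 0 (avoids NaN;
  rectification would zero near-parallel negatives anyway). Euclidean
  norms use an exact-value sqrt whose *gradient* is clamped near zero so
  hinge terms sitting at zero distance stay finite.
- **NT-Xent stabilization** subtracts detached per-row/column maxima
  before exponentiation. The denominator includes the k = i term, exactly
  as the loss is defined. A single cell gives loss 0 (one-term softmax).
- **Mini-batch NT-Xent** samples one uniform batch per call and restricts
  the denominator to the batch; batch indices are kept sorted, so a batch
  of size N is bitwise the full loss.
- **kNN determinism**: exact Euclidean kNN with distance ties broken by
  ascending cell index; symmetrization by union (OR). Even-count medians
  are the mean of the middle two.
- **Coincident cells** (d = 0) are excluded from the learned adjacency
  support (the refinement is defined on strictly positive distances) but
  may remain Γ-neighbors; a warning is logged.
- **Zero-degree rows** in the symmetric normalization map to zero rows.
- **Zero-total cells** cannot be depth-normalized; the default drops them
  with a warning (strict mode raises).
- **Batch normalization** uses batch statistics (differentiated) during
  training and running averages (momentum 0.1, ε 1e-5) at inference.
- **HVG selection** ranks genes by variance-stabilized dispersion: a
  lowess fit of log10 variance on log10 mean (span 0.3, with the local
  window floored at 20 genes so tiny panels pool information), counts
  standardized by the fitted SD and clipped at √N, ranked by the variance
  of the clipped values. Selection only triggers for panels above the
  target size (default 3000).
- A genuinely useful identity for validation: with ω_o = 0 the adjacency
  is the closed-form decay graph regardless of parameters, and GCN
  propagation over the identity adjacency is exactly a perceptron — both
  are asserted in the tests.

## Design decisions where the design was open

- **Negative-view corruption** is a permutation of whole rows (cells),
  the standard corruption in this contrastive lineage; a within-row
  shuffle is not offered as it destroys the gene axis the projector
  relies on.
- **Γ bootstrap cadence**: once per epoch after the optimizer step
  (`gamma_update_every=1`), with A detached. At ω_Γ = 0.999 the graph
  moves slowly either way.
- **Embeddings for clustering are H** (encoder output), not the
  projection Z: the projection head exists to shape the contrastive
  space, H is the representation routed to downstream tasks.
- **Sensitivity score**: per gene, its raw counts are permuted across
  cells, the altered matrix passes through the *frozen* model (no
  retraining — a forward pass per gene keeps ~10³ genes tractable), both
  adjacencies are binarized at 0.5 and the score is the symmetric
  difference of edge sets normalized by the baseline edge count. A
  continuous alternative (1 − Pearson correlation over the union support)
  is available via `score="pearson"`. Identity permutations and
  constant genes score exactly 0 by construction.
- **Strength grouping for differential expression**: a neighbor cell
  joins the stronger (weaker) group if at least one of its edges to a
  center-type cell is labelled stronger (weaker); cells whose center
  edges carry one uniform label are excluded (no within-cell contrast),
  so mixed cells appear in both groups. Neutral edges count as variation.
  The group membership lists are the interface; the rank-sum DEG test
  itself is delegated to standard tooling.
- **Edge-count-matched CCI thresholding** breaks value ties
  lexicographically by (i, j) so the requested count is met exactly.
- **CCI analysis cutoff**: when comparing against ligand–receptor
  references the support can be restricted to the median
  10th-nearest-neighbor distance (`cutoff` argument / `--cutoff-k 10`),
  independent of the training d_c.

## The synthetic tissue and what passing tests show

`generate_layered_tissue` emulates laminar tissue (cortical-style layers):
cells uniform over a square section cut into `n_layers` horizontal bands,
each band with `markers_per_layer` dedicated marker genes whose
negative-binomial mean is `fold_change` × base inside the band
(NB via gamma–Poisson; `dispersion` is the quadratic overdispersion
coefficient α, var = μ + αμ²). Defaults — 600 cells, 60 genes, 3 layers,
5 markers/layer, base mean 1, fold change 8, α = 0.3, 2 % coordinate
jitter — give domains separable by expression *and* space, the regime the
model targets. `downsample_counts` implements dropout as binomial
thinning of count units (sequencing-depth loss); an entry-zeroing mode is
available. HVG selection is recomputed on downsampled matrices.

What the simulator does **not** emulate: spot-level cell-type mixing,
segmentation errors, spatially varying capture efficiency, batch effects,
curved or discontinuous domain geometry, and realistic gene–gene
correlation structure. Passing the recovery benchmark therefore shows the
machinery is correct and the optimization behaves as designed — not that
the model will attain any particular score on real tissue.

## Known limitations

- Transductive only: no inference on unseen cells.
- Dense N×N intermediates bound practical size to roughly 10⁴ cells on a
  typical workstation; the mini-batch NT-Xent helps the loss, not the
  adjacency memory.
- 2-D coordinates only.
- Exact numerical agreement of HVG selection with any particular
  package's implementation is not a contract; only the ranking behavior
  on separated dispersions is.
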