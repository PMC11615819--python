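"""Downstream analyses: spatial clustering, chance-corrected partition
metrics, CCI edge extraction and strength classification, neighbor
grouping for differential-expression input, and gene-shuffling
sensitivity scores.

The clustering metrics are implemented directly from the contingency
table: ARI with the pair-counting correction and AMI with the expected
mutual information under the hypergeometric (permutation) model and
arithmetic-mean normalization.

CCI strength classification compares each learned adjacency value with
its pure spatial-decay expectation e_ij = exp(-gamma (d_ij/d_c)^2):
edges below 0.7 e_ij are "weaker", edges above 0.7 e_ij + 0.3 are
"stronger", the band in between is neutral (a safety margin against
borderline calls).  Since adjacency values never exceed 1, a zero-distance
pair (e_ij = 1) can never be labelled stronger.

The sensitivity score of a gene measures how much shuffling that gene's
expression across cells perturbs the learned cell graph: both the
original and the perturbed refined adjacency are binarized and the score
is the normalized symmetric difference of the edge sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.cluster import KMeans

from .data_model_io import STDataset
from .training_engine import InferenceOutput, TrainedModel, infer

logger = logging.getLogger("stgsl")

__all__ = [
    "Partition",
    "CCIEdgeSet",
    "SensitivityResult",
    "kmeans_cluster",
    "ari",
    "ami",
    "extract_cci_edges",
    "classify_strength",
    "group_cells_by_strength",
    "gene_sensitivity",
]


# ---------------------------------------------------------------------------
# partitions and metrics
# ---------------------------------------------------------------------------

@dataclass
class Partition:
    """A clustering of N cells as a categorical label vector."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)

    def __len__(self):
        return len(self.labels)


def _labels(p) -> np.ndarray:
    return p.labels if isinstance(p, Partition) else np.asarray(p)


def _contingency(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    _, ui = np.unique(u, return_inverse=True)
    _, vi = np.unique(v, return_inverse=True)
    n = np.zeros((ui.max() + 1, vi.max() + 1), dtype=np.int64)
    np.add.at(n, (ui, vi), 1)
    return n


def _comb2(x):
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1) / 2.0


def kmeans_cluster(H: np.ndarray, n_clusters: int, seed: int = 0,
                   restarts: int = 10) -> Partition:
    """k-means on the embeddings (k-means++ init, best of `restarts`).

    Labels are relabelled to canonical order (largest cluster = 0) so the
    output is stable across numerically equivalent runs.
    """
    H = np.asarray(H)
    if n_clusters > H.shape[0]:
        raise ValueError("n_clusters exceeds the number of cells")
    km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=restarts,
                random_state=seed)
    raw = km.fit_predict(H)
    sizes = np.bincount(raw, minlength=n_clusters)
    order = np.lexsort((np.arange(n_clusters), -sizes))
    remap = np.empty(n_clusters, dtype=int)
    remap[order] = np.arange(n_clusters)
    return Partition(labels=remap[raw])


def ari(p1, p2) -> float:
    """Adjusted Rand index from the contingency table.

    Identical trivial partitions (degenerate denominator) score 1.
    """
    u, v = _labels(p1), _labels(p2)
    if len(u) != len(v):
        raise ValueError("partitions must have equal length")
    n = _contingency(u, v)
    total = _comb2(len(u))
    sum_nij = _comb2(n).sum()
    sum_a = _comb2(n.sum(axis=1)).sum()
    sum_b = _comb2(n.sum(axis=0)).sum()
    expected = sum_a * sum_b / total if total > 0 else 0.0
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0:
        return 1.0
    return float((sum_nij - expected) / denom)


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def _expected_mi(a: np.ndarray, b: np.ndarray, n: int) -> float:
    """E[MI] under the hypergeometric model of random labellings with the
    given marginals (computed in log space for stability)."""
    emi = 0.0
    log_n = np.log(n)
    gln_n = gammaln(n + 1)
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            term = nij / n * (np.log(nij) + log_n - np.log(ai) - np.log(bj))
            log_p = (gammaln(ai + 1) + gammaln(bj + 1)
                     + gammaln(n - ai + 1) + gammaln(n - bj + 1)
                     - gln_n - gammaln(nij + 1) - gammaln(ai - nij + 1)
                     - gammaln(bj - nij + 1)
                     - gammaln(n - ai - bj + nij + 1))
            emi += float((term * np.exp(log_p)).sum())
    return emi


def ami(p1, p2) -> float:
    """Adjusted mutual information (hypergeometric EMI, arithmetic mean)."""
    u, v = _labels(p1), _labels(p2)
    if len(u) != len(v):
        raise ValueError("partitions must have equal length")
    n = len(u)
    cont = _contingency(u, v)
    a = cont.sum(axis=1)
    b = cont.sum(axis=0)
    hu, hv = _entropy(a, n), _entropy(b, n)
    if hu == 0.0 and hv == 0.0:
        return 1.0  # identical trivial partitions
    nz = cont > 0
    pij = cont[nz] / n
    mi = float((pij * (np.log(cont[nz]) + np.log(n)
                       - np.log(a[nz.nonzero()[0]])
                       - np.log(b[nz.nonzero()[1]]))).sum())
    emi = _expected_mi(a, b, n)
    denom = 0.5 * (hu + hv) - emi
    eps = np.finfo(float).eps
    denom = max(denom, eps) if denom >= 0 else min(denom, -eps)
    return float((mi - emi) / denom)


# ---------------------------------------------------------------------------
# CCI edges
# ---------------------------------------------------------------------------

@dataclass
class CCIEdgeSet:
    """Undirected (i < j) learned-adjacency edges with decay expectations.

    ``edges`` columns: i, j, a_prime, d, e (= exp(-gamma (d/d_c)^2)) and,
    after classification, strength_label in {stronger, weaker, neutral}.
    """

    edges: pd.DataFrame
    d_c: float
    gamma_decay: float

    def __len__(self):
        return len(self.edges)


def extract_cci_edges(out: InferenceOutput,
                      target_edge_count: int | None = None,
                      threshold: float | None = None,
                      gamma_decay: float = 2.0,
                      cutoff: float | None = None) -> CCIEdgeSet:
    """Select CCI edges from the learned adjacency A'.

    Either keep pairs with a_prime > `threshold`, or — to match a
    reference method's edge count — keep exactly `target_edge_count`
    edges with the largest values (ties broken lexicographically by
    (i, j)).  ``cutoff`` optionally restricts the support to a shorter
    distance than the training d_c, e.g. the median 10th-nearest-neighbor
    distance used when comparing against ligand–receptor references.
    """
    if (target_edge_count is None) == (threshold is None):
        raise ValueError("give exactly one of target_edge_count / threshold")
    d_c = min(out.pairs.d_c, cutoff) if cutoff is not None else out.pairs.d_c
    tab = out.edge_table()
    tab = tab[tab["d"] <= d_c].reset_index(drop=True)
    tab["e"] = np.exp(-gamma_decay * (tab["d"] / d_c) ** 2)

    if threshold is not None:
        keep = tab[tab["a_prime"] > threshold].reset_index(drop=True)
    else:
        m = int(target_edge_count)
        if m > len(tab):
            warnings.warn("target_edge_count exceeds available pairs; keeping all")
            m = len(tab)
        order = np.lexsort((tab["j"], tab["i"], -tab["a_prime"]))
        keep = tab.iloc[order[:m]].sort_values(["i", "j"]).reset_index(drop=True)
    return CCIEdgeSet(edges=keep, d_c=d_c, gamma_decay=gamma_decay)


def classify_strength(edges: CCIEdgeSet, margin_lo: float = 0.7,
                      margin_hi_offset: float = 0.3) -> CCIEdgeSet:
    """Label each edge against its spatial-decay expectation.

    weaker  : a_prime < margin_lo * e
    stronger: a_prime > margin_lo * e + margin_hi_offset
    neutral : the safety band in between
    """
    tab = edges.edges.copy()
    lo = margin_lo * tab["e"]
    hi = lo + margin_hi_offset
    label = np.where(tab["a_prime"] < lo, "weaker",
                     np.where(tab["a_prime"] > hi, "stronger", "neutral"))
    tab["strength_label"] = label
    return _dc_replace(edges, edges=tab)


def group_cells_by_strength(edges: CCIEdgeSet, center_type, neighbor_type,
                            cell_types) -> tuple[set, set]:
    """Split neighbor-type cells by the strength of their edges to
    center-type cells — the membership lists that feed differential
    expression between the two groups.

    A neighbor cell joins the stronger (weaker) group when at least one of
    its edges to a center cell is labelled stronger (weaker); cells whose
    edges to center cells all carry one uniform label are dropped (no
    within-cell contrast), so mixed-strength cells can appear in both
    groups.
    """
    cell_types = np.asarray(cell_types)
    if "strength_label" not in edges.edges.columns:
        raise ValueError("run classify_strength first")
    per_cell: dict[int, set] = {}
    for row in edges.edges.itertuples(index=False):
        i, j = int(row.i), int(row.j)
        for center, nb in ((i, j), (j, i)):
            if cell_types[center] == center_type and cell_types[nb] == neighbor_type:
                per_cell.setdefault(nb, set()).add(row.strength_label)
    stronger, weaker = set(), set()
    for cell, lab in per_cell.items():
        if lab in ({"stronger"}, {"weaker"}, {"neutral"}):
            continue  # no varying strength with its neighbors
        if "stronger" in lab:
            stronger.add(cell)
        if "weaker" in lab:
            weaker.add(cell)
    if not stronger or not weaker:
        warnings.warn("empty strength group for this type pair")
    return stronger, weaker


# ---------------------------------------------------------------------------
# gene sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    """Per-gene perturbation scores, ranked descending."""

    scores: pd.DataFrame  # columns: gene, score, rank


def _edge_set(a_prime: np.ndarray, threshold: float) -> set:
    ii, jj = np.nonzero(np.triu(a_prime > threshold, k=1))
    return set(zip(ii.tolist(), jj.tolist()))


def gene_sensitivity(model: TrainedModel, ds: STDataset,
                     genes: list[str] | None = None,
                     threshold: float = 0.5, seed: int = 0,
                     score: str = "binary",
                     permutation: str = "shuffle") -> SensitivityResult:
    """Rank genes by how much shuffling each one perturbs the cell graph.

    One gene at a time, its raw counts are permuted across cells (a seeded
    uniform permutation; ``permutation="identity"`` runs the no-op
    control), the altered matrix is pushed through the frozen model, and
    the perturbed A' is compared with the baseline.  ``score="binary"``
    binarizes both at `threshold` and reports |E_g delta E_0| /
    max(|E_0|, 1); ``score="pearson"`` reports 1 - Pearson correlation of
    the A' values over the union support.
    """
    if ds.gene_names is None:
        raise ValueError("dataset must carry gene names")
    if genes is None:
        genes = list(model.gene_names or ds.gene_names)
    unknown = [g for g in genes if g not in ds.gene_names]
    if unknown:
        raise KeyError(f"unknown gene(s): {unknown}")
    base = infer(model, ds)
    base_a = base.refined_adjacency
    base_edges = _edge_set(base_a, threshold)
    rng = np.random.default_rng(seed)
    name_to_col = {g: i for i, g in enumerate(ds.gene_names)}
    counts = ds.counts_dense()

    rows = []
    for g in genes:
        perm = (np.arange(ds.n_cells) if permutation == "identity"
                else rng.permutation(ds.n_cells))
        altered = counts.copy()
        altered[:, name_to_col[g]] = altered[perm, name_to_col[g]]
        pert = infer(model, _dc_replace(ds, counts=altered))
        if score == "binary":
            e_g = _edge_set(pert.refined_adjacency, threshold)
            s = len(base_edges ^ e_g) / max(len(base_edges), 1)
        elif score == "pearson":
            mask = (base_a > 0) | (pert.refined_adjacency > 0)
            iu = np.triu(mask, k=1)
            x, y = base_a[iu], pert.refined_adjacency[iu]
            if x.size < 2 or x.std() == 0 or y.std() == 0:
                s = 0.0
            else:
                s = float(1.0 - np.corrcoef(x, y)[0, 1])
        else:
            raise ValueError(f"unknown score {score!r}")
        rows.append({"gene": g, "score": s})
    df = pd.DataFrame(rows).sort_values(["score", "gene"],
                                        ascending=[False, True],
                                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return SensitivityResult(scores=df)
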