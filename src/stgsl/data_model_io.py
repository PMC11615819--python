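"""Dataset container, standard-format IO and deterministic preprocessing.

The universal input record is :class:`STDataset`: a cells x genes
non-negative count matrix with 2-D spatial coordinates, optionally carrying
gene names, ground-truth domain labels and cell identifiers.  Accepted
on-disk containers are H5AD (AnnData), a MatrixMarket directory
(matrix.mtx + genes/barcodes lists + coordinates CSV) and plain CSV/TSV.

Preprocessing is the deterministic front end of the model: highly variable
gene selection (Seurat-v3-style standardized variance, applied only when
the gene panel exceeds the target size) and median-scaled log
normalization

    value[i, j] = ln( median_total * counts[i, j] / rowsum_i + 1 )

where ``median_total`` is the median across cells of the total count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("stgsl")

__all__ = [
    "STDataset",
    "NormalizedFeatures",
    "load_dataset",
    "select_hvg",
    "fp1_normalize",
    "export_results",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class STDataset:
    """A spatial transcriptomics dataset: counts, coordinates, annotations.

    ``counts`` may be dense (ndarray) or a scipy sparse matrix; sparsity is
    preserved end-to-end and densified only at the model boundary.
    """

    counts: np.ndarray | sp.spmatrix
    coords: np.ndarray
    gene_names: list[str] | None = None
    labels: np.ndarray | None = None
    cell_ids: list[str] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("dimension mismatch: coords must be N x 2")
        if self.coords.shape[0] != self.counts.shape[0]:
            raise ValueError(
                f"dimension mismatch: {self.counts.shape[0]} cells in counts "
                f"vs {self.coords.shape[0]} coordinate rows")
        if self.counts_min() < 0:
            raise ValueError("invalid count matrix: negative entries")
        if self.gene_names is not None:
            self.gene_names = list(self.gene_names)
            if len(self.gene_names) != self.counts.shape[1]:
                raise ValueError("dimension mismatch: gene_names length")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.counts.shape[0]:
                raise ValueError("dimension mismatch: labels length")
        if self.cell_ids is not None:
            self.cell_ids = [str(c) for c in self.cell_ids]
            if len(self.cell_ids) != self.counts.shape[0]:
                raise ValueError("dimension mismatch: cell_ids length")

    def counts_min(self) -> float:
        if sp.issparse(self.counts):
            stored = self.counts.data.min() if self.counts.nnz else 0.0
            implicit_zero = self.counts.nnz < np.prod(self.counts.shape)
            return float(min(stored, 0.0) if implicit_zero else stored)
        arr = np.asarray(self.counts)
        return float(arr.min()) if arr.size else 0.0

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def counts_dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)

    def subset_genes(self, index: np.ndarray) -> "STDataset":
        counts = self.counts[:, index] if not sp.issparse(self.counts) \
            else self.counts.tocsc()[:, index].tocsr()
        names = [self.gene_names[i] for i in index] if self.gene_names else None
        return replace(self, counts=counts, gene_names=names)

    def subset_cells(self, index: np.ndarray) -> "STDataset":
        return replace(
            self,
            counts=self.counts[index],
            coords=self.coords[index],
            labels=None if self.labels is None else self.labels[index],
            cell_ids=None if self.cell_ids is None
            else [self.cell_ids[i] for i in np.atleast_1d(np.arange(self.n_cells)[index])],
        )


@dataclass
class NormalizedFeatures:
    """Median-scaled log-normalized expression values.

    ``kept`` marks the cells with positive total counts; in the default
    (non-strict) mode zero-total cells are dropped from ``values`` and the
    mask records which rows survive.
    """

    values: np.ndarray
    median_total: float
    kept: np.ndarray = field(default=None)  # boolean over original cells

    def __post_init__(self):
        if self.kept is None:
            self.kept = np.ones(self.values.shape[0], dtype=bool)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "mtx_dir"
    if path.suffix == ".h5ad":
        return "h5ad"
    return "csv"


def load_dataset(path, format: str | None = None, *,
                 coords_path=None, coords_key: str = "spatial",
                 label_key: str | None = None) -> STDataset:
    """Read an ST dataset from H5AD, an MTX directory, or a CSV/TSV pair.

    For ``csv``, ``path`` is the counts table (cells x genes, header row of
    gene names, first column of cell ids) and ``coords_path`` the matching
    coordinates table with columns ``cell_id,x,y``; when ``coords_path`` is
    omitted a sibling ``<stem>.coords.csv`` is tried.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)

    if fmt == "h5ad":
        import anndata as ad
        adata = ad.read_h5ad(path)
        if coords_key not in adata.obsm:
            raise ValueError("coordinates required: obsm key "
                             f"{coords_key!r} missing")
        labels = None
        if label_key is not None and label_key in adata.obs:
            labels = np.asarray(adata.obs[label_key])
        X = adata.X
        counts = X if sp.issparse(X) else np.asarray(X)
        return STDataset(counts=counts,
                         coords=np.asarray(adata.obsm[coords_key])[:, :2],
                         gene_names=list(adata.var_names),
                         labels=labels,
                         cell_ids=list(adata.obs_names))

    if fmt == "mtx_dir":
        from scipy.io import mmread
        mtx = None
        for name in ("matrix.mtx", "counts.mtx"):
            if (path / name).exists():
                mtx = sp.csr_matrix(mmread(path / name))
                break
        if mtx is None:
            raise FileNotFoundError(f"no matrix.mtx in {path}")
        coords_file = None
        for name in ("coords.csv", "coordinates.csv"):
            if (path / name).exists():
                coords_file = path / name
                break
        if coords_file is None:
            raise ValueError("coordinates required: no coords.csv in MTX directory")
        cdf = pd.read_csv(coords_file)
        genes = None
        for name in ("genes.tsv", "features.tsv"):
            if (path / name).exists():
                genes = pd.read_csv(path / name, sep="\t", header=None)[0].tolist()
                break
        barcodes = None
        if (path / "barcodes.tsv").exists():
            barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t",
                                   header=None)[0].tolist()
        n_cells = len(cdf)
        if mtx.shape[0] != n_cells and mtx.shape[1] == n_cells:
            mtx = mtx.T.tocsr()  # genes x cells on disk
        return STDataset(counts=mtx,
                         coords=cdf[["x", "y"]].to_numpy(),
                         gene_names=genes,
                         cell_ids=[str(c) for c in cdf["cell_id"]]
                         if "cell_id" in cdf else barcodes)

    if fmt == "csv":
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        cpath = Path(coords_path) if coords_path else path.with_suffix(".coords.csv")
        if not cpath.exists():
            raise ValueError("coordinates required: no coordinates table found")
        cdf = pd.read_csv(cpath)
        return STDataset(counts=df.to_numpy(dtype=float),
                         coords=cdf[["x", "y"]].to_numpy(),
                         gene_names=list(df.columns),
                         cell_ids=[str(i) for i in df.index])

    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# highly variable genes (Seurat-v3-style standardized variance)
# ---------------------------------------------------------------------------

def _standardized_variance(counts: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Per-gene variance of clipped standardized counts.

    A lowess fit of log10(variance) on log10(mean) gives each gene an
    expected standard deviation; counts are standardized with it, clipped
    at sqrt(N), and the variance of the clipped values is the ranking
    statistic.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    n = counts.shape[0]
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    stat = np.zeros(counts.shape[1])
    ok = (mean > 0) & (var > 0)
    if ok.sum() < 2:
        return stat
    x = np.log10(mean[ok])
    y = np.log10(var[ok])
    # keep the local window at >= 20 genes so tiny panels are pooled
    frac = min(1.0, max(span, 20.0 / ok.sum()))
    fitted = lowess(y, x, frac=frac, return_sorted=False)
    sd_exp = np.sqrt(10.0 ** fitted)
    clip = np.sqrt(n)
    z = (counts[:, ok] - mean[ok]) / sd_exp
    np.clip(z, -clip, clip, out=z)
    stat[ok] = np.sum(z ** 2, axis=0) / (n - 1) - n * z.mean(axis=0) ** 2 / (n - 1)
    return stat


def select_hvg(ds: STDataset, n_top: int = 3000) -> STDataset:
    """Retain the ``n_top`` most variable genes (no-op when F_g <= n_top).

    The retained set keeps the original gene order; ranking is by
    variance-stabilized dispersion as in the Seurat v3 procedure.
    """
    if n_top <= 0:
        raise ValueError("invalid n_top")
    if ds.n_genes <= n_top:
        return ds
    counts = ds.counts_dense()
    stat = _standardized_variance(counts)
    # top n_top by statistic, ties broken by gene index; original order kept
    order = np.lexsort((np.arange(len(stat)), -stat))
    keep = np.sort(order[:n_top])
    return ds.subset_genes(keep)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def fp1_normalize(ds: STDataset, strict: bool = False) -> NormalizedFeatures:
    """Median-scaled log normalization of the raw counts.

    Cells with zero total count cannot be normalized (the transform divides
    by the row sum).  In strict mode they raise; by default they are
    dropped with a warning and the surviving rows are flagged in ``kept``.
    The median total is computed over the surviving cells.
    """
    counts = ds.counts_dense()
    rowsum = counts.sum(axis=1)
    kept = rowsum > 0
    if not kept.all():
        if strict:
            raise ValueError(f"empty cell: {int((~kept).sum())} cells have zero total count")
        logger.warning("dropping %d zero-total cells before normalization",
                       int((~kept).sum()))
        warnings.warn("dropping zero-total cells", stacklevel=2)
    counts = counts[kept]
    rowsum = rowsum[kept]
    median_total = float(np.median(rowsum))
    values = np.log1p(median_total * counts / rowsum[:, None])
    if not np.isfinite(values).all():
        raise ArithmeticError("non-finite normalized values")
    return NormalizedFeatures(values=values, median_total=median_total, kept=kept)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_results(labels, embeddings, edges: pd.DataFrame, out_dir) -> None:
    """Write cluster labels, embeddings and the CCI edge table.

    Produces ``labels.csv`` (cell_id, cluster), ``embeddings.tsv`` and
    ``cci_edges.tsv`` (source, target, adjacency_value, distance); all three
    round-trip losslessly through :func:`pandas.read_csv`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(labels)
    pd.DataFrame({"cell_id": np.arange(len(labels)), "cluster": labels}) \
        .to_csv(out / "labels.csv", index=False)
    pd.DataFrame(np.asarray(embeddings)).to_csv(out / "embeddings.tsv",
                                                sep="\t", index=False)
    cols = ["source", "target", "adjacency_value", "distance"]
    if edges is None or len(edges) == 0:
        pd.DataFrame(columns=cols).to_csv(out / "cci_edges.tsv", sep="\t", index=False)
    else:
        edges = edges.rename(columns={"i": "source", "j": "target",
                                      "a_prime": "adjacency_value",
                                      "d": "distance"})
        edges[[c for c in cols if c in edges.columns]
              + [c for c in edges.columns if c not in cols]] \
            .to_csv(out / "cci_edges.tsv", sep="\t", index=False)
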