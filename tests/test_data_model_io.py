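"""Dataset container, format round-trips, HVG selection and normalization."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from stgsl import (STDataset, export_results, fp1_normalize, load_dataset,
                   select_hvg)


def _toy(n=3, g=4, seed=0):
    rng = np.random.default_rng(seed)
    return STDataset(counts=rng.poisson(3, size=(n, g)).astype(float) + 1,
                     coords=rng.uniform(size=(n, 2)),
                     gene_names=[f"g{i}" for i in range(g)],
                     cell_ids=[f"c{i}" for i in range(n)])


class TestSTDataset:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="invalid count matrix"):
            STDataset(counts=np.array([[-1.0, 2.0]]), coords=np.zeros((1, 2)))
        with pytest.raises(ValueError, match="dimension mismatch"):
            STDataset(counts=np.ones((3, 4)), coords=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="dimension mismatch"):
            STDataset(counts=np.ones((3, 4)), coords=np.zeros((3, 2)),
                      gene_names=["a", "b"])

    def test_sparse_counts_preserved(self):
        ds = STDataset(counts=sp.csr_matrix(np.eye(4)), coords=np.zeros((4, 2)))
        assert sp.issparse(ds.counts)
        assert ds.counts_min() == 0.0


class TestLoadDataset:
    def test_csv_pair_shapes(self, tmp_path):
        counts = pd.DataFrame(np.arange(12).reshape(3, 4),
                              index=["c0", "c1", "c2"],
                              columns=list("abcd"))
        counts.to_csv(tmp_path / "m.csv")
        pd.DataFrame({"cell_id": ["c0", "c1", "c2"],
                      "x": [0, 1, 2], "y": [0, 0, 0]}) \
            .to_csv(tmp_path / "m.coords.csv", index=False)
        ds = load_dataset(tmp_path / "m.csv", format="csv")
        assert (ds.n_cells, ds.n_genes) == (3, 4)
        assert ds.gene_names == list("abcd")

    def test_csv_coords_row_mismatch(self, tmp_path):
        pd.DataFrame(np.ones((3, 2)), index=list("abc"),
                     columns=["g1", "g2"]).to_csv(tmp_path / "m.csv")
        pd.DataFrame({"cell_id": ["a", "b"], "x": [0, 1], "y": [0, 0]}) \
            .to_csv(tmp_path / "m.coords.csv", index=False)
        with pytest.raises(ValueError, match="dimension mismatch"):
            load_dataset(tmp_path / "m.csv", format="csv")

    def test_missing_coords(self, tmp_path):
        pd.DataFrame(np.ones((2, 2))).to_csv(tmp_path / "m.csv")
        with pytest.raises(ValueError, match="coordinates required"):
            load_dataset(tmp_path / "m.csv", format="csv")

    def test_h5ad_round_trip(self, tmp_path):
        import anndata as ad
        ds = _toy(5, 6)
        adata = ad.AnnData(X=ds.counts_dense(),
                           obs=pd.DataFrame(index=ds.cell_ids),
                           var=pd.DataFrame(index=ds.gene_names))
        adata.obsm["spatial"] = ds.coords
        adata.write_h5ad(tmp_path / "d.h5ad")
        back = load_dataset(tmp_path / "d.h5ad")
        np.testing.assert_array_equal(back.counts_dense(), ds.counts_dense())
        np.testing.assert_allclose(back.coords, ds.coords)
        assert back.gene_names == ds.gene_names
        assert back.cell_ids == ds.cell_ids

    def test_mtx_dir_round_trip(self, tmp_path):
        from scipy.io import mmwrite
        ds = _toy(4, 5)
        mmwrite(tmp_path / "matrix.mtx", sp.csr_matrix(ds.counts))
        pd.DataFrame({"cell_id": ds.cell_ids, "x": ds.coords[:, 0],
                      "y": ds.coords[:, 1]}).to_csv(tmp_path / "coords.csv",
                                                    index=False)
        pd.Series(ds.gene_names).to_csv(tmp_path / "genes.tsv", sep="\t",
                                        index=False, header=False)
        back = load_dataset(tmp_path, format="mtx_dir")
        np.testing.assert_array_equal(back.counts_dense(), ds.counts_dense())
        assert back.gene_names == ds.gene_names


class TestSelectHVG:
    def test_no_op_when_panel_small(self):
        ds = _toy(10, 20)
        assert select_hvg(ds, n_top=3000) is ds

    def test_cardinality(self):
        rng = np.random.default_rng(1)
        ds = STDataset(counts=rng.poisson(2, size=(50, 40)).astype(float),
                       coords=rng.uniform(size=(50, 2)),
                       gene_names=[f"g{i}" for i in range(40)])
        out = select_hvg(ds, n_top=10)
        assert out.n_genes == 10
        # retained genes keep their original relative order
        idx = [ds.gene_names.index(g) for g in out.gene_names]
        assert idx == sorted(idx)

    def test_dominant_dispersion_gene_retained(self):
        rng = np.random.default_rng(2)
        n = 200
        counts = rng.poisson(5, size=(n, 10)).astype(float)
        # gene 0: same mean as the rest, strongly inflated variance
        counts[: n // 2, 0] = 0.0
        counts[n // 2:, 0] = 10.0
        ds = STDataset(counts=counts, coords=rng.uniform(size=(n, 2)),
                       gene_names=[f"g{i}" for i in range(10)])
        out = select_hvg(ds, n_top=1)
        assert out.gene_names == ["g0"]

    def test_invalid_n_top(self):
        with pytest.raises(ValueError, match="invalid n_top"):
            select_hvg(_toy(), n_top=0)


class TestFp1Normalize:
    def test_single_cell_identity(self):
        ds = STDataset(counts=np.array([[5.0]]), coords=np.zeros((1, 2)))
        nf = fp1_normalize(ds)
        assert nf.median_total == 5.0
        np.testing.assert_allclose(nf.values, [[np.log(6.0)]])

    def test_hand_worked_two_by_two(self):
        ds = STDataset(counts=np.array([[1.0, 1.0], [2.0, 2.0]]),
                       coords=np.zeros((2, 2)))
        nf = fp1_normalize(ds)
        assert nf.median_total == 3.0  # mean of middle two rowsums (2, 4)
        np.testing.assert_allclose(nf.values, np.log(2.5) * np.ones((2, 2)))

    def test_zero_column_maps_to_zero(self):
        ds = STDataset(counts=np.array([[0.0, 4.0], [0.0, 4.0]]),
                       coords=np.zeros((2, 2)))
        nf = fp1_normalize(ds)
        np.testing.assert_array_equal(nf.values[:, 0], [0.0, 0.0])

    def test_depth_invariance_between_proportional_cells(self):
        """Per-cell depth is divided out: cells with proportional count
        vectors normalize to identical rows."""
        base = np.array([[2.0, 3.0, 5.0]])
        counts = np.vstack([base, 4.0 * base, 0.5 * base])
        nf = fp1_normalize(STDataset(counts=counts, coords=np.zeros((3, 2))))
        np.testing.assert_allclose(nf.values[1], nf.values[0], rtol=1e-12)
        np.testing.assert_allclose(nf.values[2], nf.values[0], rtol=1e-12)

    def test_global_scaling_acts_through_median_total(self):
        """Scaling all counts by s multiplies median_total and rowsums by s,
        so the linear-scale values expm1(f_p1) scale by s exactly."""
        ds = _toy(6, 5, seed=3)
        a = fp1_normalize(ds)
        b = fp1_normalize(STDataset(counts=ds.counts_dense() * 7.0,
                                    coords=ds.coords))
        assert b.median_total == pytest.approx(7.0 * a.median_total)
        np.testing.assert_allclose(np.expm1(b.values), 7.0 * np.expm1(a.values),
                                   rtol=1e-9)

    def test_row_permutation_equivariance(self):
        ds = _toy(8, 5, seed=4)
        perm = np.random.default_rng(0).permutation(8)
        nf = fp1_normalize(ds)
        nf_p = fp1_normalize(STDataset(counts=ds.counts_dense()[perm],
                                       coords=ds.coords[perm]))
        np.testing.assert_allclose(nf_p.values, nf.values[perm], rtol=1e-12)

    def test_zero_total_cells(self):
        counts = np.array([[1.0, 2.0], [0.0, 0.0], [3.0, 1.0]])
        ds = STDataset(counts=counts, coords=np.zeros((3, 2)))
        with pytest.raises(ValueError, match="empty cell"):
            fp1_normalize(ds, strict=True)
        with pytest.warns(UserWarning):
            nf = fp1_normalize(ds)
        assert nf.values.shape[0] == 2
        np.testing.assert_array_equal(nf.kept, [True, False, True])


class TestExportResults:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, size=5)
        emb = rng.normal(size=(5, 4))
        edges = pd.DataFrame({"i": [0, 1], "j": [2, 3],
                              "a_prime": [0.9, 0.4], "d": [1.0, 2.0]})
        export_results(labels, emb, edges, tmp_path)
        back_labels = pd.read_csv(tmp_path / "labels.csv")
        np.testing.assert_array_equal(back_labels["cluster"], labels)
        back_emb = pd.read_csv(tmp_path / "embeddings.tsv", sep="\t")
        np.testing.assert_allclose(back_emb.to_numpy(), emb)
        back_edges = pd.read_csv(tmp_path / "cci_edges.tsv", sep="\t")
        np.testing.assert_allclose(back_edges["adjacency_value"], [0.9, 0.4])

    def test_empty_edge_set(self, tmp_path):
        export_results([0, 1], np.zeros((2, 2)), pd.DataFrame(), tmp_path)
        back = pd.read_csv(tmp_path / "cci_edges.tsv", sep="\t")
        assert len(back) == 0
        assert list(back.columns) == ["source", "target", "adjacency_value",
                                      "distance"]
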