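"""Clustering, ARI/AMI, CCI edge extraction/classification/grouping,
gene sensitivity."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score

from stgsl import (CCIEdgeSet, ami, ari, classify_strength, extract_cci_edges,
                   gene_sensitivity, group_cells_by_strength, infer,
                   kmeans_cluster)


class TestKmeans:
    def test_separated_clouds_perfectly_split(self):
        rng = np.random.default_rng(0)
        h = np.vstack([rng.normal(0, 0.1, size=(30, 3)),
                       rng.normal(10, 0.1, size=(30, 3))])
        truth = np.repeat([0, 1], 30)
        part = kmeans_cluster(h, 2, seed=0)
        assert ari(part.labels, truth) == 1.0

    def test_n_clusters_equals_n(self):
        h = np.arange(10.0)[:, None] * 100
        part = kmeans_cluster(h, 10, seed=0)
        assert len(set(part.labels)) == 10

    def test_seed_determinism(self):
        h = np.random.default_rng(1).normal(size=(50, 4))
        a = kmeans_cluster(h, 4, seed=3)
        b = kmeans_cluster(h, 4, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_canonical_relabeling(self):
        h = np.r_[np.zeros((40, 1)), np.full((10, 1), 50.0)]
        part = kmeans_cluster(h, 2, seed=0)
        assert (part.labels[:40] == 0).all()  # largest cluster gets label 0

    def test_too_many_clusters(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((3, 2)), 4)


class TestMetrics:
    def test_identical_partitions_score_one(self):
        labels = np.array([0, 0, 1, 1, 2, 2, 2])
        assert ari(labels, labels) == 1.0
        assert ami(labels, labels) == pytest.approx(1.0, abs=1e-12)

    def test_hand_contingency(self):
        # contingency [[2, 0], [1, 1]]
        a = np.array([1, 1, 2, 2])
        b = np.array([1, 1, 1, 2])
        sum_nij = 1.0       # C(2,2)
        sum_a = 1.0 + 1.0   # C(2,2) + C(2,2)
        sum_b = 3.0 + 0.0   # C(3,2)
        total = 6.0         # C(4,2)
        expected = (sum_nij - sum_a * sum_b / total) / (
            0.5 * (sum_a + sum_b) - sum_a * sum_b / total)
        assert ari(a, b) == pytest.approx(expected, abs=1e-12)

    def test_trivial_single_cluster_pair(self):
        a = np.zeros(5, dtype=int)
        assert ari(a, a) == 1.0
        assert ami(a, a) == 1.0

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_sklearn_reference(self, trial):
        rng = np.random.default_rng(300 + trial)
        n = int(rng.integers(10, 60))
        a = rng.integers(0, rng.integers(2, 6), size=n)
        b = rng.integers(0, rng.integers(2, 6), size=n)
        assert ari(a, b) == pytest.approx(adjusted_rand_score(a, b),
                                          abs=1e-10)
        assert ami(a, b) == pytest.approx(
            adjusted_mutual_info_score(a, b, average_method="arithmetic"),
            abs=1e-10)

    def test_independent_partitions_near_zero(self):
        rng = np.random.default_rng(4)
        n = 10_000
        a = rng.integers(0, 5, size=n)
        b = rng.integers(0, 5, size=n)
        assert abs(ari(a, b)) < 0.02
        assert abs(ami(a, b)) < 0.02

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ari([0, 1], [0, 1, 2])
        with pytest.raises(ValueError):
            ami([0, 1], [0, 1, 2])


def _edge_set(values, distances, d_c=1.0, gamma=2.0):
    tab = pd.DataFrame({
        "i": np.arange(len(values)),
        "j": np.arange(len(values)) + 100,
        "a_prime": values,
        "d": distances,
    })
    tab["e"] = np.exp(-gamma * (tab["d"] / d_c) ** 2)
    return CCIEdgeSet(edges=tab, d_c=d_c, gamma_decay=gamma)


class TestExtractCci(object):
    def test_threshold_and_count_selection(self, tiny_trained):
        model, _, ds = tiny_trained
        out = infer(model, ds)
        by_count = extract_cci_edges(out, target_edge_count=50)
        assert len(by_count) == 50
        thr = extract_cci_edges(out, threshold=0.5)
        assert (thr.edges["a_prime"] > 0.5).all()

    def test_count_matches_sorting_oracle(self, tiny_trained):
        model, _, ds = tiny_trained
        out = infer(model, ds)
        all_edges = out.edge_table()
        m = 20
        sel = extract_cci_edges(out, target_edge_count=m)
        top = np.sort(all_edges["a_prime"].to_numpy())[-m:]
        np.testing.assert_allclose(np.sort(sel.edges["a_prime"].to_numpy()),
                                   top)

    def test_count_exceeding_pairs_keeps_all(self, tiny_trained):
        model, _, ds = tiny_trained
        out = infer(model, ds)
        n_avail = len(out.edge_table())
        with pytest.warns(UserWarning):
            sel = extract_cci_edges(out, target_edge_count=n_avail + 1000)
        assert len(sel) == n_avail

    def test_shorter_cutoff_restricts_support(self, tiny_trained):
        model, _, ds = tiny_trained
        out = infer(model, ds)
        short = extract_cci_edges(out, threshold=0.0,
                                  cutoff=out.pairs.d_c / 2)
        assert (short.edges["d"] <= out.pairs.d_c / 2).all()


class TestClassifyStrength:
    def test_boundary_cases(self):
        es = _edge_set([0.3, 0.7], [np.sqrt(np.log(2) / 2)] * 2)  # e = 0.5
        np.testing.assert_allclose(es.edges["e"], 0.5)
        out = classify_strength(es)
        assert list(out.edges["strength_label"]) == ["weaker", "stronger"]

    def test_zero_distance_cannot_be_stronger(self):
        es = _edge_set([1.0], [0.0])  # e = 1, threshold 0.7 + 0.3 = 1.0
        out = classify_strength(es)
        assert out.edges["strength_label"].iloc[0] != "stronger"

    def test_labels_partition_edges(self):
        rng = np.random.default_rng(5)
        es = _edge_set(rng.uniform(0, 1, 200), rng.uniform(0, 1, 200))
        out = classify_strength(es)
        lab = out.edges["strength_label"]
        assert set(lab) <= {"stronger", "weaker", "neutral"}
        assert len(lab) == 200  # every edge gets exactly one label


class TestGrouping:
    def _edges(self, rows):
        tab = pd.DataFrame(rows, columns=["i", "j", "strength_label"])
        tab["a_prime"] = 0.5
        tab["d"] = 0.5
        tab["e"] = 0.5
        return CCIEdgeSet(edges=tab, d_c=1.0, gamma_decay=2.0)

    def test_mixed_cell_in_both_groups(self):
        # cell 2 (type B) has a stronger edge to center 0 and weaker to 1
        edges = self._edges([(0, 2, "stronger"), (1, 2, "weaker")])
        types = np.array(["A", "A", "B"])
        stronger, weaker = group_cells_by_strength(edges, "A", "B", types)
        assert stronger == {2} and weaker == {2}

    def test_consistent_cell_excluded(self):
        edges = self._edges([(0, 2, "stronger"), (1, 2, "stronger"),
                             (0, 3, "stronger"), (1, 3, "weaker")])
        types = np.array(["A", "A", "B", "B"])
        with pytest.warns(UserWarning):
            # cell 2 is uniformly stronger -> dropped; cell 3 mixed -> both
            stronger, weaker = group_cells_by_strength(
                self._edges([(0, 2, "stronger"), (1, 2, "stronger")]),
                "A", "B", np.array(["A", "A", "B"]))
        assert stronger == set() and weaker == set()
        stronger, weaker = group_cells_by_strength(edges, "A", "B", types)
        assert 2 not in stronger and stronger == {3} and weaker == {3}

    def test_no_edges_for_type_pair(self):
        edges = self._edges([(0, 1, "stronger")])
        types = np.array(["A", "A"])
        with pytest.warns(UserWarning):
            stronger, weaker = group_cells_by_strength(edges, "A", "B", types)
        assert stronger == set() and weaker == set()


class TestSensitivity:
    def test_identity_control_scores_zero(self, tiny_trained):
        model, _, ds = tiny_trained
        res = gene_sensitivity(model, ds, genes=ds.gene_names[:3],
                               permutation="identity")
        assert (res.scores["score"] == 0.0).all()

    def test_constant_gene_scores_zero(self, tiny_trained):
        import dataclasses
        model, _, ds = tiny_trained
        counts = ds.counts_dense()
        counts[:, 5] = 3.0  # make gene 5 constant across cells
        flat = dataclasses.replace(ds, counts=counts)
        res = gene_sensitivity(model, flat, genes=[ds.gene_names[5]], seed=0)
        assert res.scores["score"].iloc[0] == 0.0

    def test_unknown_gene_rejected(self, tiny_trained):
        model, _, ds = tiny_trained
        with pytest.raises(KeyError, match="unknown gene"):
            gene_sensitivity(model, ds, genes=["no_such_gene"])

    def test_ranking_is_descending(self, tiny_trained):
        model, _, ds = tiny_trained
        res = gene_sensitivity(model, ds, genes=ds.gene_names[:5], seed=1)
        s = res.scores["score"].to_numpy()
        assert (np.diff(s) <= 0).all()
        assert list(res.scores["rank"]) == [1, 2, 3, 4, 5]
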