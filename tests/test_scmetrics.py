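"""Single-cell QC, embedding and concordance metrics."""

import numpy as np
import pandas as pd
import pytest

from lanesplit import scmetrics as sm
from lanesplit.splitsim import SplitSpec, split_count_matrix


def make_counts(rng, n_genes=50, n_cells=20):
    return pd.DataFrame(
        rng.integers(0, 30, (n_genes, n_cells)),
        index=[f"G{i}" for i in range(n_genes)],
        columns=[f"C{i}" for i in range(n_cells)],
    )


class TestQcFilterCells:
    def _matrix(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(1200)] + ["MT1", "MT2", "RP1", "RP2"]
        cells = [f"C{i}" for i in range(6)]
        cm = pd.DataFrame(
            rng.integers(1, 5, (len(genes), len(cells))), index=genes, columns=cells
        )
        cm.loc[["RP1", "RP2"]] = 600  # plenty of ribosomal signal by default
        return cm

    def test_strict_gene_threshold(self):
        cm = self._matrix()
        cm.loc[[f"G{i}" for i in range(300)], "C0"] = 0  # C0 detects < 1000 genes
        filtered, report = sm.qc_filter_cells(
            cm, mt_genes=["MT1", "MT2"], rp_genes=["RP1", "RP2"], mode="10x"
        )
        assert "C0" not in filtered.columns
        assert report["removed_low_genes"] == 1

    def test_mt_and_rp_fractions(self):
        cm = self._matrix()
        cm.loc[["MT1", "MT2"], "C1"] = 400  # MT fraction above 10%
        cm.loc[["RP1", "RP2"], "C2"] = 0  # RP fraction below 20%
        filtered, report = sm.qc_filter_cells(
            cm, mt_genes=["MT1", "MT2"], rp_genes=["RP1", "RP2"], mode="10x"
        )
        assert {"C1", "C2"}.isdisjoint(filtered.columns)
        assert report["removed_high_mt"] >= 1
        assert report["removed_low_rp"] >= 1
        # MT/RP genes dropped from the surviving matrix
        assert {"MT1", "MT2", "RP1", "RP2"}.isdisjoint(filtered.index)

    def test_smartseq_mode(self):
        rng = np.random.default_rng(2)
        cm = make_counts(rng, n_genes=120, n_cells=10)
        cm.iloc[60:, :] = 0  # features in no cells
        cm.iloc[:, 0] = 0
        cm.iloc[:30, 0] = 1  # cell 0 has only 30 features
        filtered, report = sm.qc_filter_cells(cm, mode="smartseq")
        assert "C0" not in filtered.columns
        assert report["features_removed"] >= 60

    def test_all_cells_removed_raises(self):
        cm = pd.DataFrame(np.zeros((10, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="all cells removed"):
            sm.qc_filter_cells(cm, mode="smartseq")


class TestKnnGraph:
    def test_collinear_points(self):
        emb = pd.DataFrame({"x": [0.0, 1.0, 2.0]}, index=["a", "b", "c"])
        g = sm.knn_graph(emb, k=1)
        assert g["a"] == ["b"] and g["c"] == ["b"]

    def test_matches_brute_force(self, rng):
        emb = pd.DataFrame(rng.normal(size=(50, 4)), index=[f"c{i}" for i in range(50)])
        g = sm.knn_graph(emb, k=5)
        x = emb.to_numpy()
        for i, cell in enumerate(emb.index):
            d = ((x - x[i]) ** 2).sum(axis=1)
            d[i] = np.inf
            expect = [emb.index[j] for j in np.argsort(d, kind="stable")[:5]]
            assert g[cell] == expect

    def test_complete_graph(self):
        emb = pd.DataFrame(np.eye(4), index=list("abcd"))
        g = sm.knn_graph(emb, k=3)
        for cell in emb.index:
            assert set(g[cell]) == set(emb.index) - {cell}

    def test_k_too_large_rejected(self):
        emb = pd.DataFrame(np.eye(3), index=list("abc"))
        with pytest.raises(ValueError):
            sm.knn_graph(emb, k=3)


class TestMarkerJsi:
    def test_identical_sets(self):
        assert sm.cluster_marker_jsi({"a", "b"}, {"a", "b"}) == 1.0

    def test_empty_set_convention(self):
        assert sm.cluster_marker_jsi(set(), {"a"}) == 0.0
        assert sm.cluster_marker_jsi({"a"}, set()) == 0.0
        assert sm.cluster_marker_jsi(set(), set()) == 0.0

    def test_smaller_set_restriction(self):
        # full containment of the smaller set scores 1 under the overlap rule
        assert sm.cluster_marker_jsi({"g1", "g2", "g3", "g4"}, {"g1", "g2"}) == 1.0
        assert sm.cluster_marker_jsi(
            {"g1", "g2", "g3", "g4"}, {"g1", "g2"}, method="jaccard"
        ) == pytest.approx(0.5)

    def test_bounded(self, rng):
        for _ in range(20):
            a = set(rng.choice(50, rng.integers(0, 10), replace=False).tolist())
            b = set(rng.choice(50, rng.integers(0, 10), replace=False).tolist())
            v = sm.cluster_marker_jsi(a, b)
            assert 0.0 <= v <= 1.0


class TestPerCellMarkerJsi:
    @staticmethod
    def _markers(d):
        rows = [
            {"cluster": cl, "gene": g, "effect_size": 1.0, "padj": 0.01}
            for cl, genes in d.items()
            for g in genes
        ]
        return pd.DataFrame(rows)

    def test_identical_everything(self):
        ca = pd.Series(["x", "x", "y"], index=["c1", "c2", "c3"])
        mk = self._markers({"x": ["g1", "g2"], "y": ["g3"]})
        out = sm.per_cell_marker_jsi(ca, ca.copy(), mk, mk.copy())
        assert (out == 1.0).all()

    def test_empty_marker_list_scores_zero(self):
        ca = pd.Series(["x"], index=["c1"])
        cb = pd.Series(["z"], index=["c1"])
        ma = self._markers({"x": ["g1"]})
        mb = self._markers({"z": []})
        out = sm.per_cell_marker_jsi(ca, cb, ma, mb)
        assert out["c1"] == 0.0

    def test_single_mislabelled_cell(self):
        ca = pd.Series(["x"] * 3 + ["y"] * 3, index=[f"c{i}" for i in range(6)])
        cb = ca.copy()
        cb["c0"] = "y"  # one cell moves to the other cluster
        mk = self._markers({"x": ["g1", "g2"], "y": ["g3", "g4"]})
        out = sm.per_cell_marker_jsi(ca, cb, mk, mk.copy())
        assert out["c0"] == 0.0
        assert (out.drop("c0") == 1.0).all()


class TestComembership:
    def test_identical_clusterings(self):
        ca = pd.Series(["a", "a", "b", "b"], index=list("wxyz"))
        sim = sm.per_cell_comembership_similarity(ca, ca.copy())
        assert (sim == 1.0).all()

    def test_singletons_against_one_cluster(self):
        n = 8
        ca = pd.Series(["all"] * n, index=[f"c{i}" for i in range(n)])
        cb = pd.Series([f"s{i}" for i in range(n)], index=ca.index)
        sim = sm.per_cell_comembership_similarity(ca, cb)
        assert np.allclose(sim, 1.0 / n)

    def test_merging_two_equal_clusters(self):
        ca = pd.Series(["a"] * 4 + ["b"] * 4 + ["c"] * 4, index=[f"c{i}" for i in range(12)])
        cb = ca.replace({"b": "a"})
        sim = sm.per_cell_comembership_similarity(ca, cb)
        merged = sim[[f"c{i}" for i in range(8)]]
        untouched = sim[[f"c{i}" for i in range(8, 12)]]
        assert np.allclose(merged, 0.5)
        assert np.allclose(untouched, 1.0)

    def test_symmetric(self, rng):
        cells = [f"c{i}" for i in range(30)]
        ca = pd.Series(rng.choice(["a", "b", "c"], 30), index=cells)
        cb = pd.Series(rng.choice(["p", "q"], 30), index=cells)
        assert sm.per_cell_comembership_similarity(ca, cb).equals(
            sm.per_cell_comembership_similarity(cb, ca)
        )

    def test_disjoint_universes_rejected(self):
        ca = pd.Series(["a"], index=["c1"])
        cb = pd.Series(["a"], index=["c2"])
        with pytest.raises(ValueError):
            sm.per_cell_comembership_similarity(ca, cb)

    def test_summary_fractions(self):
        sim = pd.Series([0.9, 0.8, 0.1, 0.4])
        s = sm.comembership_summary(sim)
        assert s["fraction_high"] == 0.5
        assert s["fraction_low"] == 0.25
        assert s["fraction_intermediate"] == 0.25


class TestIslandNnFraction:
    def test_complete_graph_exact_value(self):
        emb = pd.DataFrame(np.eye(6), index=[f"c{i}" for i in range(6)])
        g = sm.knn_graph(emb, k=5)
        island = {"c0", "c1", "c2"}
        fracs, mean = sm.island_nn_fraction(g, island)
        assert np.allclose(fracs, 2 / 5)

    def test_separated_island_all_ones(self):
        rng = np.random.default_rng(3)
        body = rng.normal(0, 1, (40, 2))
        island = rng.normal(100, 1, (8, 2))
        emb = pd.DataFrame(
            np.vstack([body, island]), index=[f"c{i}" for i in range(48)]
        )
        g = sm.knn_graph(emb, k=5)
        fracs, mean = sm.island_nn_fraction(g, {f"c{i}" for i in range(40, 48)})
        assert mean == 1.0

    def test_random_labels_expectation(self):
        n, k, isl = 200, 10, 40
        means = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            emb = pd.DataFrame(rng.normal(size=(n, 3)), index=[f"c{i}" for i in range(n)])
            g = sm.knn_graph(emb, k=k)
            island = set(rng.choice(emb.index, isl, replace=False))
            means.append(sm.island_nn_fraction(g, island)[1])
        expect = (isl - 1) / (n - 1)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - expect) < 3 * se

    def test_rotation_invariance(self):
        rng = np.random.default_rng(9)
        emb = pd.DataFrame(rng.normal(size=(30, 2)), index=[f"c{i}" for i in range(30)])
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        emb_rot = pd.DataFrame(emb.to_numpy() @ rot.T + 5.0, index=emb.index)
        island = {f"c{i}" for i in range(10)}
        f1, _ = sm.island_nn_fraction(sm.knn_graph(emb, k=4), island)
        f2, _ = sm.island_nn_fraction(sm.knn_graph(emb_rot, k=4), island)
        assert f1.equals(f2)

    def test_missing_island_cells_rejected(self):
        emb = pd.DataFrame(np.eye(3), index=list("abc"))
        g = sm.knn_graph(emb, k=1)
        with pytest.raises(ValueError):
            sm.island_nn_fraction(g, {"zzz"})


class TestPcaEmbed:
    def test_planar_data_exact_reconstruction(self, rng):
        basis = rng.normal(size=(2, 8))
        weights = rng.normal(size=(40, 2))
        x = weights @ basis  # cells x genes, rank 2
        cm = pd.DataFrame(x.T, index=[f"G{i}" for i in range(8)], columns=[f"C{i}" for i in range(40)])
        emb = sm.pca_embed(cm - 0, d=2, n_top_genes=8)
        centred = x - x.mean(axis=0)
        recon_var = (emb.to_numpy() ** 2).sum()
        assert recon_var == pytest.approx((centred**2).sum(), rel=1e-9)

    def test_orthogonal_components(self, rng):
        cm = pd.DataFrame(rng.normal(10, 3, (60, 30)))
        emb = sm.pca_embed(cm, d=5, n_top_genes=60)
        gram = emb.to_numpy().T @ emb.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_separates_two_clusters(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (50, 30))
        b = rng.normal(6, 1, (50, 30))
        cm = pd.DataFrame(np.vstack([a, b]).T)
        emb = sm.pca_embed(cm, d=2, n_top_genes=30)
        labels = [0] * 50 + [1] * 50
        assert silhouette_score(emb.to_numpy()[:, :1], labels) > 0.5

    def test_rank_deficient_warns(self):
        cm = pd.DataFrame(np.ones((10, 4)) * np.arange(4))
        with pytest.warns(UserWarning, match="rank"):
            emb = sm.pca_embed(cm, d=4, n_top_genes=10)
        assert emb.shape[1] < 4


class TestPipelineOnTruth:
    def test_clean_two_cluster_recovery(self):
        from lanesplit.synthdata import gen_sc_dataset

        truth = gen_sc_dataset(
            n_cells=120, n_genes=300, cluster_weights=(0.5, 0.5),
            markers_per_cluster=10, island_size=0, nb_dispersion=0.0,
            seed=5, marker_fold_range=(20.0, 20.0),
        )
        emb = sm.pca_embed(sm.normalize_counts(truth.counts), d=10)
        labels = sm.kmeans_clusters(emb, 2, seed=0)
        sim = sm.per_cell_comembership_similarity(truth.labels, labels)
        assert (sim == 1.0).all()

    def test_island_collapses_without_driver(self, sc_truth):
        norm = sm.normalize_counts(sc_truth.counts)
        emb_full = sm.pca_embed(norm, d=30)
        _, frac_full = sm.island_nn_fraction(
            sm.knn_graph(emb_full, k=20), sc_truth.island_cells
        )
        nodriver = sc_truth.counts.drop(index=[sc_truth.island_driver_gene])
        emb_nd = sm.pca_embed(sm.normalize_counts(nodriver), d=30)
        _, frac_nd = sm.island_nn_fraction(
            sm.knn_graph(emb_nd, k=20), sc_truth.island_cells
        )
        assert frac_full > frac_nd

    def test_split_degrades_marker_overlap(self, sc_truth):
        norm = sm.normalize_counts(sc_truth.counts)
        mk_gt = sm.rank_markers(norm, sc_truth.labels)
        spec = SplitSpec.equal(2, seed=13)
        s_counts = split_count_matrix(sc_truth.counts, spec, 0)
        mk_s = sm.rank_markers(sm.normalize_counts(s_counts), sc_truth.labels)
        sets_gt = sm.marker_sets(mk_gt, top=25)
        sets_s = sm.marker_sets(mk_s, top=25)
        jsis = [
            sm.cluster_marker_jsi(sets_gt[cl], sets_s.get(cl, []))
            for cl in sets_gt
        ]
        assert np.mean(jsis) < 1.0
        assert np.mean(jsis) > 0.5  # clusters still recognisable


class TestRankMarkers:
    def test_planted_markers_top_ranked(self, sc_truth):
        norm = sm.normalize_counts(sc_truth.counts)
        mk = sm.rank_markers(norm, sc_truth.labels)
        sets = sm.marker_sets(mk, top=25)
        for cl, planted in sc_truth.planted_markers.items():
            if cl == "island":
                continue
            # strongest planted markers (largest folds) must rank in the top 25
            strong = planted[:5]
            assert len(set(strong) & set(sets[cl])) >= 4

    def test_ordering_by_effect(self, sc_truth):
        norm = sm.normalize_counts(sc_truth.counts)
        mk = sm.rank_markers(norm, sc_truth.labels)
        for _, sub in mk.groupby("cluster"):
            eff = sub["effect_size"].to_numpy()
            assert (np.diff(eff) <= 1e-12).all()
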