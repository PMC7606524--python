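"""Normalization, PCA, SNN graph clustering and partition comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import ncembryo as nc

from conftest import make_matrix


class TestLogNormalize:
    def test_forced_arithmetic(self):
        # cell total 10000, count 1 -> ln(1 + 10000*1/10000) = ln 2
        vals = np.zeros((2, 1))
        vals[0, 0] = 1
        vals[1, 0] = 9999
        m = make_matrix(vals, ["g1", "g2"], ["c1"])
        norm = nc.log_normalize(m)
        assert norm.values[0, 0] == pytest.approx(np.log(2.0))

    def test_zero_count_maps_to_zero(self):
        m = make_matrix([[0], [5]], ["g1", "g2"], ["c1"])
        assert nc.log_normalize(m).values[0, 0] == 0.0

    def test_depth_invariance(self):
        base = np.array([[3.0, 6.0], [7.0, 14.0], [1.0, 2.0]])
        m = make_matrix(base, ["g1", "g2", "g3"], ["c1", "c2"])
        norm = nc.log_normalize(m)
        assert np.allclose(norm.values[:, 0], norm.values[:, 1])

    def test_zero_total_cell_lists_ids(self):
        m = make_matrix([[1, 0], [2, 0]], ["g1", "g2"], ["c1", "dead"])
        with pytest.raises(ValueError, match="dead"):
            nc.log_normalize(m)

    @given(st.floats(1.1, 10.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_depth_invariance_any_factor(self, factor):
        base = np.array([[3.0], [7.0], [1.0]])
        m = make_matrix(np.hstack([base, base * factor]),
                        ["g1", "g2", "g3"], ["c1", "c2"])
        norm = nc.log_normalize(m)
        assert np.allclose(norm.values[:, 0], norm.values[:, 1])


class TestPCAEmbed:
    def test_matches_bruteforce_eigendecomposition(self):
        rng = np.random.default_rng(2)
        X = rng.random((10, 20)) * 5
        norm = nc.ExpressionMatrix(X, [f"g{i}" for i in range(10)],
                                   [f"c{j}" for j in range(20)], "lognorm")
        cfg = nc.ClusteringConfig(n_pcs=3, knn_k=5)
        coords = nc.pca_embed(norm, cfg)
        # oracle: explicit eigendecomposition of the standardized covariance
        Z = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        Z = np.clip(Z, -cfg.clip_value, cfg.clip_value)
        M = Z.T
        w, V = np.linalg.eigh(M.T @ M / (M.shape[0] - 1))
        V = V[:, np.argsort(w)[::-1][:3]]
        for k in range(3):
            j = int(np.argmax(np.abs(V[:, k])))
            if V[j, k] < 0:
                V[:, k] *= -1
        assert np.abs(coords - M @ V).max() < 1e-8

    def test_rank_one_structure_concentrates_on_pc1(self):
        rng = np.random.default_rng(4)
        signal = rng.normal(size=30)
        X = np.tile(signal, (10, 1)) * rng.uniform(0.5, 2.0, size=(10, 1))
        norm = nc.ExpressionMatrix(X, [f"g{i}" for i in range(10)],
                                   [f"c{j}" for j in range(30)], "lognorm",
                                   _validate=False)
        coords = nc.pca_embed(norm, nc.ClusteringConfig(n_pcs=2, knn_k=5))
        var = coords.var(axis=0)
        assert var[0] / var.sum() > 0.99

    def test_duplicated_cells_give_duplicated_rows(self):
        rng = np.random.default_rng(5)
        X = rng.random((8, 12))
        X = np.hstack([X, X[:, :1]])  # cell 12 duplicates cell 0
        norm = nc.ExpressionMatrix(X, [f"g{i}" for i in range(8)],
                                   [f"c{j}" for j in range(13)], "lognorm")
        coords = nc.pca_embed(norm, nc.ClusteringConfig(n_pcs=2, knn_k=5))
        assert np.allclose(coords[0], coords[12])

    def test_too_few_nonconstant_genes_rejected(self):
        X = np.ones((5, 30))
        X[0] = np.arange(30)
        norm = nc.ExpressionMatrix(X, [f"g{i}" for i in range(5)],
                                   [f"c{j}" for j in range(30)], "lognorm")
        with pytest.raises(ValueError, match="non-constant"):
            nc.pca_embed(norm, nc.ClusteringConfig(n_pcs=4, knn_k=5))


class TestClusterCells:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(3)
        emb = np.vstack([rng.normal(0, 1, (100, 5)), rng.normal(20, 1, (100, 5))])
        labels = nc.cluster_cells(emb, nc.ClusteringConfig(seed=3))
        truth = np.array([0] * 100 + [1] * 100)
        assert len(np.unique(labels)) == 2
        assert adjusted_rand_score(labels, truth) == 1.0

    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(3)
        emb = rng.normal(size=(120, 6))
        a = nc.cluster_cells(emb, nc.ClusteringConfig(seed=9))
        b = nc.cluster_cells(emb, nc.ClusteringConfig(seed=9))
        assert (a == b).all()

    def test_identical_embedding_is_one_cluster(self):
        labels = nc.cluster_cells(np.zeros((50, 3)),
                                  nc.ClusteringConfig(seed=0, knn_k=10))
        assert len(np.unique(labels)) == 1

    def test_cell_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        emb = np.vstack([rng.normal(0, 1, (100, 5)), rng.normal(20, 1, (100, 5))])
        truth = np.array([0] * 100 + [1] * 100)
        perm = rng.permutation(200)
        labels = nc.cluster_cells(emb[perm], nc.ClusteringConfig(seed=3))
        assert adjusted_rand_score(labels, truth[perm]) == 1.0

    def test_fewer_cells_than_k_rejected(self):
        with pytest.raises(ValueError, match="knn_k"):
            nc.cluster_cells(np.zeros((5, 2)), nc.ClusteringConfig(knn_k=20))


class TestEmbed2D:
    def test_shape_determinism_finiteness(self):
        rng = np.random.default_rng(6)
        emb = rng.normal(size=(40, 8))
        a = nc.embed_2d(emb, seed=1)
        b = nc.embed_2d(emb, seed=1)
        assert a.shape == (40, 2)
        assert np.isfinite(a).all()
        assert np.allclose(a, b)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            nc.embed_2d(np.zeros((5, 3)), seed=0)


class TestComparePartitions:
    def test_identical_labelings(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        comp = nc.compare_partitions(labels, labels)
        assert comp.adjusted_rand_index == 1.0
        assert all(v == 1 for v in comp.dispersion.values())

    def test_within_cluster_permutation_keeps_contingency(self):
        rng = np.random.default_rng(0)
        a = np.repeat([0, 1, 2], 20)
        b = rng.integers(0, 4, size=60)
        base = nc.compare_partitions(a, b).contingency
        # permuting cells within one cluster of `a` cannot change the table
        idx = np.arange(60)
        block = idx[a == 1]
        idx[a == 1] = rng.permutation(block)
        permuted = nc.compare_partitions(a[idx], b[idx]).contingency
        assert base.equals(permuted)

    def test_even_split_gives_dispersion_five(self):
        a = np.zeros(50, dtype=int)
        b = np.repeat(np.arange(5), 10)
        comp = nc.compare_partitions(a, b)
        assert comp.dispersion[0] == 5

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            nc.compare_partitions([0, 1], [0, 1, 2])


class TestFeatureSetClustering:
    def test_ncrna_on_coding_only_annotation_rejected(self):
        genes = [nc.GeneRecord(f"g{i}", "coding", 100) for i in range(5)]
        counts = make_matrix(np.ones((5, 30)), [g.gene_id for g in genes],
                             [f"c{j}" for j in range(30)])
        with pytest.raises(ValueError, match="no genes"):
            nc.run_feature_set_clustering(counts, genes, "ncrna")

    def test_planted_ncrna_type_recovered_only_by_ncrna_features(self):
        """The ncRNA-defined cell type forms a pure ncRNA-only cluster but
        scatters across >= 2 coding-only clusters."""
        cfg = nc.SimulationConfig(n_cells=400, seed=5)
        counts, _, genes, _, truth = nc.simulate(cfg)
        ccfg = nc.ClusteringConfig(seed=5)
        lab_nc = nc.run_feature_set_clustering(counts, genes, "ncrna", ccfg)
        lab_cod = nc.run_feature_set_clustering(counts, genes, "coding", ccfg)
        muscle = np.array([t == "muscle" for t in truth.cell_types])
        best = max(np.unique(lab_nc), key=lambda k: muscle[lab_nc == k].sum())
        assert muscle[lab_nc == best].mean() >= 0.9  # cluster purity
        assert (lab_nc[muscle] == best).mean() >= 0.9  # capture
        assert len(np.unique(lab_cod[muscle])) >= 2  # dispersed on coding

    def test_combined_close_to_coding_without_informative_ncrnas(self):
        cfg = nc.SimulationConfig(n_cells=400, seed=8, ncrna_only_type=None)
        counts, _, genes, _, _ = nc.simulate(cfg)
        ccfg = nc.ClusteringConfig(seed=8)
        lab_comb = nc.run_feature_set_clustering(counts, genes, "combined", ccfg)
        lab_cod = nc.run_feature_set_clustering(counts, genes, "coding", ccfg)
        assert adjusted_rand_score(lab_comb, lab_cod) >= 0.9
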