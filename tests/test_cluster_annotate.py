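"""Normalisation, PCA, SNN-Louvain clustering, DE markers and
signature-based annotation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from enskit.cluster_annotate import (
    GraphClusterConfig,
    NormalizeConfig,
    annotate_classes,
    cluster_counts,
    de_markers,
    normalize_hvg,
    pca_embed,
    snn_louvain,
)
from enskit.containers import NormalizedMatrix
from enskit.synthetic_data import SimCountsConfig, gen_counts

from conftest import toy_counts


class TestNormalizeHvg:
    def test_log_cpm_closed_form(self):
        # one cell with library size 1e4: count 1 -> log1p(1)
        X = np.zeros((3, 1), dtype=int)
        X[0, 0] = 1
        X[1, 0] = 9999
        nm, _ = normalize_hvg(toy_counts(X), NormalizeConfig(method="log_cpm", n_hvg=3))
        assert nm.values[0, 0] == pytest.approx(np.log1p(1.0), abs=1e-12)

    def test_excluded_gene_absent_but_hvg_count_kept(self, clean_sim):
        _, counts, truth = clean_sim
        top_marker = truth.marker_genes["class1"][0]
        cfg = NormalizeConfig(n_hvg=50, exclude_genes=[top_marker])
        _, hvgs = normalize_hvg(counts, cfg)
        assert top_marker not in hvgs
        assert len(hvgs) == 50

    def test_constant_gene_never_hvg(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(5, size=(20, 30))
        X[0, :] = 3  # constant gene
        nm, hvgs = normalize_hvg(
            toy_counts(X), NormalizeConfig(method="pearson_residual", n_hvg=10)
        )
        assert "g0" not in hvgs
        assert nm.values[0, :].var() < nm.values[1:, :].var(axis=1).max()

    def test_zero_libsize_cell_rejected(self):
        X = np.zeros((5, 2), dtype=int)
        X[:, 0] = 1
        with pytest.raises(ValueError):
            normalize_hvg(toy_counts(X))

    def test_pearson_residuals_clipped(self, clean_sim):
        _, counts, _ = clean_sim
        nm, _ = normalize_hvg(counts, NormalizeConfig(method="pearson_residual"))
        clip = np.sqrt(counts.n_cells)
        assert np.abs(nm.values).max() <= clip + 1e-9


class TestPcaEmbed:
    def test_orthonormal_loadings_and_variance_order(self, clean_sim):
        _, counts, _ = clean_sim
        nm, _ = normalize_hvg(counts, NormalizeConfig(n_hvg=100))
        emb = pca_embed(nm, n_pcs=10)
        np.testing.assert_allclose(
            emb.loadings @ emb.loadings.T, np.eye(10), atol=1e-8
        )
        assert (np.diff(emb.explained_variance) <= 1e-9).all()

    def test_matches_direct_eigendecomposition(self):
        """PCA coordinates agree with an eigendecomposition oracle."""
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(10, 20))  # 10 genes x 20 cells
        nm = NormalizedMatrix(vals, [f"g{i}" for i in range(10)],
                              [f"c{i}" for i in range(20)])
        emb = pca_embed(nm, n_pcs=5)
        M = vals.T - vals.T.mean(axis=0)
        w, V = np.linalg.eigh(M.T @ M)
        order = np.argsort(w)[::-1][:5]
        oracle = M @ V[:, order]
        for j in range(5):  # sign-invariant comparison
            assert (
                np.allclose(emb.coords[:, j], oracle[:, j], atol=1e-8)
                or np.allclose(emb.coords[:, j], -oracle[:, j], atol=1e-8)
            )


class TestSnnLouvain:
    @staticmethod
    def _blob_embedding(seed=0):
        from enskit.cluster_annotate import Embedding

        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(200, 5))
        b = rng.normal(10, 1, size=(200, 5))
        coords = np.vstack([a, b])
        cells = pd.Index([f"c{i}" for i in range(400)])
        return Embedding(coords, cells, np.eye(5), np.ones(5), pd.Index(list("abcde"))), (
            np.repeat([0, 1], 200)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_two_separated_blobs_fully_recovered(self, seed):
        emb, truth = self._blob_embedding(seed)
        cl = snn_louvain(emb, GraphClusterConfig(n_pcs=5, k_neighbors=15,
                                                 resolution=0.2, seed=seed))
        assert cl.n_clusters == 2
        assert adjusted_rand_score(truth, cl.labels) == 1.0

    def test_tiny_resolution_gives_single_community(self):
        # a single connected point cloud collapses as resolution -> 0+
        from enskit.cluster_annotate import Embedding

        rng = np.random.default_rng(1)
        coords = rng.normal(0, 1, size=(300, 5))
        cells = pd.Index([f"c{i}" for i in range(300)])
        emb = Embedding(coords, cells, np.eye(5), np.ones(5), pd.Index(list("abcde")))
        cl = snn_louvain(emb, GraphClusterConfig(n_pcs=5, k_neighbors=30,
                                                 resolution=1e-4, seed=0))
        assert cl.n_clusters == 1

    def test_recovers_planted_classes(self, clean_sim):
        _, counts, truth = clean_sim
        cl = cluster_counts(counts, resolution=0.1, n_pcs=20, seed=0)
        assert cl.n_clusters == 3
        assert adjusted_rand_score(truth.class_of_cell, cl.labels) >= 0.9

    def test_invariant_to_cell_order(self, clean_sim):
        _, counts, truth = clean_sim
        perm = np.random.default_rng(5).permutation(counts.n_cells)
        shuffled = counts.subset_cells(perm)
        a = cluster_counts(counts, resolution=0.1, n_pcs=20, seed=0)
        b = cluster_counts(shuffled, resolution=0.1, n_pcs=20, seed=0)
        joined = pd.concat([a.labels.rename("a"), b.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_weak_resolution_monotonicity(self, clean_sim):
        _, counts, _ = clean_sim
        lo = cluster_counts(counts, resolution=0.04, n_pcs=20, seed=0)
        hi = cluster_counts(counts, resolution=0.4, n_pcs=20, seed=0)
        assert lo.n_clusters <= hi.n_clusters

    def test_k_at_least_n_cells_rejected(self):
        emb, _ = self._blob_embedding(0)
        with pytest.raises(ValueError):
            snn_louvain(emb, GraphClusterConfig(k_neighbors=400, seed=0))


class TestDeMarkers:
    def test_planted_marker_ranks_first(self, clean_sim):
        cfg, counts, truth = clean_sim
        cl = cluster_counts(counts, resolution=0.1, n_pcs=20, seed=0)
        nm, _ = normalize_hvg(counts)
        table = de_markers(nm, cl)
        marker_sets = [set(v) for v in truth.marker_genes.values()]
        for clu in range(cl.n_clusters):
            top = table[(table.cluster == clu) & (table["rank"] == 1)].gene.iloc[0]
            assert any(top in s for s in marker_sets)

    def test_rank_sum_statistic_matches_pair_counting_oracle(self):
        """Wilcoxon U equals brute-force pair counting on groups <= 30."""
        from scipy import stats

        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.4, 1, 30)
        u, _ = stats.mannwhitneyu(x, y, alternative="two-sided")
        oracle = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
        assert u == pytest.approx(oracle)

    def test_p_value_matches_enumeration_oracle_on_tiny_groups(self):
        """Exact two-sided p equals full enumeration over group assignments."""
        from scipy import stats

        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 6)
        y = rng.normal(0, 1, 6)
        u, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        pool = np.concatenate([x, y])
        mu = len(x) * len(y) / 2
        vals = []
        for comb in itertools.combinations(range(12), 6):
            a = pool[list(comb)]
            b = np.delete(pool, list(comb))
            vals.append(sum((ai > bi) + 0.5 * (ai == bi) for ai in a for bi in b))
        p_oracle = np.mean(np.abs(np.asarray(vals) - mu) >= abs(u - mu))
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_null_gene_type_one_error_controlled(self):
        """BH at 0.05 keeps false-positive marker rate near nominal."""
        from enskit.cluster_annotate import ClusterAssignment

        rng = np.random.default_rng(9)
        n_genes, n_cells = 400, 120
        vals = rng.normal(size=(n_genes, n_cells))
        nm = NormalizedMatrix(vals, [f"g{i}" for i in range(n_genes)],
                              [f"c{i}" for i in range(n_cells)], method="raw")
        labels = pd.Series(rng.integers(0, 2, n_cells),
                           index=nm.cells, name="cluster")
        table = de_markers(nm, ClusterAssignment(labels, resolution=1.0))
        fp_rate = (table.p_adj < 0.05).mean()
        assert fp_rate <= 0.06

    def test_singleton_cluster_skipped_with_warning(self):
        from enskit.cluster_annotate import ClusterAssignment

        rng = np.random.default_rng(1)
        vals = rng.normal(size=(10, 5))
        nm = NormalizedMatrix(vals, [f"g{i}" for i in range(10)],
                              [f"c{i}" for i in range(5)], method="raw")
        labels = pd.Series([0, 0, 0, 0, 1], index=nm.cells)
        with pytest.warns(UserWarning, match="cluster 1"):
            table = de_markers(nm, ClusterAssignment(labels, resolution=1.0))
        assert set(table.cluster.unique()) == {0}


class TestAnnotateClasses:
    def test_recovers_named_classes(self):
        cfg = SimCountsConfig(
            n_cells=600, n_genes=800, doublet_fraction=0.0, contaminant_fraction=0.0,
            class_names=("smENC1", "smENC2", "smENC3"),
            marker_names={0: ["Nmu", "Adgrg6"], 1: ["Sst"], 2: ["Vip", "Npy"]},
            seed=13,
        )
        counts, truth = gen_counts(cfg)
        cl = cluster_counts(counts, resolution=0.1, n_pcs=20, seed=0)
        nm, _ = normalize_hvg(counts)
        ann = annotate_classes(nm, cl).set_index("cluster")["class"]
        # each cluster's annotation matches its dominant truth class
        for clu in range(cl.n_clusters):
            cells = cl.cells_in(clu)
            dominant = truth.class_of_cell[cells].mode()[0]
            assert ann[clu] == dominant

    def test_no_signature_overlap_gives_unassigned(self):
        rng = np.random.default_rng(2)
        counts = toy_counts(rng.poisson(5, size=(20, 40)))
        cl = cluster_counts(counts, resolution=1.0, n_pcs=5, k_neighbors=5, seed=0)
        nm, _ = normalize_hvg(counts)
        with pytest.warns(UserWarning, match="no signature gene"):
            ann = annotate_classes(nm, cl, {"foo": ("NotAGene",)})
        assert (ann["class"] == "unassigned").all()

    def test_tie_within_margin_is_unassigned(self):
        from enskit.cluster_annotate import ClusterAssignment

        rng = np.random.default_rng(3)
        vals = rng.normal(size=(4, 40))
        vals[0, :20] += 5.0  # geneA high in cluster 0
        vals[1, :20] += 5.0  # geneB identically high -> tie
        nm = NormalizedMatrix(vals, ["geneA", "geneB", "geneC", "geneD"],
                              [f"c{i}" for i in range(40)], method="raw")
        labels = pd.Series(np.repeat([0, 1], 20), index=nm.cells)
        ann = annotate_classes(
            nm, ClusterAssignment(labels, 1.0),
            {"sigA": ("geneA",), "sigB": ("geneB",)}, margin=10.0,
        )
        assert (ann["class"] == "unassigned").all()
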