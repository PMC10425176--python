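"""QC filtering rules, PC selection, clustering, confounder handling."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from npbfates.containers import CountMatrix, ExpressionMatrix, normalize_counts
from npbfates.qc import (
    classify_sex,
    cluster_cells,
    filter_cells,
    filter_genes,
    flag_contaminant_clusters,
    flag_poor_clusters,
    regress_covariates,
    select_pcs,
)


def _cm_from_dense(X, gene_ids=None, barcodes=None):
    X = np.asarray(X)
    genes = gene_ids or [f"G{i}" for i in range(X.shape[0])]
    cells = barcodes or [f"C{j}" for j in range(X.shape[1])]
    return CountMatrix(counts=sp.csr_matrix(X), gene_ids=genes, cell_barcodes=cells)


class TestFilterGenes:
    def test_detection_boundary_at_five_cells(self):
        # detected in {2, 5, 100 (i.e. all), 4, 0} cells -> keep exactly 2 genes
        n = 100
        X = np.zeros((5, n), int)
        X[0, :2] = 1
        X[1, :5] = 3
        X[2, :] = 1
        X[3, :4] = 2
        keep = filter_genes(_cm_from_dense(X))
        assert list(keep.gene_ids) == ["G1", "G2"]

    def test_all_genes_removed_is_an_error(self):
        with pytest.raises(ValueError, match="5"):
            filter_genes(_cm_from_dense(np.zeros((3, 10), int)))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(0.5, size=(50, 30))
        once = filter_genes(_cm_from_dense(X))
        twice = filter_genes(once)
        assert list(once.gene_ids) == list(twice.gene_ids)


class TestFilterCells:
    def _fixture(self):
        # 7000 genes so the 6500 upper bound is reachable; detected-gene
        # counts per cell: 999, 1000, 6500, 6501, and two mito cases
        n_genes, detected = 7000, [999, 1000, 6500, 6501, 1500, 1500]
        X = np.zeros((n_genes + 1, 6), dtype=int)
        for j, d in enumerate(detected):
            X[:d, j] = 1
        # last row is the mito gene: 15.0% for cell 4, just above for cell 5
        genes = [f"G{i}" for i in range(n_genes)] + ["MT-1"]
        X[-1, 4] = 1500 * 15 // 85  # 264 -> 264/1764 = 14.97 %
        X[-1, 5] = 300              # 300/1800 = 16.7 %
        table = pd.DataFrame({"stage": ["HH4"] * 6}, index=[f"C{j}" for j in range(6)])
        return _cm_from_dense(X, gene_ids=genes), table

    def test_gene_count_and_mito_boundaries(self):
        cm, table = self._fixture()
        kept, out = filter_cells(cm, table)
        # 999 removed, 1000 kept, 6500 kept (the mito gene adds one detected
        # gene to cells 4/5), 6501 removed, 15.0% kept-ish, >15% removed
        assert list(kept.cell_barcodes) == ["C1", "C2", "C4"]
        assert (out["pct_mito"] <= 15).all()

    def test_exact_mito_boundary_kept(self):
        X = np.zeros((1100, 2), int)
        X[:1000, :] = 1
        genes = [f"G{i}" for i in range(1099)] + ["MT-1"]
        X[-1, 0] = 176  # (176)/(999+176) ... compute below
        X[-1, 1] = 177
        cm = _cm_from_dense(X, gene_ids=genes)
        t = pd.DataFrame({"stage": ["HH4", "HH4"]}, index=["C0", "C1"])
        from npbfates.containers import cell_metrics
        pct = cell_metrics(cm)["pct_mito"]
        kept, _ = filter_cells(cm, t, max_mito=float(pct.iloc[0]))
        assert list(kept.cell_barcodes) == ["C0"]

    def test_empty_result_is_error(self):
        X = np.ones((10, 3), int)
        cm = _cm_from_dense(X)
        t = pd.DataFrame({"stage": ["HH4"] * 3}, index=cm.cell_barcodes)
        with pytest.raises(ValueError, match="all cells"):
            filter_cells(cm, t, min_genes=100)


class TestSelectPcs:
    def test_worked_example(self):
        # percent-of-total vector; the three criteria combine to 4
        pct = np.array([50, 30, 10, 4, 3, 2, 0.5, 0.3, 0.15, 0.05])
        assert select_pcs(pct) == 4

    def test_single_dominant_component(self):
        assert select_pcs([95, 2, 1, 0.5, 0.25]) == 1

    def test_result_in_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sd = np.sort(rng.uniform(0.01, 5, size=rng.integers(2, 30)))[::-1]
            k = select_pcs(sd)
            assert 1 <= k <= len(sd)

    @given(st.floats(min_value=0.1, max_value=100))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariant(self, c):
        sd = np.array([5.0, 3.0, 1.0, 0.4, 0.3, 0.2, 0.05])
        assert select_pcs(sd) == select_pcs(sd * c)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            select_pcs([3.0, 0.0, 1.0])


class TestClusterCells:
    def _blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(100, 30))
        b = rng.normal(10, 1, size=(100, 30))
        X = np.vstack([a, b]).T  # genes x cells layout
        expr = ExpressionMatrix(normalized=X, gene_ids=[f"G{i}" for i in range(30)],
                                cell_barcodes=[f"C{j}" for j in range(200)],
                                scaled=X - X.mean(axis=1, keepdims=True))
        return expr

    def test_two_separated_blobs_recovered(self):
        expr = self._blobs()
        labels = cluster_cells(expr, n_pcs=5, resolution=0.5)
        truth = np.repeat([0, 1], 100)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_deterministic_given_seed(self):
        expr = self._blobs()
        a = cluster_cells(expr, n_pcs=5, resolution=0.5, seed=42)
        b = cluster_cells(expr, n_pcs=5, resolution=0.5, seed=42)
        assert np.array_equal(a, b)

    def test_duplicate_cells_share_cluster(self):
        expr = self._blobs()
        labels = cluster_cells(expr, n_pcs=5, resolution=0.5)
        # first 100 cells are one blob; any two cells of the blob agree
        assert len(set(labels[:100])) == 1

    def test_too_few_cells_rejected(self):
        expr = self._blobs()
        with pytest.raises(ValueError, match="fewer cells"):
            cluster_cells(
                ExpressionMatrix(normalized=expr.normalized[:, :3],
                                 gene_ids=expr.gene_ids,
                                 cell_barcodes=expr.cell_barcodes[:3],
                                 scaled=expr.scaled[:, :3]),
                n_pcs=10, resolution=0.5)


class TestFlagPoorClusters:
    def _table(self, genes, umis, clusters):
        return pd.DataFrame({"n_genes_detected": genes, "n_umi": umis,
                             "cluster": clusters})

    def test_low_on_both_metrics_flagged(self):
        t = self._table([100] * 10 + [2000] * 30, [200] * 10 + [9000] * 30,
                        [0] * 10 + [1] * 30)
        assert flag_poor_clusters(t) == {0}

    def test_low_on_genes_only_not_flagged(self):
        t = self._table([100] * 10 + [2000] * 30, [9000] * 40,
                        [0] * 10 + [1] * 30)
        assert flag_poor_clusters(t) == set()

    def test_equal_quality_clusters_unflagged(self):
        t = self._table([1000] * 40, [4000] * 40, [0, 1, 2, 3] * 10)
        assert flag_poor_clusters(t) == set()

    def test_single_cluster_warns_and_returns_empty(self):
        t = self._table([10, 20], [30, 40], [0, 0])
        with pytest.warns(UserWarning, match="single cluster"):
            assert flag_poor_clusters(t) == set()


class TestFlagContaminantClusters:
    def _expr(self, X):
        X = np.asarray(X, float)
        return ExpressionMatrix(normalized=X,
                                gene_ids=[f"G{i}" for i in range(X.shape[0])],
                                cell_barcodes=[f"C{j}" for j in range(X.shape[1])])

    def test_exclusive_marker_cluster_flagged(self):
        X = np.zeros((2, 60))
        X[0, :4] = 5.0  # marker gene high in a small cluster only
        clusters = [0] * 4 + [1] * 56
        flagged = flag_contaminant_clusters(self._expr(X), clusters, {"meso": ["G0"]})
        assert flagged == {0}

    def test_identical_cells_nothing_flagged(self):
        X = np.ones((3, 30))
        flagged = flag_contaminant_clusters(self._expr(X), [0] * 10 + [1] * 20,
                                            {"meso": ["G0", "G1"]})
        assert flagged == set()

    def test_two_high_clusters_both_flagged(self):
        X = np.zeros((1, 100))
        X[0, :4] = 4.0
        X[0, 4:8] = 5.0
        clusters = [0] * 4 + [1] * 4 + [2] * 92
        flagged = flag_contaminant_clusters(self._expr(X), clusters, {"m": ["G0"]})
        assert flagged == {0, 1}

    def test_absent_set_is_error(self):
        with pytest.raises(ValueError):
            flag_contaminant_clusters(self._expr(np.ones((2, 10))), [0] * 10,
                                      {"m": []})


class TestClassifySex:
    def _expr(self, w_values):
        X = np.asarray([w_values], float)
        return ExpressionMatrix(normalized=X, gene_ids=["W-1"],
                                cell_barcodes=[f"C{j}" for j in range(X.shape[1])])

    def test_bimodal_split_high_is_female(self):
        sex = classify_sex(self._expr([0, 0, 0, 5, 5, 5]), ["W-1"])
        assert list(sex) == ["male"] * 3 + ["female"] * 3

    def test_constant_expression_single_label_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            sex = classify_sex(self._expr([2.0] * 5), ["W-1"])
        assert sex.nunique() == 1

    def test_simulated_sex_recovered(self, default_dataset):
        _, counts, table, truth = default_dataset
        expr = normalize_counts(counts)
        w = [g for g in counts.gene_ids if g.startswith("W-")]
        sex = classify_sex(expr, w)
        assert (sex == truth.cells["sex"]).mean() >= 0.99


class TestRegressCovariates:
    def _expr(self, X):
        X = np.asarray(X, float)
        return ExpressionMatrix(normalized=X,
                                gene_ids=[f"G{i}" for i in range(X.shape[0])],
                                cell_barcodes=[f"C{j}" for j in range(X.shape[1])])

    def test_orthogonal_covariate_leaves_centred_expression(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=24)
        cov = np.tile([1.0, -1.0], 12)  # orthogonal to y by construction
        y = y - (y @ cov) / (cov @ cov) * cov
        expr = self._expr([y])
        covs = pd.DataFrame({"c": cov}, index=expr.cell_barcodes)
        out = regress_covariates(expr, covs)
        expected = (y - y.mean()) / y.std()
        np.testing.assert_allclose(out.scaled[0], expected, atol=1e-10)

    def test_expression_equal_to_covariate_gives_zero_residuals(self):
        cov = np.arange(10.0)
        expr = self._expr([cov])
        out = regress_covariates(expr, pd.DataFrame({"c": cov}, index=expr.cell_barcodes))
        np.testing.assert_allclose(out.scaled[0], 0.0, atol=1e-10)

    def test_collinear_covariates_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        expr = self._expr(rng.normal(size=(3, 20)))
        c = rng.normal(size=20)
        covs = pd.DataFrame({"a": c, "b": 2 * c}, index=expr.cell_barcodes)
        with pytest.warns(UserWarning, match="collinear"):
            out = regress_covariates(expr, covs)
        assert np.isfinite(out.scaled).all()

    def test_scaled_rows_have_zero_mean(self):
        rng = np.random.default_rng(2)
        expr = self._expr(rng.normal(size=(5, 30)))
        covs = pd.DataFrame({"c": rng.normal(size=30)}, index=expr.cell_barcodes)
        out = regress_covariates(expr, covs)
        np.testing.assert_allclose(out.scaled.mean(axis=1), 0.0, atol=1e-8)

    def test_planted_mito_effect_removed(self, default_dataset):
        _, counts, table, truth = default_dataset
        from npbfates.containers import cell_metrics
        met = cell_metrics(counts)
        expr = normalize_counts(counts)
        out = regress_covariates(expr, pd.DataFrame({"pct_mito": met["pct_mito"]}))
        stress = [i for i, g in enumerate(counts.gene_ids) if g.startswith("STRESS-")]
        for gi in stress[:3]:
            r = np.corrcoef(out.scaled[gi], met["pct_mito"])[0, 1]
            assert abs(r) < 0.05


class TestPlantedQcRecovery:
    def test_poor_and_contaminant_clusters_recovered(self, default_dataset):
        _, counts, table, truth = default_dataset
        cm = filter_genes(counts)
        cm, tab = filter_cells(cm, table)
        tr = truth.cells.loc[tab.index]
        expr = normalize_counts(cm)
        expr = regress_covariates(expr, pd.DataFrame(index=tab.index))
        from npbfates.qc import highly_variable_genes
        hvg = highly_variable_genes(cm)
        clusters = cluster_cells(expr, n_pcs=20, resolution=2.0, gene_idx=hvg)
        tab = tab.assign(cluster=clusters)
        poor = flag_poor_clusters(tab)
        cont = flag_contaminant_clusters(
            expr, clusters, {"mesoderm": [f"MESO-{j:02d}" for j in range(1, 13)]})
        in_poor = np.isin(clusters, sorted(poor))
        in_cont = np.isin(clusters, sorted(cont))
        # the planted poor and contaminant clusters are recovered (individual
        # stray cells may land in a normal cluster), and no normal cluster is
        # sacrificed
        assert poor and cont
        assert (tr["is_poor"] & in_poor).sum() / tr["is_poor"].sum() >= 0.95
        assert (tr["is_contaminant"] & in_cont).sum() / tr["is_contaminant"].sum() > 0.9
        normal = ~tr["is_poor"] & ~tr["is_contaminant"]
        assert (normal & (in_poor | in_cont)).mean() < 0.02
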