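"""Quality-control filtering, dimensionality selection, covariate regression
and cluster-level cleanup.

The numeric rules mirror the study's stated thresholds: genes in fewer than 5
cells removed; cells outside 1000-6500 detected genes or above 15%
mitochondrial content removed; a PC-count heuristic combining a 5%
per-component and a 90% cumulative criterion with a 0.1-point consecutive-drop
criterion; Louvain clustering on an SNN graph (resolution 2.0 for QC passes,
0.5 for analysis); poor clusters = both median genes and median UMI below the
dataset's 25th percentiles; contaminating clusters = median marker-set score
above the dataset's 90th percentile for any set.
"""

from __future__ import annotations

import random
import warnings

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import qr
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import CountMatrix, ExpressionMatrix, cell_metrics


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_genes(m: CountMatrix, min_cells: int = 5) -> CountMatrix:
    """Retain genes detected (count > 0) in at least ``min_cells`` cells."""
    detected = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    keep = detected >= min_cells
    if not keep.any():
        raise ValueError(f"no gene is detected in >= {min_cells} cells")
    return m.subset_genes(keep)


def filter_cells(m: CountMatrix, table: pd.DataFrame, min_genes: int = 1000,
                 max_genes: int = 6500, max_mito: float = 15.0):
    """Medium filtering threshold: drop cells with fewer than ``min_genes`` or
    more than ``max_genes`` detected genes, or more than ``max_mito`` percent
    mitochondrial content.  All bounds keep cells at exact equality."""
    if not table.index.equals(m.cell_barcodes):
        table = table.loc[m.cell_barcodes]
    metrics = cell_metrics(m)
    keep = (
        (metrics["n_genes_detected"] >= min_genes)
        & (metrics["n_genes_detected"] <= max_genes)
        & (metrics["pct_mito"] <= max_mito)
    ).to_numpy()
    if not keep.any():
        raise ValueError("all cells removed by the medium filtering threshold")
    out_table = pd.concat([table, metrics], axis=1).loc[m.cell_barcodes[keep]]
    return m.subset_cells(keep), out_table


def select_pcs(stdevs) -> int:
    """Number of principal components by the elbow heuristic.

    Step 1: the larger of (first PC i with percent-of-total-stdev of PC i+1
    below 5%) and (first PC at which cumulative percent exceeds 90%).
    Step 2: the first PC whose successor adds less than 0.1 percentage points
    (defaults to step 1 if never triggered).  Returns the smaller of the two.
    """
    stdevs = np.asarray(stdevs, dtype=float)
    if stdevs.size < 2:
        raise ValueError("need at least two components")
    if np.any(stdevs <= 0):
        raise ValueError("standard deviations must be strictly positive")
    pct = 100.0 * stdevs / stdevs.sum()
    n = pct.size
    cum = np.cumsum(pct)
    below5 = np.flatnonzero(pct[1:] < 5.0)
    crit_a = int(below5[0]) + 1 if below5.size else n
    over90 = np.flatnonzero(cum > 90.0)
    crit_b = int(over90[0]) + 1 if over90.size else n
    step1 = max(crit_a, crit_b)
    drops = pct[:-1] - pct[1:]
    small = np.flatnonzero(drops < 0.1)
    step2 = int(small[0]) + 1 if small.size else step1
    return int(np.clip(min(step1, step2), 1, n))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def highly_variable_genes(m: CountMatrix, n_top: int = 300) -> np.ndarray:
    """Indices of the genes most variable beyond the count mean-variance trend.

    A quadratic log-log trend of per-gene variance against mean is fitted over
    all expressed genes; genes are ranked by their residual above the trend.
    Restricting PCA to these genes keeps structured biological variation and
    drops pure sampling noise, as in the standard Seurat/scanpy workflow.
    """
    X = np.asarray(m.counts.todense(), dtype=float)
    mu = X.mean(axis=1)
    v = X.var(axis=1, ddof=1)
    ok = (mu > 0) & (v > 0)
    if ok.sum() < 3:
        return np.argsort(-v)[:n_top]
    coef = np.polyfit(np.log(mu[ok]), np.log(v[ok]), 2)
    resid = np.full(mu.size, -np.inf)
    resid[ok] = np.log(v[ok]) - np.polyval(coef, np.log(mu[ok]))
    return np.sort(np.argsort(-resid)[: min(n_top, int(ok.sum()))])


def pca_scores(expr: ExpressionMatrix, n_pcs: int, matrix: str = "scaled",
               seed: int = 42, gene_idx: np.ndarray | None = None):
    """Cells x n_pcs principal-component scores (and the component stdevs)."""
    mat = expr.scaled if matrix == "scaled" else expr.normalized
    if mat is None:
        raise ValueError(f"{matrix} matrix not available")
    if gene_idx is not None:
        mat = mat[gene_idx]
    X = mat.T  # cells x genes
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed)
    scores = pca.fit_transform(X)
    return scores, np.sqrt(pca.explained_variance_), pca


def snn_graph(scores: np.ndarray, k: int = 20, prune: float = 1 / 15) -> sp.csr_matrix:
    """Shared-nearest-neighbour graph: Jaccard overlap of k-NN sets, edges
    below the pruning threshold removed.  Symmetric, zero diagonal."""
    n = scores.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    _, idx = nn.kneighbors(scores)
    rows = np.repeat(np.arange(n), idx.shape[1])
    indicator = sp.csr_matrix(
        (np.ones(idx.size), (rows, idx.ravel())), shape=(n, n))
    shared = indicator @ indicator.T  # |N(i) & N(j)| (both sets include self)
    shared = shared.toarray()
    size = k + 1
    jaccard = shared / (2 * size - shared)
    np.fill_diagonal(jaccard, 0.0)
    jaccard[jaccard < prune] = 0.0
    return sp.csr_matrix(jaccard)


def louvain_cluster(graph: sp.csr_matrix, resolution: float, seed: int = 42) -> np.ndarray:
    """Louvain community detection (igraph multilevel) on a weighted graph."""
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    coo = sp.triu(graph, k=1).tocoo()
    g = ig.Graph(n=graph.shape[0], edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    ig.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights=coo.data.tolist() if coo.nnz else None,
                                  resolution=resolution)
    return np.asarray(part.membership, dtype=int)


def cluster_cells(expr: ExpressionMatrix, n_pcs: int, resolution: float,
                  k: int = 20, seed: int = 42,
                  gene_idx: np.ndarray | None = None) -> np.ndarray:
    """PCA (optionally on a variable-gene subset) -> SNN graph -> Louvain."""
    n_cells = len(expr.cell_barcodes)
    if n_cells < n_pcs:
        raise ValueError(f"fewer cells ({n_cells}) than requested PCs ({n_pcs})")
    scores, _, _ = pca_scores(expr, n_pcs, seed=seed, gene_idx=gene_idx)
    graph = snn_graph(scores, k=k)
    return louvain_cluster(graph, resolution, seed=seed)


# ---------------------------------------------------------------------------
# cluster-level QC
# ---------------------------------------------------------------------------

def flag_poor_clusters(table: pd.DataFrame, cluster_col: str = "cluster") -> set:
    """Clusters whose median detected genes AND median UMI both fall below the
    dataset-wide 25th percentiles."""
    clusters = table[cluster_col].unique()
    if len(clusters) < 2:
        warnings.warn("single cluster: poor-cluster filtering skipped")
        return set()
    q25_genes = np.percentile(table["n_genes_detected"], 25)
    q25_umi = np.percentile(table["n_umi"], 25)
    flagged = set()
    for c in clusters:
        sub = table[table[cluster_col] == c]
        if (sub["n_genes_detected"].median() < q25_genes
                and sub["n_umi"].median() < q25_umi):
            flagged.add(c)
    return flagged


def flag_contaminant_clusters(expr: ExpressionMatrix, clusters,
                              marker_sets: dict[str, list[str]]) -> set:
    """Clusters whose median per-cell mean normalized expression of ANY marker
    set exceeds that set's 90th percentile over all cells."""
    clusters = np.asarray(clusters)
    flagged = set()
    for name, genes in marker_sets.items():
        if not genes:
            raise ValueError(f"marker set {name!r} is empty")
        score = expr.gene_rows(genes, matrix="normalized").mean(axis=0)
        p90 = np.percentile(score, 90)
        for c in np.unique(clusters):
            if np.median(score[clusters == c]) > p90:
                flagged.add(c)
    return flagged


# ---------------------------------------------------------------------------
# confounder handling
# ---------------------------------------------------------------------------

def classify_sex(expr: ExpressionMatrix, w_genes: list[str], seed: int = 42) -> pd.Series:
    """k-means (k=2) on per-cell mean W-chromosome expression; the
    higher-centroid group is labelled female."""
    if len(expr.cell_barcodes) < 2:
        raise ValueError("need at least two cells")
    score = expr.gene_rows(w_genes, matrix="normalized").mean(axis=0)
    if np.ptp(score) == 0:
        warnings.warn("W-gene expression is constant; assigning a single sex label")
        label = "female" if score[0] > 0 else "male"
        return pd.Series(label, index=expr.cell_barcodes, name="sex")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(score.reshape(-1, 1))
    female_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    labels = np.where(km.labels_ == female_cluster, "female", "male")
    return pd.Series(labels, index=expr.cell_barcodes, name="sex")


def regress_covariates(expr: ExpressionMatrix, covariates: pd.DataFrame,
                       clip: float = 10.0) -> ExpressionMatrix:
    """Per gene, OLS of normalized expression on the covariates (plus an
    intercept); the scaled matrix holds the standardised residuals, clipped at
    +/- ``clip``.  Categorical covariates are expanded to indicators;
    collinear columns are dropped with a warning."""
    if covariates.isna().any().any():
        raise ValueError("covariates contain missing values")
    if not covariates.index.equals(expr.cell_barcodes):
        covariates = covariates.loc[expr.cell_barcodes]
    if covariates.shape[1]:
        X = pd.get_dummies(covariates, drop_first=True).astype(float)
        cols = [X[c].to_numpy() for c in X.columns]
        names = ["intercept"] + list(X.columns)
    else:
        cols, names = [], ["intercept"]
    design = np.column_stack([np.ones(len(covariates))] + cols)
    # drop linearly dependent columns via pivoted QR
    r_mat, piv = qr(design, mode="r", pivoting=True)
    r_diag = np.abs(np.diag(r_mat))
    rank = int((r_diag > 1e-10 * r_diag[0]).sum()) if design.size else 0
    if rank < design.shape[1]:
        keep = np.sort(piv[:rank])
        dropped = [names[j] for j in range(design.shape[1]) if j not in keep]
        warnings.warn(f"collinear covariates dropped: {dropped}")
        design = design[:, keep]
    Y = expr.normalized  # genes x cells
    beta, *_ = np.linalg.lstsq(design, Y.T, rcond=None)
    resid = Y - (design @ beta).T
    sd = resid.std(axis=1, ddof=0, keepdims=True)
    # numerically-zero residual variance (perfectly explained genes) -> 0
    tiny = sd <= 1e-10 * (np.abs(Y).max(axis=1, keepdims=True) + 1.0)
    sd[tiny] = np.inf
    scaled = np.clip(resid / sd, -clip, clip)
    scaled[np.broadcast_to(tiny, scaled.shape)] = 0.0
    return ExpressionMatrix(normalized=expr.normalized, gene_ids=expr.gene_ids,
                            cell_barcodes=expr.cell_barcodes, scaled=scaled)
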