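"""Fate inference on a cell-cell Markov chain.

A velocity kernel (softmax over cosine similarity between each cell's RNA
velocity vector and the displacements toward its neighbours, scale 4) is mixed
with a kNN connectivity kernel (weights 0.8 / 0.2) into a row-stochastic
transition matrix.  Named terminal cell sets are made absorbing, and the
absorption probability of every transient cell toward each fate is obtained
from the fundamental-matrix linear system (I - Q) F = R.  Cells are ordered in
a latent time by diffusion pseudotime from a stage-anchored root.

The velocity itself uses the steady-state estimator (per-gene extreme-quantile
zero-intercept regression of unspliced on spliced moments); see
docs/methods.md for why this replaces a full dynamical kinetic fit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import CountMatrix, normalize_counts


# ---------------------------------------------------------------------------
# moments and velocity
# ---------------------------------------------------------------------------

def spliced_pca(m: CountMatrix, n_pcs: int = 20, seed: int = 42):
    """PCA of normalized spliced counts; returns (cell scores, fitted PCA,
    the normalized spliced matrix genes x cells)."""
    if "spliced" not in m.layers:
        raise ValueError("spliced layer missing")
    spliced_cm = CountMatrix(counts=m.layers["spliced"], gene_ids=m.gene_ids,
                             cell_barcodes=m.cell_barcodes)
    expr = normalize_counts(spliced_cm)
    X = expr.normalized.T  # cells x genes
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed)
    scores = pca.fit_transform(X)
    return scores, pca, expr.normalized


def knn_indices(scores: np.ndarray, k: int):
    n = scores.shape[0]
    if k > n:
        raise ValueError(f"k = {k} must be at most the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k).fit(scores)
    _, idx = nn.kneighbors(scores)  # includes self (distance 0) as first column
    return idx


def compute_moments(m: CountMatrix, n_pcs: int = 20, k: int = 20, seed: int = 42):
    """First-order moments: per cell, the mean of the spliced and unspliced
    layers over its k nearest neighbours plus itself, in the top-n_pcs PC
    space of normalized spliced counts.

    Returns (u_smoothed, s_smoothed, pc_scores, knn index array), with the
    smoothed layers as genes x cells arrays.
    """
    if "unspliced" not in m.layers:
        raise ValueError("unspliced layer missing")
    scores, _, _ = spliced_pca(m, n_pcs=n_pcs, seed=seed)
    if k >= m.n_cells:
        raise ValueError(
            f"k = {k} neighbours requires more than k cells, got {m.n_cells}")
    idx = knn_indices(scores, k + 1)
    n = scores.shape[0]
    rows = np.repeat(np.arange(n), idx.shape[1])
    A = sp.csr_matrix((np.full(idx.size, 1.0 / idx.shape[1]), (rows, idx.ravel())),
                      shape=(n, n))
    s = np.asarray(m.layers["spliced"].todense(), dtype=float)
    u = np.asarray(m.layers["unspliced"].todense(), dtype=float)
    s_sm = (A @ s.T).T
    u_sm = (A @ u.T).T
    return u_sm, s_sm, scores, idx


def estimate_velocity(u: np.ndarray, s: np.ndarray, quantile: float = 0.05):
    """Steady-state velocity: per gene, gamma_hat is the zero-intercept slope
    of u on s over the cells in the bottom and top ``quantile`` of s, and
    velocity = u - gamma_hat * s.

    Returns (velocity genes x cells, gamma_hat per gene, valid-gene mask);
    genes with no spliced signal are excluded with a warning.
    """
    if u.shape != s.shape:
        raise ValueError("u and s must be aligned")
    n_genes, n_cells = s.shape
    gamma_hat = np.full(n_genes, np.nan)
    valid = s.max(axis=1) > 0
    if not valid.all():
        warnings.warn(f"{(~valid).sum()} genes with all-zero spliced signal excluded")
    n_q = max(1, int(np.ceil(quantile * n_cells)))
    order = np.argsort(s, axis=1)
    for gi in np.flatnonzero(valid):
        sel = np.concatenate([order[gi, :n_q], order[gi, -n_q:]])
        ss, uu = s[gi, sel], u[gi, sel]
        denom = (ss * ss).sum()
        gamma_hat[gi] = (uu * ss).sum() / denom if denom > 0 else 0.0
    velocity = np.where(valid[:, None], u - gamma_hat[:, None] * s, 0.0)
    return velocity, gamma_hat, valid


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def _row_stochastic(T: sp.csr_matrix) -> sp.csr_matrix:
    T = sp.csr_matrix(T)
    rowsum = np.asarray(T.sum(axis=1)).ravel()
    if np.any(rowsum <= 0):
        raise ValueError("empty transition row")
    inv = sp.diags(1.0 / rowsum)
    return sp.csr_matrix(inv @ T)


def velocity_kernel(pc_scores: np.ndarray, velocity_pcs: np.ndarray,
                    knn_idx: np.ndarray, softmax_scale: float = 4.0) -> sp.csr_matrix:
    """Transition probabilities proportional to exp(scale * cosine similarity)
    between each cell's projected velocity and the displacement toward each
    neighbour.  The cell itself is included with cosine 0; zero-velocity cells
    fall back to a uniform row over their neighbour set."""
    n, k = knn_idx.shape
    rows, cols, vals = [], [], []
    vnorm = np.linalg.norm(velocity_pcs, axis=1)
    for i in range(n):
        nbrs = knn_idx[i]
        cos = np.zeros(len(nbrs))
        if vnorm[i] > 0:
            disp = pc_scores[nbrs] - pc_scores[i]
            dnorm = np.linalg.norm(disp, axis=1)
            nz = dnorm > 0
            cos[nz] = (disp[nz] @ velocity_pcs[i]) / (dnorm[nz] * vnorm[i])
            w = np.exp(softmax_scale * (cos - cos.max()))
        else:
            w = np.ones(len(nbrs))
        w = w / w.sum()
        rows.extend([i] * len(nbrs))
        cols.extend(nbrs.tolist())
        vals.extend(w.tolist())
    T = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return _row_stochastic(T)


def project_velocity(velocity: np.ndarray, pca: PCA) -> np.ndarray:
    """Project gene-space velocities (genes x cells) into the expression PC
    space (cells x n_pcs)."""
    return velocity.T @ pca.components_.T


def connectivity_kernel(knn_idx: np.ndarray | sp.spmatrix) -> sp.csr_matrix:
    """Row-normalized symmetric kNN connectivities."""
    if sp.issparse(knn_idx):
        A = sp.csr_matrix(knn_idx)
        n = A.shape[0]
    else:
        idx = np.asarray(knn_idx)
        n = idx.shape[0]
        rows = np.repeat(np.arange(n), idx.shape[1])
        A = sp.csr_matrix((np.ones(idx.size), (rows, idx.ravel())), shape=(n, n))
    A = A.maximum(A.T)
    A = A.tolil()
    A.setdiag(0.0)
    A = A.tocsr()
    A.eliminate_zeros()
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    isolated = rowsum == 0
    if isolated.any():
        warnings.warn(f"{isolated.sum()} isolated cells given self-transition 1")
        A = A.tolil()
        for i in np.flatnonzero(isolated):
            A[i, i] = 1.0
        A = A.tocsr()
    return _row_stochastic(A)


def combine_kernels(Tv: sp.spmatrix, Tc: sp.spmatrix, w_velocity: float = 0.8,
                    w_connectivity: float = 0.2) -> sp.csr_matrix:
    if Tv.shape != Tc.shape:
        raise ValueError("kernel shapes differ")
    if w_velocity < 0 or w_connectivity < 0 or abs(w_velocity + w_connectivity - 1) > 1e-12:
        raise ValueError("kernel weights must be non-negative and sum to 1")
    return sp.csr_matrix(w_velocity * sp.csr_matrix(Tv) + w_connectivity * sp.csr_matrix(Tc))


# ---------------------------------------------------------------------------
# absorption probabilities
# ---------------------------------------------------------------------------

def absorption_probabilities(T: sp.spmatrix, terminal_sets: dict[str, np.ndarray]) -> pd.DataFrame:
    """Absorption probabilities of the chain toward each named terminal set.

    Terminal cells are made absorbing; for transient cells the linear system
    (I - Q) F = R is solved, with Q the transient-transient block and R the
    transient-to-terminal block aggregated by fate.  Rows sum to 1; a terminal
    cell carries an indicator row for its own fate.
    """
    T = sp.csr_matrix(T)
    n = T.shape[0]
    fates = list(terminal_sets)
    terminal = np.zeros(n, dtype=bool)
    fate_of = np.full(n, -1)
    for fi, f in enumerate(fates):
        idx = np.asarray(list(terminal_sets[f]), dtype=int)
        if idx.size == 0:
            raise ValueError(f"terminal set {f!r} is empty")
        if terminal[idx].any():
            raise ValueError("terminal sets must be disjoint")
        terminal[idx] = True
        fate_of[idx] = fi
    transient = ~terminal
    F = np.zeros((n, len(fates)))
    F[terminal, :] = np.eye(len(fates))[fate_of[terminal]]
    if transient.any():
        Q = T[transient][:, transient]
        R = T[transient][:, terminal].toarray()
        R_agg = np.zeros((R.shape[0], len(fates)))
        for fi in range(len(fates)):
            R_agg[:, fi] = R[:, fate_of[terminal] == fi].sum(axis=1)
        A = sp.eye(Q.shape[0], format="csc") - Q.tocsc()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # singularity surfaces as NaN rows below
                sol = spla.spsolve(A, R_agg)
        except RuntimeError:
            sol = np.column_stack([
                spla.lgmres(A, R_agg[:, j], rtol=1e-12, atol=1e-12)[0]
                for j in range(R_agg.shape[1])])
        sol = np.atleast_2d(sol)
        if sol.shape[0] != R_agg.shape[0]:
            sol = sol.T
        rowsum = sol.sum(axis=1)
        bad = np.flatnonzero(~np.isfinite(rowsum) | (np.abs(rowsum - 1.0) > 1e-6))
        if bad.size:
            orig = np.flatnonzero(transient)[bad]
            raise ValueError(
                f"cells with no path to any terminal set: {orig[:20].tolist()}"
                + ("..." if bad.size > 20 else ""))
        F[transient] = sol
    return pd.DataFrame(np.clip(F, 0.0, 1.0), columns=fates)


def simulate_absorption(T: np.ndarray, terminal_sets: dict, start: int,
                        n_walks: int, rng) -> np.ndarray:
    """Monte-Carlo absorption estimate for one start cell: ``n_walks``
    exchangeable random walks stepped as multinomial population counts."""
    T = np.asarray(T)
    n = T.shape[0]
    fates = list(terminal_sets)
    fate_of = np.full(n, -1)
    for fi, f in enumerate(fates):
        fate_of[np.asarray(list(terminal_sets[f]), dtype=int)] = fi
    counts = np.zeros(n, dtype=np.int64)
    counts[start] = n_walks
    absorbed = np.zeros(len(fates), dtype=np.int64)
    for _ in range(100000):
        nxt = np.zeros(n, dtype=np.int64)
        for s_ in np.flatnonzero(counts):
            nxt += rng.multinomial(counts[s_], T[s_])
        # settle walkers that reached a terminal cell
        for fi in range(len(fates)):
            sel = fate_of == fi
            absorbed[fi] += nxt[sel].sum()
            nxt[sel] = 0
        counts = nxt
        if counts.sum() == 0:
            break
    if counts.sum():
        raise RuntimeError("walks not absorbed within the step budget")
    return absorbed / n_walks


# ---------------------------------------------------------------------------
# latent time
# ---------------------------------------------------------------------------

def _diffusion_decomposition(adjacency: sp.spmatrix, n_comps: int = 15):
    """Eigendecomposition of the symmetrized diffusion operator
    D^-1/2 A D^-1/2; returns (eigenvalues desc, diffusion-map coordinates)."""
    A = sp.csr_matrix(adjacency)
    A = A.maximum(A.T)
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise ValueError("graph has isolated cells")
    Dm = sp.diags(1.0 / np.sqrt(deg))
    M = sp.csr_matrix(Dm @ A @ Dm)
    k = min(n_comps + 1, M.shape[0] - 1)
    vals, vecs = spla.eigsh(M, k=k, which="LA")
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # right eigenvectors of the row-stochastic walk
    psi = vecs / np.sqrt(deg)[:, None]
    psi = psi / np.linalg.norm(psi, axis=0)
    return vals, psi


def latent_time(adjacency: sp.spmatrix, cell_table: pd.DataFrame,
                stage_order, stage_col: str = "stage", n_comps: int = 15) -> pd.Series:
    """Diffusion pseudotime from a stage-anchored root, scaled to [0, 1].

    The root is the cell of the earliest represented stage with the extremal
    first non-trivial diffusion-map coordinate; latent time is the diffusion
    pseudotime distance from that root, min-max scaled.
    """
    A = sp.csr_matrix(adjacency)
    n_comp_graph, comp = connected_components(A.maximum(A.T), directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(comp)
        raise ValueError(
            f"graph is disconnected: {n_comp_graph} components with sizes {sizes.tolist()}")
    vals, psi = _diffusion_decomposition(A, n_comps=n_comps)
    stages = cell_table[stage_col].to_numpy()
    present = [s for s in stage_order if (stages == s).any()]
    if not present:
        raise ValueError("no cell belongs to any stage in stage_order")
    earliest = stages == present[0]
    psi1 = psi[:, 1]
    cand = np.flatnonzero(earliest)
    root = cand[np.argmax(np.abs(psi1[cand] - np.median(psi1)))]
    lam = vals[1:]
    lam = np.clip(lam, None, 1 - 1e-10)
    w = lam / (1.0 - lam)
    diff = (psi[:, 1:] - psi[root, 1:]) * w
    dpt = np.sqrt((diff ** 2).sum(axis=1))
    dpt = dpt - dpt.min()
    if dpt.max() > 0:
        dpt = dpt / dpt.max()
    return pd.Series(dpt, index=cell_table.index, name="latent_time")


def terminal_sets_from_labels(states, stages, selectors: dict[str, list[str]]) -> dict:
    """Resolve "STATE@stage" selectors against per-cell state/stage labels."""
    states = np.asarray(states)
    stages = np.asarray(stages)
    out = {}
    for fate, sels in selectors.items():
        idx = []
        for sel in sels:
            state, _, stage = sel.partition("@")
            m = (states == state) & ((stages == stage) if stage else True)
            idx.extend(np.flatnonzero(m).tolist())
        out[fate] = np.asarray(sorted(set(idx)), dtype=int)
        if out[fate].size == 0:
            raise ValueError(f"terminal fate {fate!r}: no cells match {sels}")
    return out
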