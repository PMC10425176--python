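"""Cell-state classification against a binary knowledge matrix.

Each cell is scored for every candidate state as the mean scaled expression of
that state's marker genes; each cluster is then assigned the state with the
highest median score over its cells.  Candidate states are restricted per
developmental stage, and classification is run on each stage subset
independently (re-scaled and re-clustered) before labels are transferred back
to the merged dataset.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix, KnowledgeMatrix, normalize_counts
from .qc import (cluster_cells, highly_variable_genes, pca_scores,
                 regress_covariates, select_pcs)


def score_states(expr: ExpressionMatrix, km: KnowledgeMatrix, stage: str) -> pd.DataFrame:
    """Cells x allowed-states mean scaled expression of each state's genes.

    Knowledge-matrix genes absent from the data are dropped per state with a
    warning; a state losing all its genes is an error.
    """
    if expr.scaled is None:
        raise ValueError("score_states requires the scaled matrix")
    allowed = km.stage_allowed[stage]
    scores = {}
    for state in allowed:
        genes = km.state_genes(state)
        present = [g for g in genes if g in expr.gene_ids]
        if not present:
            raise ValueError(f"state {state!r}: none of its genes are in the data")
        if len(present) < len(genes):
            warnings.warn(
                f"state {state!r}: {len(genes) - len(present)} knowledge-matrix "
                f"genes absent from data, dropped")
        idx = expr.gene_ids.get_indexer(present)
        scores[state] = expr.scaled[idx].mean(axis=0)
    return pd.DataFrame(scores, index=expr.cell_barcodes, columns=allowed)


def classify_clusters(scores: pd.DataFrame, clusters) -> dict:
    """Assign each cluster the state with the highest median score.

    Ties break to the earlier knowledge-matrix column (scores column order).
    """
    clusters = np.asarray(clusters)
    assignment = {}
    for c in np.unique(clusters):
        mask = clusters == c
        if not mask.any():
            raise ValueError(f"cluster {c}: no cells")
        med = scores.iloc[np.flatnonzero(mask)].median(axis=0)
        assignment[c] = med.index[int(np.argmax(med.to_numpy()))]
    return assignment


def classify_stage(counts: CountMatrix, table: pd.DataFrame, km: KnowledgeMatrix,
                   stage: str, covariate_cols: list[str] | None = None,
                   resolution: float = 0.5, seed: int = 42):
    """Classify one stage subset: re-normalize, re-scale (regressing the given
    covariates), re-cluster, score, and assign per-cluster states.

    Returns (cell_states: Series, clusters: ndarray, cluster_states: dict).
    """
    expr = normalize_counts(counts)
    if covariate_cols:
        expr = regress_covariates(expr, table[covariate_cols])
    else:
        expr = regress_covariates(expr, pd.DataFrame(index=table.index))
    hvg = highly_variable_genes(counts)
    _, stdevs, _ = pca_scores(expr, n_pcs=min(50, len(table) - 1, len(hvg) - 1),
                              seed=seed, gene_idx=hvg)
    n_pcs = max(select_pcs(stdevs), 10)
    clusters = cluster_cells(expr, n_pcs=n_pcs, resolution=resolution, seed=seed,
                             gene_idx=hvg)
    scores = score_states(expr, km, stage)
    cluster_states = classify_clusters(scores, clusters)
    cell_states = pd.Series([cluster_states[c] for c in clusters],
                            index=table.index, name="state")
    return cell_states, clusters, cluster_states


def classify_all_stages(counts: CountMatrix, table: pd.DataFrame, km: KnowledgeMatrix,
                        stage_col: str = "stage", covariate_cols: list[str] | None = None,
                        resolution: float = 0.5, seed: int = 42) -> pd.DataFrame:
    """Per-stage classification transferred onto the merged dataset as labels."""
    out = []
    for stage in pd.unique(table[stage_col]):
        mask = (table[stage_col] == stage).to_numpy()
        sub = counts.subset_cells(mask)
        sub_table = table.loc[mask]
        states, clusters, _ = classify_stage(
            sub, sub_table, km, stage, covariate_cols=covariate_cols,
            resolution=resolution, seed=seed)
        out.append(pd.DataFrame({"state": states, "stage_cluster": clusters},
                                index=sub_table.index))
    merged = pd.concat(out)
    return merged.loc[table.index]
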