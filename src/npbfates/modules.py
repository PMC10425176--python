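"""Gene-module detection and filtering.

Modules are found by iterative hierarchical clustering of gene-gene Spearman
correlations (average linkage on 1 - rho), with an expression filter applied
after each cut and the clustering repeated on the surviving genes until the
membership is stable.  Detected modules are then passed through cascaded
differential-expression filters: keep modules DE across cell states, drop
modules DE between sequencing batches, and optionally keep modules DE among
the three late lineages (or, for the NPB subset, between the neural-crest and
placodal state groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, rankdata

from .containers import ExpressionMatrix, GeneModule

LOGFC_EPS = 1e-9


def _spearman_matrix(X: np.ndarray) -> np.ndarray:
    """Gene-gene Spearman correlation (rows = genes)."""
    ranks = rankdata(X, axis=1)
    return np.corrcoef(ranks)


def prefilter_genes(expr: ExpressionMatrix, min_corr: float = 0.3,
                    min_partners: int = 3, genes=None) -> list[str]:
    """Keep genes whose Spearman correlation is >= ``min_corr`` with at least
    ``min_partners`` other genes; constant genes are dropped."""
    if genes is None:
        genes = list(expr.gene_ids)
    X = expr.gene_rows(genes)
    variable = X.std(axis=1) > 0
    genes = [g for g, v in zip(genes, variable) if v]
    X = X[variable]
    if len(genes) < min_partners + 1:
        raise ValueError("too few variable genes for the requested partner count")
    rho = _spearman_matrix(X)
    np.fill_diagonal(rho, -np.inf)
    partners = (rho >= min_corr).sum(axis=1)
    kept = [g for g, p in zip(genes, partners) if p >= min_partners]
    if not kept:
        raise ValueError(
            f"no gene has >= {min_partners} partners at Spearman >= {min_corr}; "
            "relax min_corr or min_partners")
    return kept


def module_expressed_filter(module: GeneModule, expr: ExpressionMatrix,
                            min_cells: int = 10, min_gene_frac: float = 0.40) -> bool:
    """Expression filter on a module.

    A gene is "on" in a cell if its normalized value is > 0; a cell expresses
    the module if more than half the module's genes are on.  The module passes
    iff at least ``min_cells`` cells express it and, among those cells, the
    mean fraction of module genes on is >= ``min_gene_frac``.
    """
    X = expr.gene_rows(module.genes)
    on = X > 0
    frac_on = on.mean(axis=0)
    expressing = frac_on > 0.5
    if expressing.sum() < min_cells:
        return False
    return bool(frac_on[expressing].mean() >= min_gene_frac)


def detect_modules(expr: ExpressionMatrix, n_modules: int, max_iter: int = 10,
                   genes=None, min_cells: int = 10,
                   min_gene_frac: float = 0.40) -> list[GeneModule]:
    """Iterative hierarchical clustering of genes into co-expression modules."""
    if genes is None:
        genes = list(expr.gene_ids)
    genes = list(genes)
    if len(genes) < n_modules:
        raise ValueError(f"{len(genes)} genes < {n_modules} requested modules")
    for _ in range(max_iter):
        X = expr.gene_rows(genes)
        rho = _spearman_matrix(X)
        dist = np.clip(1.0 - rho, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        k = min(n_modules, len(genes))
        labels = fcluster(linkage(squareform(dist, checks=False), method="average"),
                          t=k, criterion="maxclust")
        grouped = {}
        for g, lab in zip(genes, labels):
            grouped.setdefault(lab, []).append(g)
        survivors = []
        for lab in sorted(grouped):
            mod = GeneModule(id=f"tmp{lab}", genes=grouped[lab])
            if module_expressed_filter(mod, expr, min_cells=min_cells,
                                       min_gene_frac=min_gene_frac):
                survivors.extend(grouped[lab])
        if not survivors:
            raise ValueError("no module survives the expression filter")
        if survivors == genes:
            out = [grouped[lab] for lab in sorted(grouped)
                   if module_expressed_filter(GeneModule(id="x", genes=grouped[lab]),
                                              expr, min_cells, min_gene_frac)]
            out.sort(key=lambda gs: (-len(gs), gs[0]))
            return [GeneModule(id=f"GM{i + 1}", genes=gs) for i, gs in enumerate(out)]
        genes = survivors
    # membership still moving at max_iter: return the last surviving cut
    out = sorted(grouped.values(), key=lambda gs: (-len(gs), gs[0]))
    return [GeneModule(id=f"GM{i + 1}", genes=gs) for i, gs in enumerate(out)]


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """One-vs-rest Wilcoxon rank-sum results for one group contrast."""

    table: pd.DataFrame  # gene, group, logfc, pvalue, adj_pvalue


def de_table(genes: list[str], expr: ExpressionMatrix, groups) -> DEResult:
    """Per gene and per group: one-vs-rest two-sided Wilcoxon rank-sum on
    normalized expression; natural-log fold change of group means (pseudocount
    1e-9); Bonferroni adjustment over the tested genes."""
    groups = np.asarray(groups)
    X = expr.gene_rows(genes)
    rows = []
    n_tested = len(genes)
    for grp in pd.unique(groups):
        mask = groups == grp
        if mask.sum() < 2 or (~mask).sum() < 2:
            warnings.warn(f"group {grp!r} has fewer than 2 cells on one side; skipped")
            continue
        xin, xout = X[:, mask], X[:, ~mask]
        # fold change on the expression scale (undo log1p before averaging)
        mean_in = np.expm1(xin).mean(axis=1)
        mean_out = np.expm1(xout).mean(axis=1)
        logfc = np.log((mean_in + LOGFC_EPS) / (mean_out + LOGFC_EPS))
        for gi, g in enumerate(genes):
            p = mannwhitneyu(xin[gi], xout[gi], alternative="two-sided",
                             method="auto").pvalue
            rows.append((g, grp, logfc[gi], p, min(1.0, p * n_tested)))
    return DEResult(table=pd.DataFrame(
        rows, columns=["gene", "group", "logfc", "pvalue", "adj_pvalue"]))


def de_fraction(module: GeneModule, expr: ExpressionMatrix, groups,
                min_logfc: float, max_adj_p: float = 0.001) -> float:
    """Fraction of module genes significant (|logFC| > min_logfc and adjusted
    p < max_adj_p) in at least one group (one-vs-rest)."""
    res = de_table(module.genes, expr, groups).table
    if res.empty:
        return 0.0
    sig = res[(res["logfc"].abs() > min_logfc) & (res["adj_pvalue"] < max_adj_p)]
    return len(set(sig["gene"])) / len(module.genes)


def filter_module_set(modules: list[GeneModule], expr: ExpressionMatrix,
                      cell_states, batches, lineage_states_at_ss8: dict | None = None,
                      mode: str = "full", stages=None) -> list[GeneModule]:
    """Cascaded DE filters on a detected module set.

    mode="full": (a) keep modules with de_fraction > 0.5 across cell states at
    logFC 0.5; (b) drop modules with de_fraction > 0.5 between batches at
    logFC 0.25; (c) if ``lineage_states_at_ss8`` is given (fate name -> state
    labels), keep modules with de_fraction > 0.5 among the late lineages at
    logFC 0.25, computed on the last stage's cells.

    mode="npb": (a)/(c) are replaced by a single neural-crest-versus-placodal
    contrast at logFC 0.25; the batch filter (b) still applies.
    """
    if mode not in ("full", "npb"):
        raise ValueError(f"unknown mode {mode!r}")
    cell_states = np.asarray(cell_states)
    batches = np.asarray(batches)
    kept = list(modules)

    if mode == "full":
        kept = [m for m in kept
                if de_fraction(m, expr, cell_states, min_logfc=0.5) > 0.5]
    else:
        if lineage_states_at_ss8 is None:
            raise ValueError("npb mode requires the neural-crest/placodal state groups")
        contrast = np.full(cell_states.shape, "", dtype=object)
        for name, states in lineage_states_at_ss8.items():
            sel = np.isin(cell_states, list(states))
            if not sel.any():
                raise ValueError(f"lineage {name!r} has zero cells")
            contrast[sel] = name
        sub = contrast != ""
        sub_expr = _subset_cells(expr, sub)
        kept = [m for m in kept
                if de_fraction(m, sub_expr, contrast[sub], min_logfc=0.25) > 0.5]

    kept = [m for m in kept
            if not de_fraction(m, expr, batches, min_logfc=0.25) > 0.5]

    if mode == "full" and lineage_states_at_ss8 is not None:
        if stages is not None:
            stages = np.asarray(stages)
            last = pd.unique(stages)[-1]
            at_last = stages == last
        else:
            at_last = np.ones(cell_states.shape, bool)
        lineage = np.full(cell_states.shape, "", dtype=object)
        for name, states in lineage_states_at_ss8.items():
            sel = np.isin(cell_states, list(states)) & at_last
            if not sel.any():
                raise ValueError(f"lineage {name!r} has zero cells at the last stage")
            lineage[sel] = name
        sub = lineage != ""
        sub_expr = _subset_cells(expr, sub)
        kept = [m for m in kept
                if de_fraction(m, sub_expr, lineage[sub], min_logfc=0.25) > 0.5]
    return kept


def _subset_cells(expr: ExpressionMatrix, mask: np.ndarray) -> ExpressionMatrix:
    return ExpressionMatrix(
        normalized=expr.normalized[:, mask],
        gene_ids=expr.gene_ids,
        cell_barcodes=expr.cell_barcodes[mask],
        scaled=None if expr.scaled is None else expr.scaled[:, mask],
    )
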