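"""Core in-memory containers shared across the pipeline.

Conventions: count and expression matrices are genes x cells throughout
(rows = genes, columns = cells), matching the on-disk 10x triplet layout.
Per-cell metadata lives in a pandas DataFrame (the "cell table") indexed by
barcode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

STAGES = ("HH4", "HH5", "HH6", "HH7", "ss4", "ss8")

#: gene-id prefix -> class tag
GENE_CLASS_PREFIXES = {"MT-": "mito", "W-": "w_chrom", "Z-": "z_chrom"}


def gene_class(gene_id: str) -> str:
    for prefix, tag in GENE_CLASS_PREFIXES.items():
        if gene_id.startswith(prefix):
            return tag
    return "other"


@dataclass
class CountMatrix:
    """Raw genes x cells integer counts with optional spliced/unspliced layers."""

    counts: sp.csr_matrix
    gene_ids: pd.Index
    cell_barcodes: pd.Index
    layers: dict[str, sp.csr_matrix] = field(default_factory=dict)

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_barcodes = pd.Index(self.cell_barcodes)
        if self.gene_ids.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.cell_barcodes.has_duplicates:
            raise ValueError("duplicate cell barcodes")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_barcodes)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")
        for name, layer in self.layers.items():
            layer = sp.csr_matrix(layer)
            if layer.shape != self.counts.shape:
                raise ValueError(f"layer {name!r} shape {layer.shape} != {self.counts.shape}")
            self.layers[name] = layer

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_classes(self) -> pd.Series:
        return pd.Series([gene_class(g) for g in self.gene_ids], index=self.gene_ids)

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            counts=self.counts[idx],
            gene_ids=self.gene_ids[idx],
            cell_barcodes=self.cell_barcodes,
            layers={k: v[idx] for k, v in self.layers.items()},
        )

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            cell_barcodes=self.cell_barcodes[idx],
            layers={k: v[:, idx] for k, v in self.layers.items()},
        )


def cell_metrics(m: CountMatrix) -> pd.DataFrame:
    """Per-cell QC metrics: genes detected, total UMI, and % mitochondrial content."""
    counts = m.counts.tocsc()
    n_genes_detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    n_umi = np.asarray(counts.sum(axis=0)).ravel()
    mito = m.gene_classes.to_numpy() == "mito"
    mito_umi = np.asarray(counts[mito].sum(axis=0)).ravel() if mito.any() else np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(n_umi > 0, 100.0 * mito_umi / n_umi, 0.0)
    return pd.DataFrame(
        {
            "n_genes_detected": n_genes_detected.astype(int),
            "n_umi": n_umi.astype(int),
            "pct_mito": pct_mito,
        },
        index=m.cell_barcodes,
    )


@dataclass
class ExpressionMatrix:
    """Normalized (log of library-size-scaled counts + 1) and, optionally,
    scaled (per-gene standardised residuals after covariate regression)
    genes x cells matrices."""

    normalized: np.ndarray
    gene_ids: pd.Index
    cell_barcodes: pd.Index
    scaled: np.ndarray | None = None

    def __post_init__(self):
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_barcodes = pd.Index(self.cell_barcodes)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if self.normalized.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise ValueError("normalized shape does not match gene/cell labels")
        if self.scaled is not None:
            self.scaled = np.asarray(self.scaled, dtype=float)
            if self.scaled.shape != self.normalized.shape:
                raise ValueError("scaled shape differs from normalized")

    def gene_rows(self, genes, matrix: str = "normalized") -> np.ndarray:
        """Rows for the named genes, in the requested matrix, skipping absent genes."""
        mat = self.normalized if matrix == "normalized" else self.scaled
        if mat is None:
            raise ValueError(f"{matrix} matrix not available")
        present = [g for g in genes if g in self.gene_ids]
        missing = [g for g in genes if g not in self.gene_ids]
        if missing:
            warnings.warn(f"genes absent from data, skipped: {missing}")
        if not present:
            raise ValueError(f"none of the requested genes present: {list(genes)}")
        idx = self.gene_ids.get_indexer(present)
        return mat[idx]


def normalize_counts(m: CountMatrix, target_sum: float | None = None) -> ExpressionMatrix:
    """Library-size normalization to the median library size, then log1p."""
    counts = np.asarray(m.counts.todense(), dtype=float)
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("cells with zero total counts cannot be normalized")
    if target_sum is None:
        target_sum = float(np.median(lib))
    norm = np.log1p(counts * (target_sum / lib))
    return ExpressionMatrix(normalized=norm, gene_ids=m.gene_ids, cell_barcodes=m.cell_barcodes)


@dataclass
class KnowledgeMatrix:
    """Binary genes x cell-states matrix plus stage -> allowed-states map.

    Built from published in situ expression patterns: entry (g, s) = 1 means
    gene g is expressed in cell state s.
    """

    entries: pd.DataFrame  # genes x states, values in {0, 1}
    stage_allowed: dict[str, list[str]]

    def __post_init__(self):
        vals = self.entries.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("knowledge matrix entries must be 0/1")
        if (vals.sum(axis=0) == 0).any():
            empty = self.entries.columns[vals.sum(axis=0) == 0].tolist()
            raise ValueError(f"states with no marker genes: {empty}")
        for stage, states in self.stage_allowed.items():
            unknown = set(states) - set(self.entries.columns)
            if unknown:
                raise ValueError(f"stage {stage} allows unknown states: {sorted(unknown)}")

    @property
    def states(self) -> list[str]:
        return list(self.entries.columns)

    @property
    def genes(self) -> pd.Index:
        return self.entries.index

    def state_genes(self, state: str) -> list[str]:
        col = self.entries[state]
        return list(col.index[col == 1])


@dataclass
class GeneModule:
    """A named set of co-varying genes."""

    id: str
    genes: list[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"module {self.id}: empty gene list")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"module {self.id}: duplicate genes")


def module_scores(modules: list[GeneModule], expr: ExpressionMatrix,
                  matrix: str = "normalized") -> pd.DataFrame:
    """Per-cell mean expression over each module's genes (cells x modules)."""
    out = {}
    for m in modules:
        out[m.id] = expr.gene_rows(m.genes, matrix=matrix).mean(axis=0)
    return pd.DataFrame(out, index=expr.cell_barcodes)
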