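"""Pairwise gene-module co-expression and BLUP calling.

Module scores are min-max scaled to [0,1] within the cell set being analysed
(per stage in the pipeline).  A cell is a BLUP — a border-located undecided
progenitor — for a module pair when both scaled scores lie strictly above the
threshold (default 0.3).  The per-cell product of the two scaled scores is
the co-expression statistic summarised in histograms, and a two-colour blend
grid assigns each co-expressing cell an index pair for visualisation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def scale_module_scores(raw: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Per-module min-max scaling over all cells; a constant module becomes
    all zeros with a warning."""
    arr = np.asarray(raw, dtype=float)
    if arr.size == 0:
        raise ValueError("empty module scores")
    if arr.ndim == 1:
        arr = arr[:, None]
    lo = arr.min(axis=0)
    rng = arr.max(axis=0) - lo
    flat = rng == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant modules scaled to all zeros")
    rng_safe = np.where(flat, 1.0, rng)
    scaled = np.where(flat, 0.0, (arr - lo) / rng_safe)
    if isinstance(raw, pd.DataFrame):
        return pd.DataFrame(scaled, index=raw.index, columns=raw.columns)
    if np.asarray(raw).ndim == 1:
        return scaled.ravel()
    return scaled


def call_blups(scaled_a, scaled_b, threshold: float = 0.3) -> np.ndarray:
    """True where BOTH scaled module scores are strictly above the threshold."""
    if not (0 <= threshold < 1):
        raise ValueError("threshold must be in [0, 1)")
    a = np.asarray(scaled_a, dtype=float)
    b = np.asarray(scaled_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("scaled scores are not aligned")
    return (a > threshold) & (b > threshold)


def coexpression_product(scaled_a, scaled_b, n_bins: int = 50):
    """Per-cell product of the two scaled module scores plus a fixed-binning
    histogram summary on [0, 1].

    Returns (product array, histogram DataFrame with bin_left/bin_right/count).
    """
    a = np.asarray(scaled_a, dtype=float)
    b = np.asarray(scaled_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("scaled scores are not aligned")
    product = a * b
    counts, edges = np.histogram(product, bins=n_bins, range=(0.0, 1.0))
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    return product, hist


def blend_colors(scaled_a, scaled_b, grid: int = 100, threshold: float = 0.3) -> pd.DataFrame:
    """Two-colour blend indices on a grid x grid matrix.

    index = floor(scaled * (grid - 1)); cells failing the BLUP threshold are
    flagged unassigned (their indices are still reported).
    """
    if grid < 2:
        raise ValueError("grid must be >= 2")
    a = np.asarray(scaled_a, dtype=float)
    b = np.asarray(scaled_b, dtype=float)
    idx_a = np.floor(a * (grid - 1)).astype(int)
    idx_b = np.floor(b * (grid - 1)).astype(int)
    idx_a = np.clip(idx_a, 0, grid - 1)
    idx_b = np.clip(idx_b, 0, grid - 1)
    assigned = call_blups(a, b, threshold)
    return pd.DataFrame({"index_a": idx_a, "index_b": idx_b, "assigned": assigned})


def blup_fraction_by_group(scores: pd.DataFrame, module_a: str, module_b: str,
                           groups, threshold: float = 0.3,
                           group_order=None) -> pd.Series:
    """Fraction of BLUP-called cells per group, with min-max scaling computed
    within each group (the per-stage convention)."""
    groups = np.asarray(groups)
    order = group_order if group_order is not None else pd.unique(groups)
    out = {}
    for g in order:
        mask = groups == g
        if not mask.any():
            continue
        sub = scale_module_scores(scores.loc[mask, [module_a, module_b]])
        out[g] = float(call_blups(sub[module_a], sub[module_b], threshold).mean())
    series = pd.Series(out, name="blup_fraction")
    series.index.name = "stage"
    return series
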