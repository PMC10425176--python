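"""Readers and writers for the on-disk interchange formats.

Matrices travel as Matrix Market; gene/barcode labels as single-column TSVs
(the 10x triplet convention); tables as headed CSV; the knowledge matrix as a
CSV whose first column is the gene id with one 0/1 column per cell state, plus
a JSON stage -> allowed-states map.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, KnowledgeMatrix


def write_10x(m: CountMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", m.counts.astype(np.int64), field="integer")
    pd.Series(m.gene_ids).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(m.cell_barcodes).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    for name, layer in m.layers.items():
        scipy.io.mmwrite(outdir / f"{name}.mtx", layer.astype(np.int64), field="integer")


def read_10x(indir) -> CountMatrix:
    """Read a 10x-style triplet (plus any spliced/unspliced sidecar layers)."""
    indir = Path(indir)
    counts = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    if counts.shape[0] != len(genes):
        raise ValueError(
            f"matrix.mtx declares {counts.shape[0]} genes but features.tsv has {len(genes)} rows")
    if counts.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix.mtx declares {counts.shape[1]} cells but barcodes.tsv has {len(barcodes)} rows")
    layers = {}
    for name in ("spliced", "unspliced"):
        p = indir / f"{name}.mtx"
        if p.exists():
            layers[name] = sp.csr_matrix(scipy.io.mmread(p))
    return CountMatrix(counts=counts, gene_ids=pd.Index(genes),
                       cell_barcodes=pd.Index(barcodes), layers=layers)


def read_knowledge_matrix(csv_path, stage_map_path) -> KnowledgeMatrix:
    entries = pd.read_csv(csv_path, index_col=0)
    with open(stage_map_path) as fh:
        stage_allowed = json.load(fh)
    return KnowledgeMatrix(entries=entries, stage_allowed=stage_allowed)


def load_example_knowledge_matrix() -> KnowledgeMatrix:
    """The bundled reduced knowledge matrix.

    Illustrative only: a synthetic stand-in with the same structure as a
    literature-derived matrix (binary marker signatures per state, shared
    module genes, stage-restricted candidate states), not the published one.
    """
    data = resources.files("npbfates") / "data"
    return read_knowledge_matrix(
        str(data / "example_knowledge_matrix.csv"),
        str(data / "example_stage_states.json"),
    )


def load_example_terminal_fates() -> dict:
    data = resources.files("npbfates") / "data"
    with open(str(data / "example_terminal_fates.json")) as fh:
        return json.load(fh)


def write_csv(df: pd.DataFrame, path, **kw) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format="%.10g", **kw)
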