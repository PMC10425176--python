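"""End-to-end pipeline driver: QC -> clustering -> classification -> gene
modules -> fate inference -> dynamics -> co-expression, with every stage
writing a CSV/Matrix Market artifact and an auditable log line.  Re-running
with the same config and inputs reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import coexpression as _coexpr
from . import dynamics as _dynamics
from . import fate as _fate
from . import modules as _modules
from . import qc as _qc
from .containers import STAGES, module_scores, normalize_counts
from .io import load_example_knowledge_matrix, load_example_terminal_fates, read_10x, write_csv

log = logging.getLogger("npbfates")


@dataclass
class PipelineConfig:
    """Every threshold of the analysis in one auditable place.

    Defaults are the study's printed values: 5-cell gene filter, 1000/6500
    detected-gene bounds, 15% mitochondrial cap, clustering resolutions 2.0
    (QC) and 0.5 (analysis), Spearman 0.3 with 3 partners, module filters of
    10 cells / 40% consistency, DE cut-offs 0.5 / 0.25 logFC at adjusted p
    0.001, kernel weights 0.8 / 0.2, softmax scale 4, 20 neighbours over 20
    PCs, 4 GAM knots, and a 0.3 co-expression threshold.
    """

    min_cells: int = 5
    min_genes: int = 1000
    max_genes: int = 6500
    max_mito: float = 15.0
    resolution_qc: float = 2.0
    resolution: float = 0.5
    min_corr: float = 0.3
    min_partners: int = 3
    n_modules: int = 40
    module_min_cells: int = 10
    module_min_gene_frac: float = 0.40
    de_logfc_states: float = 0.5
    de_logfc_batch: float = 0.25
    de_max_adj_p: float = 0.001
    w_velocity: float = 0.8
    w_connectivity: float = 0.2
    softmax_scale: float = 4.0
    knn: int = 20
    n_pcs: int = 20
    gam_knots: int = 4
    coexpr_threshold: float = 0.3
    seed: int = 42
    stages: tuple = STAGES
    contaminant_markers: dict = field(
        default_factory=lambda: {"mesoderm": [f"MESO-{j:02d}" for j in range(1, 13)]})
    cycle_gene_prefix: str = "CYC-"
    terminal_fates: dict | None = None
    lineage_states: dict = field(
        default_factory=lambda: {"neural": ["N"], "neural_crest": ["NC"],
                                 "placodal": ["PPR"]})

    def validate(self):
        if self.min_cells < 0:
            raise ValueError("PipelineConfig.min_cells: must be >= 0")
        if not 0 < self.min_genes <= self.max_genes:
            raise ValueError("PipelineConfig.min_genes/max_genes: need 0 < min <= max")
        if self.max_mito < 0 or self.max_mito > 100:
            raise ValueError("PipelineConfig.max_mito: must be a percentage in [0, 100]")
        for name in ("resolution_qc", "resolution", "softmax_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PipelineConfig.{name}: must be > 0")
        if not (0 <= self.coexpr_threshold < 1):
            raise ValueError("PipelineConfig.coexpr_threshold: must be in [0, 1)")
        if abs(self.w_velocity + self.w_connectivity - 1) > 1e-12:
            raise ValueError("PipelineConfig kernel weights must sum to 1")
        if self.knn < 2 or self.n_pcs < 2:
            raise ValueError("PipelineConfig.knn/n_pcs: must be >= 2")
        if self.gam_knots < 1:
            raise ValueError("PipelineConfig.gam_knots: must be >= 1")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig, input_dir, out_dir) -> Path:
    """Run the full analysis on a 10x triplet + metadata.csv directory."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    km = load_example_knowledge_matrix()
    terminal = config.terminal_fates or load_example_terminal_fates()

    def stage_log(name, **params):
        log.info("%s: %s", name, json.dumps(params, sort_keys=True, default=str))

    try:
        counts = read_10x(input_dir)
        meta = pd.read_csv(Path(input_dir) / "metadata.csv", index_col=0)
        meta = meta.loc[counts.cell_barcodes]
    except Exception as e:
        raise RuntimeError(f"stage 'load' failed: {e}") from e

    # ---- QC ---------------------------------------------------------------
    try:
        counts = _qc.filter_genes(counts, min_cells=config.min_cells)
        stage_log("filter_genes", min_cells=config.min_cells, kept=counts.n_genes)
        counts, table = _qc.filter_cells(
            counts, meta, min_genes=config.min_genes, max_genes=config.max_genes,
            max_mito=config.max_mito)
        stage_log("filter_cells", min_genes=config.min_genes,
                  max_genes=config.max_genes, max_mito=config.max_mito,
                  kept=counts.n_cells)
        expr = normalize_counts(counts)
        expr = _qc.regress_covariates(expr, pd.DataFrame(index=table.index))
        qc_clusters = _qc.cluster_cells(expr, n_pcs=config.n_pcs,
                                        resolution=config.resolution_qc,
                                        k=config.knn, seed=config.seed)
        table["qc_cluster"] = qc_clusters
        poor = _qc.flag_poor_clusters(table, cluster_col="qc_cluster")
        marker_sets = {k: [g for g in v if g in counts.gene_ids]
                       for k, v in config.contaminant_markers.items()}
        marker_sets = {k: v for k, v in marker_sets.items() if v}
        contam = (_qc.flag_contaminant_clusters(expr, qc_clusters, marker_sets)
                  if marker_sets else set())
        stage_log("cluster_qc", resolution=config.resolution_qc, seed=config.seed,
                  poor=sorted(poor), contaminant=sorted(contam))
        keep = ~np.isin(qc_clusters, sorted(poor | contam))
        counts = counts.subset_cells(keep)
        table = table.loc[keep].copy()
        expr = normalize_counts(counts)
        w_genes = [g for g in counts.gene_ids if g.startswith("W-")]
        if w_genes:
            table["sex"] = _qc.classify_sex(expr, w_genes, seed=config.seed)
        else:
            table["sex"] = "unknown"
        cyc_genes = [g for g in counts.gene_ids if g.startswith(config.cycle_gene_prefix)]
        if cyc_genes:
            table["cycle_score"] = expr.gene_rows(cyc_genes).mean(axis=0)
        else:
            table["cycle_score"] = 0.0
        covars = table[["pct_mito", "sex", "cycle_score", "batch"]]
        expr = _qc.regress_covariates(expr, covars)
        stage_log("regress_covariates", covariates=list(covars.columns))
        write_csv(table, out / "qc_report.csv")
    except RuntimeError:
        raise
    except Exception as e:
        raise RuntimeError(f"stage 'qc' failed: {e}") from e

    # ---- classification ---------------------------------------------------
    try:
        classified = _classify.classify_all_stages(
            counts, table, km, covariate_cols=["pct_mito", "sex", "cycle_score", "batch"],
            resolution=config.resolution, seed=config.seed)
        table["state"] = classified["state"]
        table["stage_cluster"] = classified["stage_cluster"]
        stage_log("classify", resolution=config.resolution, seed=config.seed)
        write_csv(table[["stage", "batch", "state", "stage_cluster"]],
                  out / "cell_states.csv")
    except Exception as e:
        raise RuntimeError(f"stage 'classify' failed: {e}") from e

    # ---- gene modules -----------------------------------------------------
    try:
        kept_genes = _modules.prefilter_genes(
            expr, min_corr=config.min_corr, min_partners=config.min_partners)
        mods = _modules.detect_modules(
            expr, n_modules=min(config.n_modules, max(2, len(kept_genes) // 2)),
            genes=kept_genes, min_cells=config.module_min_cells,
            min_gene_frac=config.module_min_gene_frac)
        surviving = _modules.filter_module_set(
            mods, expr, table["state"], table["batch"],
            lineage_states_at_ss8=config.lineage_states, mode="full",
            stages=table["stage"])
        stage_log("modules", n_detected=len(mods), n_surviving=len(surviving))
        write_csv(pd.DataFrame(
            [(m.id, g) for m in surviving for g in m.genes],
            columns=["module_id", "gene"]), out / "modules.csv", index=False)
        scores = module_scores(surviving, expr)
        write_csv(scores, out / "module_scores.csv")
    except Exception as e:
        raise RuntimeError(f"stage 'modules' failed: {e}") from e

    # ---- fate inference ---------------------------------------------------
    try:
        # moments are taken in raw spliced PC space; the kernel geometry and
        # the latent-time graph live in covariate-regressed spliced PC space,
        # so that sex/batch structure does not fragment the graph
        u_sm, s_sm, _, _ = _fate.compute_moments(
            counts, n_pcs=config.n_pcs, k=config.knn, seed=config.seed)
        velocity, gamma_hat, valid = _fate.estimate_velocity(u_sm, s_sm)
        from .containers import CountMatrix as _CM
        spl = _CM(counts=counts.layers["spliced"], gene_ids=counts.gene_ids,
                  cell_barcodes=counts.cell_barcodes)
        sexpr = _qc.regress_covariates(normalize_counts(spl), covars)
        hvg_s = _qc.highly_variable_genes(spl)
        pcs, _, pca = _qc.pca_scores(sexpr, config.n_pcs, seed=config.seed,
                                     gene_idx=hvg_s)
        knn_idx = _fate.knn_indices(pcs, config.knn)
        vel_pcs = velocity[hvg_s].T @ pca.components_.T
        Tv = _fate.velocity_kernel(pcs, vel_pcs, knn_idx,
                                   softmax_scale=config.softmax_scale)
        Tc = _fate.connectivity_kernel(knn_idx)
        T = _fate.combine_kernels(Tv, Tc, config.w_velocity, config.w_connectivity)
        tsets = _fate.terminal_sets_from_labels(
            table["state"], table["stage"], terminal)
        probs = _fate.absorption_probabilities(T, tsets)
        probs.index = table.index
        lt = _fate.latent_time(Tc, table, stage_order=config.stages)
        stage_log("fate", w_velocity=config.w_velocity,
                  w_connectivity=config.w_connectivity,
                  softmax_scale=config.softmax_scale, knn=config.knn,
                  n_pcs=config.n_pcs)
        write_csv(probs, out / "fate_probabilities.csv")
        write_csv(lt.to_frame(), out / "latent_time.csv")
    except Exception as e:
        raise RuntimeError(f"stage 'fate' failed: {e}") from e

    # ---- dynamics ---------------------------------------------------------
    try:
        grids = []
        for m in surviving:
            for fate_name in probs.columns:
                w = probs[fate_name].to_numpy()
                if (w > 0).sum() < config.gam_knots + 2:
                    continue
                fit = _dynamics.fit_weighted_gam(
                    lt.to_numpy(), scores[m.id].to_numpy(), w,
                    knots=config.gam_knots)
                grid = np.linspace(lt.min(), lt.max(), 100)
                mean, lo_ci, hi_ci = fit.predict_with_ci(grid)
                grids.append(pd.DataFrame(
                    {"module": m.id, "fate": fate_name, "latent_time": grid,
                     "mean": mean, "lower": lo_ci, "upper": hi_ci}))
        stage_log("dynamics", knots=config.gam_knots, n_fits=len(grids))
        if grids:
            write_csv(pd.concat(grids, ignore_index=True),
                      out / "dynamics_predictions.csv", index=False)
    except Exception as e:
        raise RuntimeError(f"stage 'dynamics' failed: {e}") from e

    # ---- co-expression ----------------------------------------------------
    try:
        if len(surviving) >= 2:
            a, b = surviving[0].id, surviving[1].id
            fracs = _coexpr.blup_fraction_by_group(
                scores, a, b, table["stage"], threshold=config.coexpr_threshold,
                group_order=config.stages)
            rows, hists = [], []
            for stg in config.stages:
                mask = (table["stage"] == stg).to_numpy()
                if not mask.any():
                    continue
                sub = _coexpr.scale_module_scores(scores.loc[mask, [a, b]])
                product, hist = _coexpr.coexpression_product(sub[a], sub[b])
                blup = _coexpr.call_blups(sub[a], sub[b], config.coexpr_threshold)
                rows.append(pd.DataFrame(
                    {"cell": scores.index[mask], "module_a": a, "module_b": b,
                     "scaled_a": sub[a].to_numpy(), "scaled_b": sub[b].to_numpy(),
                     "product": product, "blup": blup}))
                hist.insert(0, "stage", stg)
                hists.append(hist)
            stage_log("coexpression", pair=[a, b],
                      threshold=config.coexpr_threshold,
                      blup_fractions=fracs.round(4).to_dict())
            write_csv(pd.concat(rows, ignore_index=True),
                      out / "coexpression.csv", index=False)
            write_csv(pd.concat(hists, ignore_index=True),
                      out / "coexpression_histograms.csv", index=False)
            write_csv(fracs.to_frame(), out / "blup_fractions.csv")
    except Exception as e:
        raise RuntimeError(f"stage 'coexpression' failed: {e}") from e

    config.to_json(out / "config.json")
    return out
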