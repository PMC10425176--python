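"""Synthetic scRNA-seq generator for the neural plate border analysis.

Emulates six ordered chick stages (HH4..ss8) in which discrete cell states
with binarized marker signatures sit along a mediolateral axis.  Fate-linked
gene modules are expressed as graded logistic bands along that axis; the band
overlap narrows stage by stage, so cells co-expressing two fate modules
(BLUP-like cells) become rarer over developmental time.  Spliced/unspliced
layers follow a transcription-splicing-degradation kinetic model with
stage-increasing time, so RNA velocity points from early toward late states.

All counts are negative binomial around the configured means; a single seeded
generator drives every random draw, so identical configs give bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import STAGES, CountMatrix, KnowledgeMatrix
from .io import load_example_knowledge_matrix


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

@dataclass
class KineticParams:
    """Rates of the two-species transcription model du/dt = alpha - beta*u,
    ds/dt = beta*u - gamma*s, evaluated from u(0) = s(0) = 0."""

    alpha: float
    beta: float
    gamma_rate: float
    t: float

    def validate(self):
        for name in ("alpha", "beta", "gamma_rate", "t"):
            v = getattr(self, name)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"KineticParams.{name}: non-finite value")
        if np.any(np.asarray(self.alpha) < 0):
            raise ValueError("KineticParams.alpha: must be >= 0")
        if np.any(np.asarray(self.beta) <= 0):
            raise ValueError("KineticParams.beta: must be > 0")
        if np.any(np.asarray(self.gamma_rate) <= 0):
            raise ValueError("KineticParams.gamma_rate: must be > 0")
        if np.any(np.asarray(self.t) < 0):
            raise ValueError("KineticParams.t: must be >= 0")


def simulate_kinetics(p: KineticParams):
    """Closed-form unspliced/spliced abundances of the kinetic model.

    u(t) = (alpha/beta)(1 - e^(-beta t))
    s(t) = (alpha/gamma)(1 - e^(-gamma t)) + alpha (e^(-gamma t) - e^(-beta t)) / (gamma - beta)

    with the analytic limit used where beta == gamma.  Accepts scalars or
    broadcastable arrays in any field.
    """
    p.validate()
    alpha = np.asarray(p.alpha, dtype=float)
    beta = np.asarray(p.beta, dtype=float)
    gamma = np.asarray(p.gamma_rate, dtype=float)
    t = np.asarray(p.t, dtype=float)
    u = (alpha / beta) * (1.0 - np.exp(-beta * t))
    close = np.isclose(beta, gamma, rtol=1e-12, atol=1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        cross = alpha * (np.exp(-gamma * t) - np.exp(-beta * t)) / (gamma - beta)
    cross_limit = -alpha * t * np.exp(-gamma * t)
    cross = np.where(close, cross_limit, cross)
    s = (alpha / gamma) * (1.0 - np.exp(-gamma * t)) + cross
    u = np.maximum(u, 0.0)
    s = np.maximum(s, 0.0)
    if u.ndim == 0:
        return float(u), float(s)
    return u, s


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Generator settings.  Defaults are the study conditions the pipeline is
    exercised under: 6 stages x 500 cells, 2000 genes, two sequencing batches,
    marker fold-change 2 over a baseline mean of 10 counts."""

    n_cells_per_stage: int = 500
    stages: tuple = STAGES
    n_genes: int = 2000
    knowledge_matrix: KnowledgeMatrix | None = None
    marker_effect: float = 2.0
    baseline_mean: float = 10.0
    dispersion: float = 0.2
    n_batches: int = 2
    batch_effect_sd: float = 0.7
    frac_mito_genes: float = 0.02
    frac_w_genes: float = 0.01
    frac_poor_cells: float = 0.04
    frac_contaminant_cells: float = 0.03
    gradient_steepness: float = 250.0
    blup_frac: float = 0.25
    seed: int = 0
    # secondary knobs (documented in docs/methods.md)
    module_factor_sd: float = 0.2
    block_factor_sd: float = 0.6
    marker_factor_sd: float = 0.0
    splicing_rate: float = 2.0
    degradation_rate: float = 1.0
    stage_time_unit: float = 0.2
    poor_retention: tuple = (0.03, 0.10)

    def validate(self):
        if self.knowledge_matrix is None:
            object.__setattr__(self, "knowledge_matrix", load_example_knowledge_matrix())
        pos = ("n_cells_per_stage", "n_genes", "baseline_mean", "dispersion",
               "gradient_steepness", "batch_effect_sd", "splicing_rate",
               "degradation_rate", "stage_time_unit")
        for name in pos:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"SimConfig.{name}: non-finite value")
        if self.n_cells_per_stage <= 0:
            raise ValueError("SimConfig.n_cells_per_stage: must be positive")
        if self.n_genes <= 0:
            raise ValueError("SimConfig.n_genes: must be positive")
        if self.marker_effect <= 1:
            raise ValueError("SimConfig.marker_effect: must be > 1")
        if self.baseline_mean <= 0:
            raise ValueError("SimConfig.baseline_mean: must be > 0")
        if self.dispersion <= 0:
            raise ValueError("SimConfig.dispersion: must be > 0")
        if self.n_batches < 1:
            raise ValueError("SimConfig.n_batches: must be >= 1")
        if self.batch_effect_sd < 0:
            raise ValueError("SimConfig.batch_effect_sd: must be >= 0")
        for name in ("frac_mito_genes", "frac_w_genes", "frac_poor_cells",
                     "frac_contaminant_cells", "blup_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"SimConfig.{name}: must be in [0, 1]")
        if len(self.stages) != len(set(self.stages)):
            raise ValueError("SimConfig.stages: labels must be unique")
        missing = [s for s in self.stages if s not in self.knowledge_matrix.stage_allowed]
        if missing:
            raise ValueError(f"SimConfig.stages: no allowed-state entry for {missing}")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SimTruth:
    """Ground truth per synthetic cell plus the planted gene-module partition."""

    cells: pd.DataFrame  # state, ml_position, fate, stage, batch, sex, is_poor, is_contaminant
    module_assignment: dict  # gene -> module id

    def module_genes(self, module_id: str) -> list[str]:
        return [g for g, m in self.module_assignment.items() if m == module_id]


# ---------------------------------------------------------------------------
# spatial band machinery
# ---------------------------------------------------------------------------

def _stage_bands(km: KnowledgeMatrix, stage: str) -> dict[str, tuple[float, float]]:
    """Equal partition of the mediolateral axis [0,1] over the stage's allowed
    states, in the order the stage map lists them (medial first)."""
    states = km.stage_allowed[stage]
    edges = np.linspace(0.0, 1.0, len(states) + 1)
    return {s: (edges[i], edges[i + 1]) for i, s in enumerate(states)}


def _soft_band(x: np.ndarray, a: float, b: float, scale: float) -> np.ndarray:
    """Logistic membership of [a, b]; outer boundaries (0 and 1) do not decay."""
    left = 1.0 if a <= 0 else 1.0 / (1.0 + np.exp(-(x - a) / scale))
    right = 1.0 if b >= 1 else 1.0 / (1.0 + np.exp(-(b - x) / scale))
    return left * right


def _hard_band(x: np.ndarray, bands: dict) -> np.ndarray:
    """State label per position from the band partition (right-open intervals)."""
    states = list(bands)
    edges = [bands[s][0] for s in states] + [1.0 + 1e-12]
    idx = np.searchsorted(edges, x, side="right") - 1
    idx = np.clip(idx, 0, len(states) - 1)
    return np.asarray(states, dtype=object)[idx]


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def _gene_catalogue(config: SimConfig):
    """Fixed, deterministic gene layout: knowledge-matrix genes first, then
    planted batch-artifact / flat blocks, contaminant markers, mito / sex /
    stress / cell-cycle genes, and housekeeping filler."""
    km_genes = list(config.knowledge_matrix.genes)
    n_mito = int(round(config.frac_mito_genes * config.n_genes))
    n_w = int(round(config.frac_w_genes * config.n_genes))
    blocks = {
        "batch1": [f"BATCH1-{j:02d}" for j in range(1, 9)],
        "batch2": [f"BATCH2-{j:02d}" for j in range(1, 9)],
        "flat1": [f"FLAT1-{j:02d}" for j in range(1, 9)],
        "flat2": [f"FLAT2-{j:02d}" for j in range(1, 9)],
        "meso": [f"MESO-{j:02d}" for j in range(1, 13)],
        "mito": [f"MT-G{j:03d}" for j in range(1, n_mito + 1)],
        "w": [f"W-G{j:03d}" for j in range(1, n_w + 1)],
        "z": [f"Z-G{j:03d}" for j in range(1, 6)],
        "stress": [f"STRESS-{j:02d}" for j in range(1, 11)],
        "cycle": [f"CYC-{j:02d}" for j in range(1, 11)],
    }
    n_fixed = len(km_genes) + sum(len(v) for v in blocks.values())
    n_hk = config.n_genes - n_fixed
    if n_hk < 10:
        raise ValueError(
            f"SimConfig.n_genes: need at least {n_fixed + 10} genes for the "
            f"configured catalogue, got {config.n_genes}")
    blocks["hk"] = [f"HK-{j:04d}" for j in range(1, n_hk + 1)]
    gene_ids = km_genes + [g for v in blocks.values() for g in v]
    return gene_ids, blocks


def _module_map(km: KnowledgeMatrix):
    """Genes marked for >=2 states form graded fate modules, grouped by their
    state signature; single-state genes are crisp state markers."""
    sig = {}
    for g in km.genes:
        on = tuple(s for s in km.states if km.entries.loc[g, s] == 1)
        sig.setdefault(on, []).append(g)
    markers = {}   # gene -> state
    modules = {}   # signature -> genes
    for on, genes in sig.items():
        if len(on) == 1:
            for g in genes:
                markers[g] = on[0]
        else:
            modules[on] = genes
    return markers, modules


def _module_id(states: tuple, final_states: list) -> str:
    """Name a module after its earliest final-stage state (medial first)."""
    for s in final_states:
        if s in states:
            return "module_" + s
    return "module_" + "+".join(states)


def simulate_dataset(config: SimConfig):
    """Generate (CountMatrix with spliced/unspliced layers, CellTable, SimTruth)."""
    config.validate()
    km = config.knowledge_matrix
    rng = np.random.default_rng(config.seed)
    stages = list(config.stages)
    n_stages = len(stages)
    n_cells = config.n_cells_per_stage * n_stages
    gene_ids, blocks = _gene_catalogue(config)
    n_genes = len(gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    markers, modules = _module_map(km)
    final_bands = _stage_bands(km, stages[-1])
    # overlap width of the graded module bands, shrinking over stages,
    # while the in-band amplitude of the fate programs rises (fate genes are
    # upregulated as expression domains sharpen)
    shrink = np.geomspace(0.72, 0.06, n_stages)
    widths = config.blup_frac * shrink
    amp = np.linspace(1.0, 2.2, n_stages)
    marker_scale = 1.0 / config.gradient_steepness

    # --- per-cell latent variables -------------------------------------
    stage_idx = np.repeat(np.arange(n_stages), config.n_cells_per_stage)
    stage_lab = np.asarray(stages, dtype=object)[stage_idx]
    x = rng.uniform(0.0, 1.0, n_cells)
    batch = rng.integers(0, config.n_batches, n_cells)
    sex = np.where(rng.random(n_cells) < 0.5, "female", "male")
    f_mito = rng.uniform(0.02, 0.10, n_cells)
    cyc = rng.normal(0.0, 1.0, n_cells)
    n_poor = int(round(config.frac_poor_cells * n_cells))
    n_cont = int(round(config.frac_contaminant_cells * n_cells))
    flagged = rng.choice(n_cells, size=n_poor + n_cont, replace=False)
    is_poor = np.zeros(n_cells, bool)
    is_poor[flagged[:n_poor]] = True
    is_cont = np.zeros(n_cells, bool)
    is_cont[flagged[n_poor:]] = True
    # two severity tiers: severe cells fall below the per-cell gene threshold,
    # mild ones survive it and are left for cluster-level QC
    poor_severe = np.zeros(n_cells, bool)
    poor_severe[flagged[: n_poor // 2]] = True
    poor_mild = is_poor & ~poor_severe
    # mild poor cells look like dying cells: raised mitochondrial fraction
    f_mito[poor_mild] = rng.uniform(0.10, 0.14, int(poor_mild.sum()))
    eta = {sig_: rng.normal(0.0, config.module_factor_sd, n_cells) for sig_ in modules}
    eta_state = {st: rng.normal(0.0, config.marker_factor_sd, n_cells)
                 for st in km.states}
    eta_block = {b: rng.normal(0.0, config.block_factor_sd, n_cells)
                 for b in ("batch1", "batch2", "flat1", "flat2", "meso")}
    t_frac = rng.uniform(0.0, 1.15, n_cells)  # within-stage maturation spread

    # --- mean matrix ----------------------------------------------------
    me = config.marker_effect
    base = config.baseline_mean
    mean = np.full((n_genes, n_cells), base, dtype=float)
    state = np.empty(n_cells, dtype=object)
    beta, gamma = config.splicing_rate, config.degradation_rate
    t_cell = config.stage_time_unit * (stage_idx + t_frac)
    spliced_mean = np.empty_like(mean)
    unspliced_mean = np.empty_like(mean)
    spliced_mean[:] = mean
    unspliced_mean[:] = mean * (gamma / beta)

    for si, stg in enumerate(stages):
        cells = stage_idx == si
        bands = _stage_bands(km, stg)
        state[cells] = _hard_band(x[cells], bands)
        allowed = set(km.stage_allowed[stg])
        xs = x[cells]
        # crisp state markers (steady-state layers: u/s at the kinetic
        # equilibrium around the marker mean)
        for g, st in markers.items():
            if st in allowed:
                a, b = bands[st]
                m = _soft_band(xs, a, b, marker_scale)
                mu_g = (base * (1.0 + (me - 1.0) * m)
                        * np.exp(eta_state[st][cells]))
                mean[gene_pos[g], cells] = mu_g
                spliced_mean[gene_pos[g], cells] = mu_g
                unspliced_mean[gene_pos[g], cells] = mu_g * (gamma / beta)
        # graded fate modules: soft membership of the union of the module's
        # state bands at this stage, width narrowing with stage
        for sig_, genes in modules.items():
            present = [s for s in sig_ if s in allowed]
            if present:
                m = np.zeros_like(xs)
                for s in present:
                    a, b = bands[s]
                    m = np.maximum(m, _soft_band(xs, a, b, widths[si]))
            else:
                m = np.zeros_like(xs)
            # fate-specifier profile: near-off outside the domain, rising
            # in-band amplitude over stages
            target = (base * (0.15 + (me - 1.0) * m * amp[si])
                      * np.exp(eta[sig_][cells]))
            # kinetic lag: expression rises toward the stage target over time
            p = KineticParams(alpha=gamma * target, beta=beta, gamma_rate=gamma,
                              t=t_cell[cells])
            u, s_ = simulate_kinetics(p)
            # all genes of one module share the module-level factor; their
            # independent NB noise is added at sampling time.  The main counts
            # carry the full-strength graded program; only the kinetic layers
            # are scaled down early, putting early cells on the rising branch.
            for g in genes:
                gi = gene_pos[g]
                mean[gi, cells] = target
                spliced_mean[gi, cells] = s_
                unspliced_mean[gi, cells] = u

    # contaminant cells express a mesoderm-like program instead of ectoderm
    if is_cont.any():
        km_rows = [gene_pos[g] for g in km.genes]
        mean[np.ix_(km_rows, is_cont)] = base
        spliced_mean[np.ix_(km_rows, is_cont)] = base
        unspliced_mean[np.ix_(km_rows, is_cont)] = base * (gamma / beta)
    meso_rows = [gene_pos[g] for g in blocks["meso"]]
    mean[meso_rows] = base * 0.1
    mean[np.ix_(meso_rows, is_cont)] = base * 4.0
    for j, b in enumerate(("batch1", "batch2")):
        rows = [gene_pos[g] for g in blocks[b]]
        bump = np.where(batch == (j % config.n_batches), math.exp(config.batch_effect_sd), 1.0)
        mean[rows] = base * bump * np.exp(eta_block[b])
    for b in ("flat1", "flat2"):
        rows = [gene_pos[g] for g in blocks[b]]
        mean[rows] = base * np.exp(eta_block[b])
    mean[meso_rows] *= np.exp(eta_block["meso"])
    mito_rows = [gene_pos[g] for g in blocks["mito"]]
    mean[mito_rows] = base * 60.0 * f_mito
    w_rows = [gene_pos[g] for g in blocks["w"]]
    mean[w_rows] = base * np.where(sex == "female", 1.5, 0.05)
    z_rows = [gene_pos[g] for g in blocks["z"]]
    mean[z_rows] = base * np.where(sex == "female", 0.8, 1.4)
    stress_rows = [gene_pos[g] for g in blocks["stress"]]
    mean[stress_rows] = base * np.exp(0.8 * (f_mito - 0.06) / 0.0231)
    for rows in (meso_rows, mito_rows, w_rows, z_rows, stress_rows):
        spliced_mean[rows] = mean[rows]
        unspliced_mean[rows] = mean[rows] * (gamma / beta)
    cyc_rows = [gene_pos[g] for g in blocks["cycle"]]
    mean[cyc_rows] = base * np.exp(0.4 * cyc)
    spliced_mean[cyc_rows] = mean[cyc_rows]
    unspliced_mean[cyc_rows] = mean[cyc_rows] * (gamma / beta)
    for b in ("batch1", "batch2", "flat1", "flat2"):
        rows = [gene_pos[g] for g in blocks[b]]
        spliced_mean[rows] = mean[rows]
        unspliced_mean[rows] = mean[rows] * (gamma / beta)

    # mild poor cells: degraded mRNA flattens the expression program
    if poor_mild.any():
        km_rows_all = [gene_pos[g] for g in km.genes]
        sub = np.ix_(km_rows_all, poor_mild)
        mean[sub] = base + 0.15 * (mean[sub] - base)
        spliced_mean[sub] = base + 0.15 * (spliced_mean[sub] - base)
        unspliced_mean[sub] = (gamma / beta) * spliced_mean[sub]

    # --- sampling -------------------------------------------------------
    def nb(mu):
        if config.dispersion < 1e-8:
            return rng.poisson(mu)
        size = 1.0 / config.dispersion
        return rng.negative_binomial(size, size / (size + mu))

    counts = nb(mean)
    spliced = nb(spliced_mean)
    unspliced = nb(unspliced_mean)

    # poor-quality cells: downsampled libraries (two severity tiers, the
    # milder of which survives the per-cell medium filter and is left for
    # cluster-level QC to catch)
    for idx_set, keep in ((np.flatnonzero(poor_severe), config.poor_retention[0]),
                          (np.flatnonzero(poor_mild), config.poor_retention[1])):
        if len(idx_set):
            counts[:, idx_set] = rng.binomial(counts[:, idx_set], keep)
            spliced[:, idx_set] = rng.binomial(spliced[:, idx_set], keep)
            unspliced[:, idx_set] = rng.binomial(unspliced[:, idx_set], keep)

    barcodes = pd.Index([f"CELL{i:05d}" for i in range(n_cells)])
    cm = CountMatrix(
        counts=sp.csr_matrix(counts.astype(np.int64)),
        gene_ids=pd.Index(gene_ids),
        cell_barcodes=barcodes,
        layers={
            "spliced": sp.csr_matrix(spliced.astype(np.int64)),
            "unspliced": sp.csr_matrix(unspliced.astype(np.int64)),
        },
    )
    cell_table = pd.DataFrame(
        {"stage": stage_lab, "batch": [f"batch{b + 1}" for b in batch]}, index=barcodes)
    fate = _hard_band(x, final_bands)
    module_assignment = {}
    final_states = km.stage_allowed[stages[-1]]
    for sig_, genes in modules.items():
        for g in genes:
            module_assignment[g] = _module_id(sig_, final_states)
    for b in ("batch1", "batch2", "flat1", "flat2"):
        for g in blocks[b]:
            module_assignment[g] = f"module_{b}"
    truth = SimTruth(
        cells=pd.DataFrame(
            {
                "stage": stage_lab,
                "batch": [f"batch{b + 1}" for b in batch],
                "state": state,
                "ml_position": x,
                "fate": fate,
                "sex": sex,
                "is_poor": is_poor,
                "is_contaminant": is_cont,
            },
            index=barcodes,
        ),
        module_assignment=module_assignment,
    )
    return cm, cell_table, truth
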