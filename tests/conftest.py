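import warnings

import numpy as np
import pandas as pd
import pytest

from npbfates import SimConfig, normalize_counts, simulate_dataset
from npbfates.containers import cell_metrics

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def default_dataset():
    """The full-scale synthetic dataset: 6 stages x 500 cells at default
    generator settings (marker effect 2, two batches, poor and contaminant
    cells planted)."""
    cfg = SimConfig(seed=7)
    counts, table, truth = simulate_dataset(cfg)
    return cfg, counts, table, truth


@pytest.fixture(scope="session")
def clean_dataset():
    """A smaller clean dataset (no poor/contaminant cells) for module,
    fate and co-expression tests."""
    cfg = SimConfig(n_cells_per_stage=250, seed=5,
                    frac_poor_cells=0.0, frac_contaminant_cells=0.0)
    counts, table, truth = simulate_dataset(cfg)
    return cfg, counts, table, truth


@pytest.fixture(scope="session")
def clean_covariates(clean_dataset):
    """Confounder table (mito %, sex call, cycle score, batch) for the clean
    dataset, as the pipeline builds it."""
    from npbfates.qc import classify_sex

    cfg, counts, table, truth = clean_dataset
    met = cell_metrics(counts)
    expr = normalize_counts(counts)
    sex = classify_sex(expr, [g for g in counts.gene_ids if g.startswith("W-")])
    cyc = expr.gene_rows([g for g in counts.gene_ids if g.startswith("CYC-")]).mean(axis=0)
    return pd.DataFrame(
        {"pct_mito": met["pct_mito"], "sex": sex, "cycle_score": cyc,
         "batch": table["batch"]})


def rk4_kinetics(alpha, beta, gamma, t_end, n_steps=20000):
    """Independent numerical oracle for the transcription-splicing-degradation
    ODE du/dt = alpha - beta u, ds/dt = beta u - gamma s from (0, 0)."""
    h = t_end / n_steps
    u = s = 0.0
    for _ in range(n_steps):
        def du(u_):
            return alpha - beta * u_

        def ds(u_, s_):
            return beta * u_ - gamma * s_

        k1u, k1s = du(u), ds(u, s)
        k2u, k2s = du(u + h / 2 * k1u), ds(u + h / 2 * k1u, s + h / 2 * k1s)
        k3u, k3s = du(u + h / 2 * k2u), ds(u + h / 2 * k2u, s + h / 2 * k2s)
        k4u, k4s = du(u + h * k3u), ds(u + h * k3u, s + h * k3s)
        u += h / 6 * (k1u + 2 * k2u + 2 * k3u + k4u)
        s += h / 6 * (k1s + 2 * k2s + 2 * k3s + k4s)
    return u, s
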