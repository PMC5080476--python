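import numpy as np
import pandas as pd
import pytest

from regforest import features as ft
from regforest import synthdata as sd


@pytest.fixture(scope="session")
def small_config() -> sd.SynthConfig:
    """A reduced cohort used across module tests: 60 genes x 80 samples,
    12 TFs (3 active), 12 miRNAs (2 active)."""
    return sd.SynthConfig(
        n_genes=60,
        n_samples=80,
        n_tfs=12,
        n_mirnas=12,
        n_active_tfs=3,
        n_active_mirnas=2,
        binding_density=0.15,
        n_targets_per_regulator=12,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sd.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    cohort, tfb, mirb, _ = small_cohort
    genes = ft.filter_model_genes(cohort.gene_expr.index, cohort, tfb, mirb)
    return [ft.assemble_gene_features(g, cohort, tfb, mirb) for g in genes]


def make_paired_counts(n_pairs, n_genes, dispersion, seed, logfc=None, patient_sd=0.2):
    """Paired tumor/normal NB counts with optional per-gene log2 fold changes,
    built directly (independent of the package's generator) for DE tests."""
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(6.0, 1.0, n_genes))
    pat = np.exp(rng.normal(0.0, patient_sd, n_pairs))
    sf = np.exp(rng.normal(0.0, 0.25, 2 * n_pairs))
    fc = np.ones(n_genes) if logfc is None else 2.0 ** np.asarray(logfc, dtype=float)
    cols, patients, cond = [], [], []
    means = np.empty((n_genes, 2 * n_pairs))
    for p in range(n_pairs):
        for k, c in enumerate(("tumor", "normal")):
            j = 2 * p + k
            cols.append(f"P{p + 1:02d}_{'T' if c == 'tumor' else 'N'}")
            patients.append(f"P{p + 1:02d}")
            cond.append(c)
            m = mu * pat[p] * sf[j]
            if c == "tumor":
                m = m * fc
            means[:, j] = m
    r = 1.0 / dispersion
    counts = pd.DataFrame(
        rng.negative_binomial(r, r / (r + means)),
        index=[f"G{i + 1:04d}" for i in range(n_genes)],
        columns=cols,
    )
    sheet = pd.DataFrame({"sample": cols, "patient": patients, "condition": cond})
    return counts, sheet
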