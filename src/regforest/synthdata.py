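"""Synthetic multi-omics cohort with planted regulatory ground truth.

Generates a tumor cohort in which gene expression is driven by a known
combination of copy-number dosage, promoter methylation, transcription-factor
and miRNA regulation, so the full modeling pipeline can be validated against
planted truth: expression for gene g is

    baseline_g + cnv_effect * CNV[g, s] + meth_effect * Beta[probe_g, s]
               + sum_r beta_{r,g} * f_r(regulator_expr[r, s]) + N(0, noise_sd)

where beta_{r,g} is nonzero only for planted (active regulator, target) pairs,
miRNA effects are strictly negative (repression), and a configurable fraction
of TF effects passes through a hinge nonlinearity max(0, x - median) to
exercise the forest's nonlinear capacity. Companion generators emit paired
tumor/normal negative-binomial counts with planted log fold changes, promoter
sequences with planted motif sites, knockdown-style p-value tables, and
survival times tied to a planted driver regulator.

All generators are reproducible: a single master seed feeds fixed per-stage
substreams, so regenerating any piece with the same seed is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from regforest.motifscan import BindingMatrix, MotifPFM

# fixed substream keys: one master seed, per-generator streams by offset
_STREAM_COHORT = 11
_STREAM_COUNTS = 13
_STREAM_KNOCKDOWN = 17
_STREAM_SURVIVAL = 19
_STREAM_PROMOTERS = 23


@dataclass(frozen=True)
class SynthConfig:
    """Cohort dimensions and planted effect sizes (log2 expression scale)."""

    n_genes: int = 200
    n_samples: int = 150
    n_tfs: int = 40
    n_mirnas: int = 40
    n_active_tfs: int = 5
    n_active_mirnas: int = 3
    binding_density: float = 0.10
    effect_size_range: tuple[float, float] = (0.8, 1.5)
    cnv_effect: float = 0.5
    meth_effect: float = -2.0
    noise_sd: float = 0.5
    nb_dispersion: float = 0.2
    seed: int = 0
    n_targets_per_regulator: int = 30
    hinge_fraction: float = 0.3
    probes_per_gene: int = 3

    def validate(self) -> None:
        for name in ("n_genes", "n_samples", "n_tfs", "n_mirnas", "probes_per_gene"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_active_tfs > self.n_tfs:
            raise ValueError("n_active_tfs must not exceed n_tfs")
        if self.n_active_mirnas > self.n_mirnas:
            raise ValueError("n_active_mirnas must not exceed n_mirnas")
        if not 0 <= self.binding_density < 1:
            raise ValueError("binding_density must lie in [0, 1)")
        lo, hi = self.effect_size_range
        if lo < 0 or hi < lo:
            raise ValueError("effect_size_range must be a nonnegative interval")
        if self.cnv_effect < 0:
            raise ValueError("cnv_effect must be nonnegative")
        if self.meth_effect > 0:
            raise ValueError("meth_effect must be nonpositive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.hinge_fraction <= 1:
            raise ValueError("hinge_fraction must be a probability")
        if self.n_targets_per_regulator > self.n_genes:
            raise ValueError("n_targets_per_regulator must not exceed n_genes")


@dataclass
class OmicsCohort:
    """Aligned multi-omics measurements; all matrices share the sample axis."""

    gene_expr: pd.DataFrame  # genes x samples, log2 scale
    tf_expr: pd.DataFrame  # TFs x samples
    mirna_expr: pd.DataFrame  # miRNAs x samples
    cnv: pd.DataFrame  # genes x samples, centered at 0
    meth_beta: pd.DataFrame  # probes x samples, in [0, 1]
    probe_gene_map: pd.Series  # probe id -> gene id
    sample_ids: list[str] = field(default_factory=list)
    paired_normal_ids: dict[str, str] | None = None

    def __post_init__(self):
        if not self.sample_ids:
            self.sample_ids = list(self.gene_expr.columns)
        for name in ("gene_expr", "tf_expr", "mirna_expr", "cnv", "meth_beta"):
            df = getattr(self, name)
            if list(df.columns) != self.sample_ids:
                raise ValueError(f"{name} sample axis out of order")
            if df.isna().any().any():
                raise ValueError(f"{name} contains missing values")
        b = self.meth_beta.to_numpy()
        if b.min() < 0 or b.max() > 1:
            raise ValueError("meth_beta entries must lie in [0, 1]")

    def probes_for(self, gene: str) -> list[str]:
        return sorted(self.probe_gene_map.index[self.probe_gene_map == gene])


@dataclass
class SyntheticTruth:
    """Planted ground truth backing a generated cohort."""

    active_tfs: set[str]
    active_mirnas: set[str]
    target_map: dict[str, dict[str, float]]  # regulator -> {gene: signed effect}
    cnv_effect_per_gene: pd.Series
    meth_effect_per_gene: pd.Series
    survival_driver: str
    planted_logfc: pd.Series
    baseline: pd.Series
    causal_probe: dict[str, str]  # gene -> the probe used in generation
    hinge_pairs: set[tuple[str, str]]  # (regulator, gene) via hinge nonlinearity

    def to_json(self, path) -> None:
        payload = {
            "active_tfs": sorted(self.active_tfs),
            "active_mirnas": sorted(self.active_mirnas),
            "target_map": {r: dict(sorted(t.items())) for r, t in sorted(self.target_map.items())},
            "cnv_effect_per_gene": self.cnv_effect_per_gene.to_dict(),
            "meth_effect_per_gene": self.meth_effect_per_gene.to_dict(),
            "survival_driver": self.survival_driver,
            "planted_logfc": self.planted_logfc.to_dict(),
            "baseline": self.baseline.to_dict(),
            "causal_probe": self.causal_probe,
            "hinge_pairs": sorted(map(list, self.hinge_pairs)),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _ids(prefix: str, n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _hinge(x: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, x - np.median(x))


def generate_cohort(
    config: SynthConfig,
) -> tuple[OmicsCohort, BindingMatrix, BindingMatrix, SyntheticTruth]:
    """Generate the cohort, TF/miRNA binding matrices and planted truth."""
    config.validate()
    rng = np.random.default_rng([_STREAM_COHORT, config.seed])

    genes = _ids("G", config.n_genes)
    samples = _ids("S", config.n_samples)
    tfs = _ids("TF", config.n_tfs)
    mirnas = _ids("MIR", config.n_mirnas)

    tf_expr = rng.normal(0.0, 1.0, (config.n_tfs, config.n_samples))
    mirna_expr = rng.normal(0.0, 1.0, (config.n_mirnas, config.n_samples))
    cnv = rng.normal(0.0, 0.5, (config.n_genes, config.n_samples))

    # methylation: probes_per_gene probes, one causal per gene; Beta-values are
    # logistic-transformed Gaussians so they stay in [0, 1]
    n_probes = config.n_genes * config.probes_per_gene
    latent = rng.normal(0.0, 1.0, (n_probes, config.n_samples))
    probe_offsets = rng.normal(0.0, 0.5, n_probes)
    beta = 1.0 / (1.0 + np.exp(-(1.5 * latent + probe_offsets[:, None])))
    probe_ids, probe_genes = [], []
    for g in genes:
        for j in range(config.probes_per_gene):
            probe_ids.append(f"{g}_p{j + 1}")
            probe_genes.append(g)
    causal_idx = rng.integers(0, config.probes_per_gene, config.n_genes)
    causal_probe = {g: f"{g}_p{causal_idx[i] + 1}" for i, g in enumerate(genes)}
    causal_rows = np.arange(config.n_genes) * config.probes_per_gene + causal_idx
    beta_causal = beta[causal_rows]

    # binding incidence: iid Bernoulli, then planted pairs forced to 1
    tf_bits = (rng.random((config.n_tfs, config.n_genes)) < config.binding_density).astype(np.int8)
    mirna_bits = (rng.random((config.n_mirnas, config.n_genes)) < config.binding_density).astype(np.int8)

    active_tfs = sorted(rng.choice(tfs, config.n_active_tfs, replace=False).tolist())
    active_mirnas = sorted(rng.choice(mirnas, config.n_active_mirnas, replace=False).tolist())

    lo, hi = config.effect_size_range
    target_map: dict[str, dict[str, float]] = {}
    hinge_pairs: set[tuple[str, str]] = set()
    contrib = np.zeros((config.n_genes, config.n_samples))
    gene_index = {g: i for i, g in enumerate(genes)}

    for r in active_tfs:
        ri = tfs.index(r)
        targets = sorted(rng.choice(genes, config.n_targets_per_regulator, replace=False).tolist())
        effects: dict[str, float] = {}
        for g in targets:
            mag = rng.uniform(lo, hi)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            eff = sign * mag
            effects[g] = eff
            tf_bits[ri, gene_index[g]] = 1
            x = tf_expr[ri]
            if rng.random() < config.hinge_fraction:
                hinge_pairs.add((r, g))
                contrib[gene_index[g]] += eff * _hinge(x)
            else:
                contrib[gene_index[g]] += eff * x
        target_map[r] = effects

    for r in active_mirnas:
        ri = mirnas.index(r)
        targets = sorted(rng.choice(genes, config.n_targets_per_regulator, replace=False).tolist())
        effects = {}
        for g in targets:
            eff = -rng.uniform(lo, hi)  # miRNAs repress
            effects[g] = eff
            mirna_bits[ri, gene_index[g]] = 1
            contrib[gene_index[g]] += eff * mirna_expr[ri]
        target_map[r] = effects

    baseline = rng.normal(0.0, 1.0, config.n_genes)
    noise = rng.normal(0.0, 1.0, (config.n_genes, config.n_samples)) * config.noise_sd
    gene_expr = (
        baseline[:, None]
        + config.cnv_effect * cnv
        + config.meth_effect * beta_causal
        + contrib
        + noise
    )

    # planted tumor-vs-normal log2 fold changes for the paired-count generator:
    # ~15% of genes DE with |logFC| in [1.2, 3]
    n_de = max(1, int(round(0.15 * config.n_genes)))
    de_idx = rng.choice(config.n_genes, n_de, replace=False)
    logfc = np.zeros(config.n_genes)
    logfc[de_idx] = rng.uniform(1.2, 3.0, n_de) * np.where(rng.random(n_de) < 0.5, 1.0, -1.0)

    cohort = OmicsCohort(
        gene_expr=pd.DataFrame(gene_expr, index=genes, columns=samples),
        tf_expr=pd.DataFrame(tf_expr, index=tfs, columns=samples),
        mirna_expr=pd.DataFrame(mirna_expr, index=mirnas, columns=samples),
        cnv=pd.DataFrame(cnv, index=genes, columns=samples),
        meth_beta=pd.DataFrame(beta, index=probe_ids, columns=samples),
        probe_gene_map=pd.Series(probe_genes, index=probe_ids, name="gene_id"),
    )
    truth = SyntheticTruth(
        active_tfs=set(active_tfs),
        active_mirnas=set(active_mirnas),
        target_map=target_map,
        cnv_effect_per_gene=pd.Series(config.cnv_effect, index=genes),
        meth_effect_per_gene=pd.Series(config.meth_effect, index=genes),
        survival_driver=active_tfs[0],
        planted_logfc=pd.Series(logfc, index=genes),
        baseline=pd.Series(baseline, index=genes),
        causal_probe=causal_probe,
        hinge_pairs=hinge_pairs,
    )
    tf_binding = BindingMatrix(tfs, genes, tf_bits)
    mirna_binding = BindingMatrix(mirnas, genes, mirna_bits)

    # planted pairs must carry binding bit 1
    for r, targets in target_map.items():
        bm = tf_binding if r in truth.active_tfs else mirna_binding
        ri = bm.regulators.index(r)
        assert all(bm.bits[ri, gene_index[g]] == 1 for g in targets)

    return cohort, tf_binding, mirna_binding, truth


def deterministic_expression(
    cohort: OmicsCohort, truth: SyntheticTruth, config: SynthConfig
) -> pd.DataFrame:
    """The noise-free part of the generative equation, reconstructed from the
    cohort and planted truth (used to verify generator correctness)."""
    genes = list(cohort.gene_expr.index)
    out = pd.DataFrame(0.0, index=genes, columns=cohort.sample_ids)
    out += truth.baseline.to_numpy()[:, None]
    out += config.cnv_effect * cohort.cnv.to_numpy()
    causal = cohort.meth_beta.loc[[truth.causal_probe[g] for g in genes]].to_numpy()
    out += config.meth_effect * causal
    for r, targets in truth.target_map.items():
        src = cohort.tf_expr if r in truth.active_tfs else cohort.mirna_expr
        x = src.loc[r].to_numpy()
        for g, eff in targets.items():
            v = _hinge(x) if (r, g) in truth.hinge_pairs else x
            out.loc[g] += eff * v
    return out


def generate_paired_counts(
    config: SynthConfig,
    truth: SyntheticTruth,
    n_pairs: int = 30,
    size_factors: np.ndarray | None = None,
    mean_log_mu: float = 6.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired tumor/normal NB count matrix with planted log2 fold changes.

    Returns (counts genes x 2*n_pairs, sample sheet with sample/patient/
    condition columns). Tumor column means are shifted by 2**planted_logfc;
    per-sample library-size factors default to lognormal draws, multiplied by
    a lognormal per-patient baseline shared within each pair.
    """
    config.validate()
    rng = np.random.default_rng([_STREAM_COUNTS, config.seed])
    genes = list(truth.planted_logfc.index)
    mu = np.exp(rng.normal(mean_log_mu, 1.0, len(genes)))
    if size_factors is None:
        size_factors = np.exp(rng.normal(0.0, 0.25, 2 * n_pairs))
    else:
        size_factors = np.asarray(size_factors, dtype=float)
        if size_factors.shape != (2 * n_pairs,):
            raise ValueError("size_factors must have one entry per column")
    patient_base = np.exp(rng.normal(0.0, 0.2, n_pairs))
    fc = 2.0 ** truth.planted_logfc.to_numpy()

    cols, patients, conditions = [], [], []
    means = np.empty((len(genes), 2 * n_pairs))
    for p in range(n_pairs):
        for k, cond in enumerate(("tumor", "normal")):
            j = 2 * p + k
            cols.append(f"P{p + 1:02d}_{'T' if cond == 'tumor' else 'N'}")
            patients.append(f"P{p + 1:02d}")
            conditions.append(cond)
            m = mu * patient_base[p] * size_factors[j]
            if cond == "tumor":
                m = m * fc
            means[:, j] = m
    r_nb = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r_nb, r_nb / (r_nb + means))
    counts_df = pd.DataFrame(counts, index=genes, columns=cols)
    sheet = pd.DataFrame({"sample": cols, "patient": patients, "condition": conditions})
    return counts_df, sheet


def generate_knockdown(
    truth: SyntheticTruth,
    regulator: str,
    n_genes: int,
    seed: int,
    target_beta_a: float = 0.1,
) -> pd.Series:
    """Emulated regulator-knockdown differential-expression p-values.

    Planted targets of ``regulator`` draw p ~ Beta(target_beta_a, 1)
    (concentrated near 0); all other genes draw p ~ Uniform(0, 1).
    """
    if regulator not in truth.active_tfs | truth.active_mirnas:
        raise KeyError(f"regulator {regulator!r} is not an active planted regulator")
    rng = np.random.default_rng([_STREAM_KNOCKDOWN, seed])
    genes = _ids("G", n_genes)
    p = rng.uniform(0.0, 1.0, n_genes)
    targets = set(truth.target_map.get(regulator, {}))
    mask = np.array([g in targets for g in genes])
    if mask.any():
        p[mask] = rng.beta(target_beta_a, 1.0, int(mask.sum()))
    return pd.Series(p, index=genes, name="p_value")


def generate_survival(
    cohort: OmicsCohort,
    truth: SyntheticTruth,
    hazard_ratio: float,
    censor_rate: float,
    seed: int,
    baseline_hazard: float = 0.02,
) -> pd.DataFrame:
    """Exponential survival times with the planted driver modulating hazard.

    Samples whose driver expression exceeds its median carry hazard
    ``baseline_hazard * hazard_ratio``; censored samples (independent
    Bernoulli(censor_rate)) report a uniform time before their event.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not 0 <= censor_rate <= 1:
        raise ValueError("censor_rate must be a probability")
    driver = truth.survival_driver
    source = cohort.tf_expr if driver in cohort.tf_expr.index else cohort.mirna_expr
    expr = source.loc[driver]
    rng = np.random.default_rng([_STREAM_SURVIVAL, seed])
    high = expr.to_numpy() > np.median(expr.to_numpy())
    rate = baseline_hazard * np.where(high, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / rate)
    censored = rng.random(len(expr)) < censor_rate
    time = np.where(censored, rng.uniform(0.0, t_event), t_event)
    time = np.maximum(time, 1e-9)
    return pd.DataFrame(
        {"sample": cohort.sample_ids, "time": time, "event": (~censored).astype(int)}
    )


def generate_promoters_with_sites(
    pfms: Sequence[MotifPFM],
    n_genes: int,
    planted_sites: Mapping[str, Sequence[str]],
    seed: int,
    promoter_length: int = 4000,
    background: np.ndarray | None = None,
) -> tuple[dict[str, str], BindingMatrix, dict[tuple[str, str], int]]:
    """Background promoters with consensus motif sites planted at recorded
    offsets. Returns (promoters, expected binding matrix, offsets keyed by
    (motif, gene)). Background hits beyond the planted ones are possible at
    the scanner's false-positive rate."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    rng = np.random.default_rng([_STREAM_PROMOTERS, seed])
    genes = _ids("G", n_genes)
    pfm_by_id = {p.motif_id: p for p in pfms}
    bases = np.array(list("ACGT"))
    promoters: dict[str, str] = {}
    offsets: dict[tuple[str, str], int] = {}
    bits = np.zeros((len(pfms), n_genes), dtype=np.int8)
    motif_order = [p.motif_id for p in pfms]
    for gi, g in enumerate(genes):
        seq = rng.choice(bases, promoter_length, p=bg)
        for motif_id in planted_sites.get(g, []):
            pfm = pfm_by_id[motif_id]
            if pfm.length > promoter_length:
                raise ValueError(
                    f"site {motif_id} (length {pfm.length}) longer than promoter"
                )
            off = int(rng.integers(0, promoter_length - pfm.length + 1))
            seq[off : off + pfm.length] = list(pfm.consensus())
            offsets[(motif_id, g)] = off
            bits[motif_order.index(motif_id), gi] = 1
        promoters[g] = "".join(seq)
    return promoters, BindingMatrix(motif_order, genes, bits), offsets


def random_pfms(
    n: int, length_range: tuple[int, int] = (6, 12), seed: int = 0, sharpness: float = 8.0
) -> list[MotifPFM]:
    """Random informative PFMs (Dirichlet columns with one favored base)."""
    rng = np.random.default_rng([29, seed])
    out = []
    for i in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        cols = []
        for _ in range(L):
            alpha = np.ones(4)
            alpha[rng.integers(0, 4)] = sharpness
            cols.append(rng.dirichlet(alpha) * 100.0)
        out.append(MotifPFM(f"M{i + 1:03d}", np.array(cols).T, name=f"synthetic-{i + 1}"))
    return out


# ---------------------------------------------------------------------------
# TSV writers (first column = feature id, header = sample ids)

def write_matrix(df: pd.DataFrame, path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def write_cohort(
    cohort: OmicsCohort,
    tf_binding: BindingMatrix,
    mirna_binding: BindingMatrix,
    truth: SyntheticTruth,
    outdir,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.gene_expr, outdir / "gene_expr.tsv", "gene_id")
    write_matrix(cohort.tf_expr, outdir / "tf_expr.tsv", "tf_id")
    write_matrix(cohort.mirna_expr, outdir / "mirna_expr.tsv", "mirna_id")
    write_matrix(cohort.cnv, outdir / "cnv.tsv", "gene_id")
    write_matrix(cohort.meth_beta, outdir / "meth_beta.tsv", "probe_id")
    cohort.probe_gene_map.rename("gene_id").to_csv(
        outdir / "probe_gene_map.tsv", sep="\t", index_label="probe_id"
    )
    write_matrix(tf_binding.to_frame(), outdir / "tf_binding.tsv", "tf_id")
    write_matrix(mirna_binding.to_frame(), outdir / "mirna_binding.tsv", "mirna_id")
    truth.to_json(outdir / "truth.json")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
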