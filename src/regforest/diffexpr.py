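"""Paired tumor/normal differential expression with a negative-binomial GLM.

A compact count-based DE pipeline: low-count filtering, TMM (trimmed mean of
M-values) normalization, moment-based dispersion estimation shrunk toward a
common value, and a per-gene NB log-linear likelihood-ratio test of the tumor
effect with patient fixed effects absorbing baseline differences between
patients. Benjamini-Hochberg FDR and fixed fold-change/FDR thresholds label
genes up / down / ns.

This is deliberately simpler than full empirical-Bayes count pipelines:
per-gene dispersions are Cox-Reid adjusted profile-likelihood estimates
shrunk toward their pooled mean with a fixed prior weight — no fitted
mean-dispersion trend and no empirical-Bayes moderation. The test itself is
a standard NB GLM LRT with library-size offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

DISPERSION_FLOOR = 1e-8


@dataclass
class NormFactors:
    """TMM scaling factors (geometric mean 1) and effective library sizes."""

    factors: pd.Series
    effective_library_size: pd.Series

    def __post_init__(self):
        logf = np.log(self.factors.to_numpy())
        if abs(logf.mean()) > 1e-9:
            raise ValueError("scaling factors must have geometric mean 1")


def filter_low_counts(
    counts: pd.DataFrame, min_reads: int = 4, max_low_fraction: float = 0.7
) -> list[str]:
    """Genes kept unless count < min_reads in more than max_low_fraction of
    samples (the miRNA variant uses min_reads=2)."""
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    low_frac = (arr < min_reads).mean(axis=1)
    return [g for g, f in zip(counts.index, low_frac) if f <= max_low_fraction]


def tmm_normalize(
    counts: pd.DataFrame, trim_m: float = 0.3, trim_a: float = 0.05
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization.

    The reference library is the one whose 75th count percentile (scaled by
    library size) is closest to the mean across libraries. For each library a
    weighted mean of log-ratios (M) is taken after two-sided trimming of the
    most extreme M and A values; weights are the usual asymptotic inverse
    variances. Factors are rescaled to geometric mean 1.
    """
    arr = counts.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    for j, s in enumerate(counts.columns):
        if lib[j] == 0:
            raise ValueError(f"sample {s} has all-zero counts")
    uq = np.array([np.quantile(arr[:, j] / lib[j], 0.75) for j in range(arr.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(arr.shape[1])
    yr, Nr = arr[:, ref], lib[ref]
    for j in range(arr.shape[1]):
        if j == ref:
            continue
        y, N = arr[:, j], lib[j]
        keep = (y > 0) & (yr > 0)
        if keep.sum() == 0:
            continue
        yk, yrk = y[keep], yr[keep]
        M = np.log2((yk / N) / (yrk / Nr))
        A = 0.5 * np.log2((yk / N) * (yrk / Nr))
        w = (N - yk) / (N * yk) + (Nr - yrk) / (Nr * yrk)
        n = len(M)
        lo_m, hi_m = np.floor(n * trim_m), np.ceil(n * (1 - trim_m))
        lo_a, hi_a = np.floor(n * trim_a), np.ceil(n * (1 - trim_a))
        rank_m = stats.rankdata(M, method="ordinal")
        rank_a = stats.rankdata(A, method="ordinal")
        sel = (rank_m > lo_m) & (rank_m <= hi_m) & (rank_a > lo_a) & (rank_a <= hi_a)
        if sel.sum() == 0 or w[sel].sum() == 0:
            continue
        factors[j] = 2.0 ** (np.sum(M[sel] / w[sel]) / np.sum(1.0 / w[sel]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    fs = pd.Series(factors, index=counts.columns, name="factor")
    eff = pd.Series(lib * factors, index=counts.columns, name="effective_library_size")
    return NormFactors(fs, eff)


def _design_matrices(sample_sheet: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Full (patient dummies + tumor indicator) and reduced (patient only)
    design matrices, in the sheet's sample order."""
    required = {"sample", "patient", "condition"}
    if not required.issubset(sample_sheet.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    cond = sample_sheet["condition"].str.lower()
    if not set(cond) <= {"tumor", "normal"}:
        raise ValueError("condition must be 'tumor' or 'normal'")
    patients = pd.get_dummies(sample_sheet["patient"], drop_first=True, dtype=float)
    intercept = np.ones((len(sample_sheet), 1))
    reduced = np.hstack([intercept, patients.to_numpy()])
    tumor = (cond == "tumor").to_numpy(dtype=float)[:, None]
    full = np.hstack([reduced, tumor])
    return full, reduced, list(sample_sheet["sample"])


_DISP_LOWER = 1e-6
_DISP_UPPER = 10.0


def estimate_dispersion(
    counts: pd.DataFrame,
    design: np.ndarray,
    norm: NormFactors,
    prior_weight: float = 0.25,
) -> pd.Series:
    """Per-gene NB dispersion by Cox-Reid adjusted profile likelihood,
    shrunk toward the common (pooled) estimate with a fixed prior weight.

    Each gene's dispersion maximizes the NB log-likelihood penalized by
    ``-0.5 * logdet(X' W X)`` (W = IRLS working weights), which removes the
    downward bias induced by estimating many patient nuisance coefficients.
    Genes whose optimum sits at the lower search bound (effectively Poisson)
    are recorded as 0; estimates are shrunk as
    ``(1 - prior_weight) * raw + prior_weight * mean(raw)`` and floored at
    1e-8.
    """
    from scipy import optimize

    X = np.asarray(design, dtype=float)
    offset = np.log(norm.effective_library_size.loc[counts.columns].to_numpy())
    raw = np.zeros(len(counts.index))
    for i, (_, y) in enumerate(counts.iterrows()):
        raw[i] = _cr_apl_dispersion(y.to_numpy(dtype=float), X, offset, optimize)
    common = float(np.mean(raw)) if len(raw) else 0.0
    shrunk = (1.0 - prior_weight) * raw + prior_weight * common
    return pd.Series(np.maximum(shrunk, DISPERSION_FLOOR), index=counts.index, name="dispersion")


def _cr_apl_dispersion(y, X, offset, optimize) -> float:
    """Maximize the Cox-Reid adjusted NB profile likelihood over dispersion."""

    def neg_apl(log_alpha: float) -> float:
        alpha = float(np.exp(log_alpha))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(
                    y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
                ).fit(maxiter=30)
            w = res.mu / (1.0 + alpha * res.mu)
            _, logdet = np.linalg.slogdet((X * w[:, None]).T @ X)
            return -(res.llf - 0.5 * logdet)
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            return np.inf

    res = optimize.minimize_scalar(
        neg_apl,
        bounds=(np.log(_DISP_LOWER), np.log(_DISP_UPPER)),
        method="bounded",
        options={"xatol": 0.05},
    )
    if not np.isfinite(res.fun):
        return 0.0
    alpha = float(np.exp(res.x))
    # optimum pinned at the lower bound means no evidence of overdispersion
    return 0.0 if alpha <= _DISP_LOWER * 1.2 else alpha


def nb_glm_lrt(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    norm: NormFactors,
    dispersion: pd.Series,
    maxiter: int = 50,
) -> pd.DataFrame:
    """Per-gene NB GLM likelihood-ratio test of the tumor coefficient.

    Full model: patient fixed effects + tumor indicator; reduced model:
    patient effects only; offsets are log effective library sizes. The LRT
    statistic is referred to chi-square(1); log_fc is the tumor coefficient
    converted to log2. Non-converging genes are flagged with p = 1.
    """
    X_full, X_red, order = _design_matrices(sample_sheet)
    counts = counts[order]
    offset = np.log(norm.effective_library_size.loc[order].to_numpy())
    rows = []
    for gene, y in counts.iterrows():
        yv = y.to_numpy(dtype=float)
        alpha = float(dispersion.loc[gene])
        fam = sm.families.NegativeBinomial(alpha=max(alpha, DISPERSION_FLOOR))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = sm.GLM(yv, X_full, family=fam, offset=offset).fit(maxiter=maxiter)
                red = sm.GLM(yv, X_red, family=fam, offset=offset).fit(maxiter=maxiter)
            if not (full.converged and red.converged):
                raise ValueError("no convergence")
            stat = max(0.0, 2.0 * (full.llf - red.llf))
            p = float(stats.chi2.sf(stat, 1))
            lfc = float(full.params[-1] / np.log(2.0))
            rows.append((gene, lfc, p, True))
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            warnings.warn(f"NB GLM did not converge for gene {gene}; p set to 1")
            rows.append((gene, 0.0, 1.0, False))
    return pd.DataFrame(
        rows, columns=["gene_id", "log_fc", "p_value", "converged"]
    ).set_index("gene_id")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    de: pd.DataFrame, lfc_thresh: float = 1.0, fdr_thresh: float = 0.05
) -> pd.DataFrame:
    """Attach FDR and up/down/ns status (strict inequalities on both
    thresholds) plus summary counts in ``.attrs``."""
    out = de.copy()
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    status = np.where(
        (out["log_fc"] > lfc_thresh) & (out["fdr"] < fdr_thresh),
        "up",
        np.where((out["log_fc"] < -lfc_thresh) & (out["fdr"] < fdr_thresh), "down", "ns"),
    )
    out["status"] = status
    out.attrs["n_up"] = int((out["status"] == "up").sum())
    out.attrs["n_down"] = int((out["status"] == "down").sum())
    return out


def de_pipeline(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    min_reads: int = 4,
    max_low_fraction: float = 0.7,
    lfc_thresh: float = 1.0,
    fdr_thresh: float = 0.05,
) -> pd.DataFrame:
    """Filter -> TMM -> dispersion -> NB LRT -> BH -> status labels."""
    kept = filter_low_counts(counts, min_reads, max_low_fraction)
    counts = counts.loc[kept]
    norm = tmm_normalize(counts)
    X_full, _, order = _design_matrices(sample_sheet)
    disp = estimate_dispersion(counts[order], X_full, norm)
    de = nb_glm_lrt(counts, sample_sheet, norm, disp)
    return call_differential(de, lfc_thresh, fdr_thresh)
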