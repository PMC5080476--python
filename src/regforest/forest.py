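"""Per-gene random-forest regression with out-of-bag evaluation.

Each gene's expression across samples is regressed on its feature table by a
forest of CART regression trees grown on bootstrap resamples, with ``mtry``
candidate features drawn at each node (delegated to scikit-learn's
DecisionTreeRegressor via ``max_features``). Out-of-bag predictions — each
sample predicted only by trees whose bootstrap excluded it — give an internal
held-out accuracy estimate (Spearman correlation with the measured
expression), and per-tree OOB permutation of each feature gives the classic
Breiman importance: the mean increase in OOB mean squared error when the
feature's values are shuffled. Importances are reported as raw (unscaled)
changes in MSE.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from regforest.features import GeneFeatureTable

_FEATURE_CLASSES = ("CNV", "METH", "TF", "miRNA")


@dataclass(frozen=True)
class ForestConfig:
    ntree: int = 100
    mtry: int = 70  # capped at the gene's feature count
    min_node_size: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.ntree < 1 or self.mtry < 1 or self.min_node_size < 1:
            raise ValueError("ntree, mtry and min_node_size must be positive")


@dataclass
class ForestFit:
    gene_id: str
    oob_prediction: np.ndarray  # NaN where a sample was never out-of-bag
    oob_spearman: float
    oob_flag: str  # '' | 'constant' | 'insufficient'
    importance: dict[str, float]
    feature_classes: dict[str, str]
    config: ForestConfig


def derive_gene_seed(master_seed: int, gene_id: str) -> int:
    """Stable per-gene seed (< 2**31) so per-gene fits are order-independent."""
    digest = hashlib.sha256(f"{master_seed}:{gene_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def fit_gene_forest(
    table: GeneFeatureTable,
    config: ForestConfig,
    importance_repeats: int = 5,
    compute_importance: bool = True,
) -> ForestFit:
    """Grow the forest, aggregate OOB predictions, and (optionally) compute
    per-tree OOB permutation importances."""
    config.validate()
    X = np.asarray(table.design, dtype=float)
    y = np.asarray(table.target, dtype=float)
    n, n_feat = X.shape
    if n < 10:
        raise ValueError(f"{table.gene_id}: need at least 10 samples")
    if n < 2 * config.min_node_size:
        raise ValueError(f"{table.gene_id}: fewer samples than 2 x min_node_size")
    mtry = min(config.mtry, n_feat)
    rng = np.random.default_rng(config.seed)

    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n, dtype=int)
    imp_sum = np.zeros(n_feat)
    trees_used = 0
    all_idx = np.arange(n)
    for _ in range(config.ntree):
        boot = rng.integers(0, n, n)
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=config.min_node_size,
            random_state=int(rng.integers(0, 2**31)),
        )
        tree.fit(X[boot], y[boot])
        oob = np.setdiff1d(all_idx, boot, assume_unique=False)
        if oob.size == 0:
            continue
        Xo = X[oob]
        yo = y[oob]
        if compute_importance and oob.size >= 2:
            # one predict call per tree: baseline block + one permuted block
            # per (feature, repeat)
            blocks = [Xo]
            for _r in range(importance_repeats):
                perm = rng.permutation(oob.size)
                for f in range(n_feat):
                    Xp = Xo.copy()
                    Xp[:, f] = Xo[perm, f]
                    blocks.append(Xp)
            preds = tree.predict(np.vstack(blocks))
            base_pred = preds[: oob.size]
            base_mse = np.mean((base_pred - yo) ** 2)
            rest = preds[oob.size :].reshape(importance_repeats, n_feat, oob.size)
            mse_perm = np.mean((rest - yo) ** 2, axis=2)  # repeats x features
            imp_sum += (mse_perm - base_mse).mean(axis=0)
            trees_used += 1
        else:
            base_pred = tree.predict(Xo)
        pred_sum[oob] += base_pred
        pred_cnt[oob] += 1

    oob_pred = np.full(n, np.nan)
    seen = pred_cnt > 0
    oob_pred[seen] = pred_sum[seen] / pred_cnt[seen]
    rho, flag = oob_spearman(oob_pred, y)
    importance = {}
    if compute_importance:
        denom = max(trees_used, 1)
        importance = {
            name: float(imp_sum[i] / denom) for i, name in enumerate(table.feature_names)
        }
    return ForestFit(
        gene_id=table.gene_id,
        oob_prediction=oob_pred,
        oob_spearman=rho,
        oob_flag=flag,
        importance=importance,
        feature_classes=dict(zip(table.feature_names, table.feature_classes)),
        config=config,
    )


def oob_spearman(oob_prediction: np.ndarray, target: np.ndarray) -> tuple[float, str]:
    """Spearman correlation over samples with defined OOB predictions.

    Returns (rho, flag); rho is 0 with flag 'constant' when either vector is
    constant, and NaN with flag 'insufficient' below 3 usable samples.
    """
    mask = ~np.isnan(np.asarray(oob_prediction, dtype=float))
    if mask.sum() < 3:
        return float("nan"), "insufficient"
    p = np.asarray(oob_prediction)[mask]
    t = np.asarray(target)[mask]
    if np.ptp(p) == 0 or np.ptp(t) == 0:
        return 0.0, "constant"
    return float(stats.spearmanr(p, t).statistic), ""


def oob_mse(fit: ForestFit, target: np.ndarray) -> float:
    mask = ~np.isnan(fit.oob_prediction)
    return float(np.mean((fit.oob_prediction[mask] - np.asarray(target)[mask]) ** 2))


def tune_hyperparameters(
    tables: Sequence[GeneFeatureTable],
    ntree_grid: Iterable[int],
    mtry_grid: Iterable[int],
    seed: int = 0,
    min_node_size: int = 5,
) -> tuple[int, int]:
    """Grid-search (mtry, ntree) minimizing mean OOB MSE over a gene sample;
    ties broken toward smaller ntree, then smaller mtry. Returns (mtry, ntree)."""
    grid = sorted((nt, mt) for nt in set(ntree_grid) for mt in set(mtry_grid))
    if not grid:
        raise ValueError("empty hyperparameter grid")
    best, best_mse = None, np.inf
    for nt, mt in grid:
        total = 0.0
        for table in tables:
            cfg = ForestConfig(
                ntree=nt,
                mtry=mt,
                min_node_size=min_node_size,
                seed=derive_gene_seed(seed, table.gene_id),
            )
            fit = fit_gene_forest(table, cfg, compute_importance=False)
            total += oob_mse(fit, table.target)
        mse = total / len(tables)
        if mse < best_mse:
            best, best_mse = (mt, nt), mse
    return best


def fit_cohort(
    tables: Sequence[GeneFeatureTable],
    config: ForestConfig,
    importance_repeats: int = 5,
    compute_importance: bool = True,
) -> list[ForestFit]:
    """Fit every gene with a seed derived from the master seed and gene id,
    so results are independent of gene order and subsetting."""
    fits = []
    for table in tables:
        cfg = ForestConfig(
            ntree=config.ntree,
            mtry=config.mtry,
            min_node_size=config.min_node_size,
            seed=derive_gene_seed(config.seed, table.gene_id),
        )
        fits.append(fit_gene_forest(table, cfg, importance_repeats, compute_importance))
    return fits


def ablation_evaluation(
    tables: Sequence[GeneFeatureTable],
    config: ForestConfig,
    classes: Sequence[str] = _FEATURE_CLASSES,
) -> dict[str, dict]:
    """Full-model vs leave-one-class-out OOB Spearman comparison.

    Each gene is fit with its derived seed for the full model and for each
    reduced model (same seed, fewer columns); per class the result carries the
    per-gene correlation vectors, their means, the mean drop, and a paired
    two-sided Wilcoxon signed-rank p-value (normal approximation with tie
    correction). A gene losing all features under an ablation contributes a
    correlation of 0 (flagged by NaN -> 0 substitution).
    """
    if len(tables) < 2:
        raise ValueError("ablation needs at least 2 genes")
    full_corr = []
    for table in tables:
        cfg = ForestConfig(
            config.ntree, config.mtry, config.min_node_size,
            derive_gene_seed(config.seed, table.gene_id),
        )
        fit = fit_gene_forest(table, cfg, compute_importance=False)
        full_corr.append(0.0 if np.isnan(fit.oob_spearman) else fit.oob_spearman)
    full_corr = np.array(full_corr)

    out: dict[str, dict] = {
        "full": {"mean_spearman": float(full_corr.mean()), "per_gene": full_corr}
    }
    for cls in classes:
        reduced_corr = []
        for i, table in enumerate(tables):
            reduced = table.drop_class(cls)
            if reduced is None:
                reduced_corr.append(0.0)
                continue
            if reduced.feature_names == table.feature_names:
                reduced_corr.append(full_corr[i])  # class absent: identical model
                continue
            cfg = ForestConfig(
                config.ntree, min(config.mtry, len(reduced.feature_names)),
                config.min_node_size, derive_gene_seed(config.seed, table.gene_id),
            )
            fit = fit_gene_forest(reduced, cfg, compute_importance=False)
            reduced_corr.append(0.0 if np.isnan(fit.oob_spearman) else fit.oob_spearman)
        reduced_corr = np.array(reduced_corr)
        diffs = full_corr - reduced_corr
        if np.allclose(diffs, 0.0):
            pval = 1.0
        else:
            pval = float(
                stats.wilcoxon(full_corr, reduced_corr, zero_method="wilcox", method="approx").pvalue
            )
        out[cls] = {
            "mean_spearman": float(reduced_corr.mean()),
            "mean_drop": float(full_corr.mean() - reduced_corr.mean()),
            "wilcoxon_p": pval,
            "per_gene": reduced_corr,
        }
    return out
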