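"""Key-regulator inference from importance ranks.

Within each gene's model, feature importances are converted to ranks (rank 1
= most predictive, ties averaged). Stacking these per-gene rank vectors gives
a genes x features rank matrix, missing where a feature was not part of a
gene's model. A feature's average rank across the genes where it appears is
the key-regulator statistic — small average rank means the feature is
consistently among the best predictors. Target sets are read off the same
matrix column-wise: the genes where a regulator achieves its best ranks are
its predicted targets, scored against an experimental list by hypergeometric
overlap of the two top-k sets.

Averaging is restricted to genes where the feature exists; support (number of
genes carrying the feature) is reported alongside, and features below a
minimum support are excluded from the ordering so one-gene features cannot
top the list by chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from regforest.forest import ForestFit


def importance_to_ranks(importances: Mapping[str, float]) -> dict[str, float]:
    """Fractional ranks of importances, rank 1 = largest; ties averaged."""
    names = list(importances)
    if not names:
        raise ValueError("no features to rank")
    vals = np.array([importances[n] for n in names], dtype=float)
    ranks = stats.rankdata(-vals, method="average")
    return dict(zip(names, ranks.astype(float)))


@dataclass
class ImportanceRankMatrix:
    """Genes x features table of within-gene importance ranks (NaN where the
    feature was absent from that gene's model)."""

    ranks: pd.DataFrame
    feature_classes: dict[str, str]

    @property
    def genes(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def features(self) -> list[str]:
        return list(self.ranks.columns)


def _feature_sort_key(feature: str, cls: str) -> tuple:
    order = {"CNV": 0, "METH": 1, "TF": 2, "miRNA": 3}
    return (order.get(cls, 4), feature)


def build_rank_matrix(fits: Sequence[ForestFit]) -> ImportanceRankMatrix:
    """Stack per-gene rank vectors; feature axis is the union over genes,
    ordered CNV, METH, TFs lexicographic, miRNAs lexicographic."""
    if not fits:
        raise ValueError("no fits")
    gene_ids = [f.gene_id for f in fits]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids in fits")
    classes: dict[str, str] = {}
    for f in fits:
        classes.update(f.feature_classes)
    features = sorted(classes, key=lambda x: _feature_sort_key(x, classes[x]))
    mat = pd.DataFrame(np.nan, index=gene_ids, columns=features)
    for f in fits:
        r = importance_to_ranks(f.importance)
        mat.loc[f.gene_id, list(r)] = list(r.values())
    return ImportanceRankMatrix(mat, classes)


def build_rank_matrix_from_long(
    importances: pd.DataFrame, classify=None
) -> ImportanceRankMatrix:
    """Rank matrix from a long-format table with columns gene_id, feature,
    importance (as written by the fit stage). ``classify`` maps a feature
    name to its class; by default CNV/METH are literal and regulator names
    starting with 'MIR' or 'miR' are miRNAs, everything else a TF."""
    if classify is None:
        def classify(name: str) -> str:
            if name in ("CNV", "METH"):
                return name
            return "miRNA" if name.upper().startswith("MIR") else "TF"

    classes: dict[str, str] = {}
    rows = {}
    for gene, grp in importances.groupby("gene_id", sort=True):
        imp = dict(zip(grp["feature"], grp["importance"]))
        rows[gene] = importance_to_ranks(imp)
        for f in imp:
            classes.setdefault(f, classify(f))
    feats = sorted(classes, key=lambda x: _feature_sort_key(x, classes[x]))
    mat = pd.DataFrame(np.nan, index=sorted(rows), columns=feats)
    for g, r in rows.items():
        mat.loc[g, list(r)] = list(r.values())
    return ImportanceRankMatrix(mat, classes)


@dataclass
class RegulatorRanking:
    """Features ordered by average rank (ascending); ties by feature id."""

    table: pd.DataFrame  # feature, class, avg_rank, support, included

    def ordering(self) -> list[str]:
        inc = self.table[self.table["included"]]
        return list(inc.index)


def average_feature_ranks(
    matrix: ImportanceRankMatrix, min_support: int = 10
) -> RegulatorRanking:
    """Average each feature's ranks over the genes where it is present.

    Features with support below ``min_support`` are reported but excluded
    from the ordering. Sorted ascending by average rank, ties by feature id.
    """
    if matrix.ranks.empty:
        raise ValueError("empty rank matrix")
    avg = matrix.ranks.mean(axis=0, skipna=True)
    support = matrix.ranks.notna().sum(axis=0)
    tbl = pd.DataFrame(
        {
            "class": [matrix.feature_classes[f] for f in matrix.features],
            "avg_rank": avg,
            "support": support.astype(int),
        },
        index=pd.Index(matrix.features, name="feature"),
    )
    tbl["included"] = tbl["support"] >= min_support
    tbl = tbl.sort_values(["avg_rank", "feature"], kind="stable")
    return RegulatorRanking(tbl)


@dataclass
class TargetSet:
    regulator: str
    ranked_genes: list[str]  # best rank first
    k: int


def infer_targets(matrix: ImportanceRankMatrix, feature: str, k: int = 500) -> TargetSet:
    """Genes where ``feature`` was a model feature, sorted by its rank
    ascending (ties by gene id); top min(k, available) returned."""
    if feature not in matrix.ranks.columns:
        raise KeyError(f"unknown feature {feature!r}")
    col = matrix.ranks[feature].dropna()
    order = sorted(col.index, key=lambda g: (col[g], g))
    return TargetSet(feature, order[: min(k, len(order))], k)


def target_overlap(
    predicted: TargetSet,
    experimental_pvalues: pd.Series,
    k: int = 500,
    universe: Iterable[str] | None = None,
) -> tuple[int, float]:
    """Overlap between the predicted top-k target set and the k genes with
    the smallest experimental p-values, with a hypergeometric tail p-value.

    The hypergeometric null draws |predicted| genes from the universe and
    counts how many land in the experimental set.
    """
    universe = set(universe) if universe is not None else set(experimental_pvalues.index)
    if len(universe) < k:
        raise ValueError("universe smaller than k")
    pred = [g for g in predicted.ranked_genes][:k]
    if not set(pred) <= universe:
        raise ValueError("predicted targets outside universe")
    pv = experimental_pvalues[experimental_pvalues.index.isin(universe)]
    exp_order = sorted(pv.index, key=lambda g: (pv[g], g))
    exp_set = set(exp_order[:k])
    overlap = len(exp_set & set(pred))
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), k, len(pred)))
    return overlap, p


def target_precision(predicted: TargetSet, truth_targets: Iterable[str], k: int | None = None) -> float:
    """Fraction of the top-k predicted targets that are planted targets."""
    top = predicted.ranked_genes if k is None else predicted.ranked_genes[:k]
    if not top:
        return 0.0
    truth = set(truth_targets)
    return sum(g in truth for g in top) / len(top)
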