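"""Per-gene design-matrix assembly.

Each modeled gene gets a samples x features table: its CNV profile, the
Beta-values of its most negatively expression-correlated methylation probe,
and the expression of every TF / miRNA whose binding bit for the gene is 1.
Feature columns are exact copies of the source rows — no scaling — since
forests split on order, not magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from regforest.motifscan import BindingMatrix
from regforest.synthdata import OmicsCohort

CLASS_CNV = "CNV"
CLASS_METH = "METH"
CLASS_TF = "TF"
CLASS_MIRNA = "miRNA"


@dataclass
class GeneFeatureTable:
    gene_id: str
    feature_names: list[str]
    feature_classes: list[str]  # parallel to feature_names
    design: np.ndarray  # samples x features
    target: np.ndarray  # expression across samples
    sample_ids: list[str]

    def __post_init__(self):
        if len(self.feature_names) < 1:
            raise ValueError(f"{self.gene_id}: at least one feature required")
        if self.design.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError(f"{self.gene_id}: design shape mismatch")
        if len(self.feature_classes) != len(self.feature_names):
            raise ValueError(f"{self.gene_id}: feature class annotation mismatch")

    def drop_class(self, cls: str) -> "GeneFeatureTable | None":
        """Leave-one-class-out copy; None when no features remain."""
        keep = [i for i, c in enumerate(self.feature_classes) if c != cls]
        if not keep:
            return None
        return GeneFeatureTable(
            self.gene_id,
            [self.feature_names[i] for i in keep],
            [self.feature_classes[i] for i in keep],
            self.design[:, keep],
            self.target,
            self.sample_ids,
        )


def select_methylation_probe(
    probe_betas: pd.DataFrame,
    gene_expr: np.ndarray,
    candidate_probes: Sequence[str],
    method: str = "spearman",
) -> tuple[str, np.ndarray]:
    """Pick the candidate probe with the largest negative expression
    correlation (ties by lexicographic probe id)."""
    if len(candidate_probes) == 0:
        raise ValueError("no candidate probes")
    candidates = sorted(candidate_probes)
    expr = np.asarray(gene_expr, dtype=float)
    if np.ptp(expr) == 0:
        warnings.warn("zero-variance expression; methylation correlation undefined")
        return candidates[0], probe_betas.loc[candidates[0]].to_numpy()
    best_probe, best_corr = None, np.inf
    for probe in candidates:
        beta = probe_betas.loc[probe].to_numpy(dtype=float)
        if np.ptp(beta) == 0:
            corr = 0.0
        elif method == "spearman":
            corr = stats.spearmanr(beta, expr).statistic
        elif method == "pearson":
            corr = stats.pearsonr(beta, expr).statistic
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        if np.isnan(corr):
            corr = 0.0
        if corr < best_corr:
            best_probe, best_corr = probe, corr
    return best_probe, probe_betas.loc[best_probe].to_numpy()


def assemble_gene_features(
    gene_id: str,
    cohort: OmicsCohort,
    tf_binding: BindingMatrix,
    mirna_binding: BindingMatrix,
    probe_method: str = "spearman",
) -> GeneFeatureTable:
    """Build the design matrix for one gene: CNV, METH, then the expression
    of each bound TF and miRNA (binding bit 1), in binding-matrix order."""
    if gene_id not in cohort.cnv.index:
        raise KeyError(f"gene {gene_id} missing from CNV matrix")
    probes = cohort.probes_for(gene_id)
    if not probes:
        raise KeyError(f"gene {gene_id} has no methylation probes")
    target = cohort.gene_expr.loc[gene_id].to_numpy(dtype=float)
    _, meth = select_methylation_probe(cohort.meth_beta, target, probes, probe_method)

    names = [CLASS_CNV, CLASS_METH]
    classes = [CLASS_CNV, CLASS_METH]
    cols = [cohort.cnv.loc[gene_id].to_numpy(dtype=float), meth]
    for binding, source, cls in (
        (tf_binding, cohort.tf_expr, CLASS_TF),
        (mirna_binding, cohort.mirna_expr, CLASS_MIRNA),
    ):
        gi = binding.genes.index(gene_id)
        for ri, reg in enumerate(binding.regulators):
            if binding.bits[ri, gi]:
                names.append(reg)
                classes.append(cls)
                cols.append(source.loc[reg].to_numpy(dtype=float))
    return GeneFeatureTable(
        gene_id, names, classes, np.column_stack(cols), target, list(cohort.sample_ids)
    )


def filter_model_genes(
    de_genes: Iterable[str],
    cohort: OmicsCohort,
    tf_binding: BindingMatrix,
    mirna_binding: BindingMatrix,
) -> list[str]:
    """Genes modeled downstream: differentially expressed, with CNV data,
    at least one methylation probe, and at least one TF or miRNA site."""
    tf_any = tf_binding.to_frame().sum(axis=0) > 0
    mir_any = mirna_binding.to_frame().sum(axis=0) > 0
    probes_per_gene = cohort.probe_gene_map.value_counts()
    out = []
    for g in de_genes:
        if g not in cohort.cnv.index or g not in cohort.gene_expr.index:
            continue
        if probes_per_gene.get(g, 0) < 1:
            continue
        if not (tf_any.get(g, False) or mir_any.get(g, False)):
            continue
        out.append(g)
    return out
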