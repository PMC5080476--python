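"""End-to-end orchestration: synth -> DE -> features -> forest -> regulators
-> survival, under one config and one master seed, with a run manifest.

Every stage writes TSV/JSON outputs under the run directory; the manifest
records the config, the master seed and a SHA-256 checksum per output file,
so reruns with an identical config are byte-identical and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from regforest import diffexpr, features, forest, regulators, survival, synthdata

log = logging.getLogger("regforest")


@dataclass
class RunConfig:
    """All stage parameters plus the master seed.

    Defaults follow the modeled study settings: low-count filter (<4 reads in
    >70% of samples), |log2FC| > 1 and FDR < 0.05 for DE, motif p < 1e-4,
    promoter flank 2000, mtry 70 / ntree 100, top-K 500.
    """

    seed: int = 0
    outdir: str = "regforest_run"
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    n_pairs: int = 30
    min_reads: int = 4
    max_low_fraction: float = 0.7
    lfc_thresh: float = 1.0
    fdr_thresh: float = 0.05
    motif_p_thresh: float = 1e-4
    promoter_flank: int = 2000
    mtry: int = 70
    ntree: int = 100
    min_node_size: int = 5
    importance_repeats: int = 5
    top_k: int = 500
    min_support: int = 10
    hazard_ratio: float = 3.0
    censor_rate: float = 0.2
    use_de_filter: bool = True
    stages: tuple = ("synth", "de", "features", "fit", "regulators", "survival")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def synth_config(self) -> synthdata.SynthConfig:
        return synthdata.SynthConfig(seed=self.seed, **self.synth)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the enabled stages in order; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = list(config.stages)
    written: list[Path] = []

    scfg = config.synth_config()
    if "synth" not in enabled:
        raise ValueError("stage 'synth' is required to seed the run (downstream stages read its outputs)")
    log.info("stage synth: %d genes x %d samples", scfg.n_genes, scfg.n_samples)
    cohort, tf_b, mir_b, truth = synthdata.generate_cohort(scfg)
    synthdata.write_cohort(cohort, tf_b, mir_b, truth, outdir)
    counts, sheet = synthdata.generate_paired_counts(scfg, truth, n_pairs=config.n_pairs)
    synthdata.write_matrix(counts, outdir / "paired_counts.tsv", "gene_id")
    sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    surv_table = synthdata.generate_survival(
        cohort, truth, config.hazard_ratio, config.censor_rate, seed=scfg.seed
    )
    surv_table.to_csv(outdir / "survival.tsv", sep="\t", index=False)
    written += [
        outdir / n
        for n in (
            "gene_expr.tsv", "tf_expr.tsv", "mirna_expr.tsv", "cnv.tsv",
            "meth_beta.tsv", "probe_gene_map.tsv", "tf_binding.tsv",
            "mirna_binding.tsv", "truth.json", "paired_counts.tsv",
            "sample_sheet.tsv", "survival.tsv",
        )
    ]

    de_genes = list(cohort.gene_expr.index)
    if "de" in enabled:
        log.info("stage de: %d genes, %d pairs", counts.shape[0], config.n_pairs)
        de = diffexpr.de_pipeline(
            counts, sheet, config.min_reads, config.max_low_fraction,
            config.lfc_thresh, config.fdr_thresh,
        )
        de.to_csv(outdir / "de_table.tsv", sep="\t")
        written.append(outdir / "de_table.tsv")
        if config.use_de_filter:
            de_genes = list(de.index[de["status"] != "ns"])
    elif config.use_de_filter:
        raise ValueError("stage 'features' needs the DE gene list; enable stage 'de'")

    fits = None
    if "fit" in enabled or "features" in enabled:
        model_genes = features.filter_model_genes(de_genes, cohort, tf_b, mir_b)
        if not model_genes:
            raise ValueError("no genes pass the modeling filters")
        log.info("stage features/fit: %d modeled genes", len(model_genes))
        tables = [
            features.assemble_gene_features(g, cohort, tf_b, mir_b) for g in model_genes
        ]
        fcfg = forest.ForestConfig(config.ntree, config.mtry, config.min_node_size, scfg.seed)
        fits = forest.fit_cohort(tables, fcfg, config.importance_repeats)
        summary = pd.DataFrame(
            {
                "gene_id": [f.gene_id for f in fits],
                "oob_spearman": [f.oob_spearman for f in fits],
                "n_features": [len(f.importance) for f in fits],
            }
        )
        summary.to_csv(outdir / "fit_summary.tsv", sep="\t", index=False)
        rows = [
            (f.gene_id, name, imp)
            for f in fits
            for name, imp in sorted(f.importance.items())
        ]
        pd.DataFrame(rows, columns=["gene_id", "feature", "importance"]).to_csv(
            outdir / "importance.tsv", sep="\t", index=False
        )
        written += [outdir / "fit_summary.tsv", outdir / "importance.tsv"]

    if "regulators" in enabled:
        if fits is None:
            raise ValueError("stage 'regulators' needs forest fits; enable stage 'fit'")
        matrix = regulators.build_rank_matrix(fits)
        ranking = regulators.average_feature_ranks(matrix, config.min_support)
        ranking.table.to_csv(outdir / "regulator_ranking.tsv", sep="\t")
        written.append(outdir / "regulator_ranking.tsv")
        overlap_rows = []
        for reg in sorted(truth.active_tfs | truth.active_mirnas):
            if reg not in matrix.ranks.columns:
                continue
            targets = regulators.infer_targets(matrix, reg, config.top_k)
            kd = synthdata.generate_knockdown(truth, reg, scfg.n_genes, seed=scfg.seed)
            k_eff = min(config.top_k, len(targets.ranked_genes), len(kd))
            ov, p = regulators.target_overlap(targets, kd, k=k_eff, universe=set(kd.index))
            overlap_rows.append((reg, k_eff, ov, p))
            pd.Series(targets.ranked_genes, name="gene_id").to_csv(
                outdir / f"targets_{reg}.tsv", sep="\t", index=False
            )
            written.append(outdir / f"targets_{reg}.tsv")
        pd.DataFrame(
            overlap_rows, columns=["regulator", "k", "overlap", "hypergeom_p"]
        ).to_csv(outdir / "target_overlap.tsv", sep="\t", index=False)
        written.append(outdir / "target_overlap.tsv")

    if "survival" in enabled:
        driver = truth.survival_driver
        expr = cohort.tf_expr.loc[driver]
        res = survival.driver_survival_analysis(expr, surv_table)
        pd.DataFrame(
            [
                {
                    "driver": driver,
                    "chi_square": res["chi_square"],
                    "p_value": res["p_value"],
                    "n_high": res["n_high"],
                    "n_low": res["n_low"],
                }
            ]
        ).to_csv(outdir / "survival_test.tsv", sep="\t", index=False)
        written.append(outdir / "survival_test.tsv")

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "seed": config.seed,
        "outputs": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir
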