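"""Generator correctness: determinism, planted structure, distributional
contracts of the synthetic cohort, counts, knockdown, survival and promoter
generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regforest import synthdata as sd


class TestGenerateCohort:
    def test_same_seed_is_bit_identical_different_seed_is_not(self, small_config):
        c1, t1, m1, _ = sd.generate_cohort(small_config)
        c2, t2, m2, _ = sd.generate_cohort(small_config)
        for a, b in [
            (c1.gene_expr, c2.gene_expr),
            (c1.cnv, c2.cnv),
            (c1.meth_beta, c2.meth_beta),
            (c1.tf_expr, c2.tf_expr),
            (c1.mirna_expr, c2.mirna_expr),
        ]:
            assert np.array_equal(a.to_numpy(), b.to_numpy())
        assert np.array_equal(t1.bits, t2.bits)
        assert np.array_equal(m1.bits, m2.bits)
        other = sd.SynthConfig(**{**small_config.__dict__, "seed": small_config.seed + 1})
        c3, _, _, _ = sd.generate_cohort(other)
        assert not np.array_equal(c1.gene_expr.to_numpy(), c3.gene_expr.to_numpy())

    def test_planted_pairs_have_binding_bit_one(self, small_cohort):
        _, tfb, mirb, truth = small_cohort
        for reg, targets in truth.target_map.items():
            bm = tfb if reg in truth.active_tfs else mirb
            ri = bm.regulators.index(reg)
            for g in targets:
                assert bm.bits[ri, bm.genes.index(g)] == 1

    def test_beta_values_bounded_and_no_missing(self, small_cohort):
        cohort = small_cohort[0]
        b = cohort.meth_beta.to_numpy()
        assert b.min() >= 0 and b.max() <= 1
        assert not cohort.gene_expr.isna().any().any()

    def test_noiseless_cohort_reproduces_generative_equation(self):
        cfg = sd.SynthConfig(
            n_genes=30, n_samples=40, n_tfs=6, n_mirnas=6, n_active_tfs=2,
            n_active_mirnas=1, noise_sd=0.0, seed=3, n_targets_per_regulator=8,
        )
        cohort, _, _, truth = sd.generate_cohort(cfg)
        expected = sd.deterministic_expression(cohort, truth, cfg)
        resid = (cohort.gene_expr - expected).abs().to_numpy()
        assert resid.max() < 1e-10

    def test_noiseless_single_cause_equals_baseline_plus_tf(self):
        """With one active TF, unit effect, no CNV/methylation/hinge effects,
        a target's expression is exactly baseline + beta * TF expression."""
        cfg = sd.SynthConfig(
            n_genes=20, n_samples=30, n_tfs=4, n_mirnas=4, n_active_tfs=1,
            n_active_mirnas=1, noise_sd=0.0, cnv_effect=0.0, meth_effect=0.0,
            effect_size_range=(1.0, 1.0), hinge_fraction=0.0, seed=11,
            n_targets_per_regulator=5,
        )
        cohort, _, _, truth = sd.generate_cohort(cfg)
        (tf,) = truth.active_tfs
        (mirna,) = truth.active_mirnas
        mirna_targets = set(truth.target_map[mirna])
        x = cohort.tf_expr.loc[tf].to_numpy()
        for g, beta in truth.target_map[tf].items():
            if g in mirna_targets:
                continue
            assert abs(abs(beta) - 1.0) < 1e-12
            expected = truth.baseline[g] + beta * x
            np.testing.assert_allclose(cohort.gene_expr.loc[g].to_numpy(), expected, atol=1e-12)

    def test_zero_density_no_targets_gives_empty_incidence(self):
        cfg = sd.SynthConfig(
            n_genes=15, n_samples=20, n_tfs=5, n_mirnas=5, n_active_tfs=1,
            n_active_mirnas=1, binding_density=0.0, n_targets_per_regulator=0,
            seed=2,
        )
        _, tfb, mirb, _ = sd.generate_cohort(cfg)
        assert tfb.bits.sum() == 0 and mirb.bits.sum() == 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="n_active_tfs"):
            sd.SynthConfig(n_tfs=3, n_active_tfs=4).validate()
        with pytest.raises(ValueError, match="binding_density"):
            sd.SynthConfig(binding_density=1.5).validate()
        with pytest.raises(ValueError, match="nb_dispersion"):
            sd.SynthConfig(nb_dispersion=0.0).validate()


class TestPairedCounts:
    def test_null_logfc_means_indistinguishable(self, small_config):
        _, _, _, truth = sd.generate_cohort(small_config)
        truth.planted_logfc[:] = 0.0
        counts, sheet = sd.generate_paired_counts(small_config, truth, n_pairs=60)
        tumor = counts.loc[:, (sheet["condition"] == "tumor").to_numpy()]
        normal = counts.loc[:, (sheet["condition"] == "normal").to_numpy()]
        rejected = 0
        for g in counts.index:
            p = stats.ttest_ind(np.log1p(tumor.loc[g]), np.log1p(normal.loc[g])).pvalue
            rejected += p < 0.01
        assert rejected / len(counts.index) <= 0.05

    def test_planted_logfc_two_gives_fourfold_mean_ratio(self, small_config):
        _, _, _, truth = sd.generate_cohort(small_config)
        truth.planted_logfc[:] = 0.0
        gene = truth.planted_logfc.index[0]
        truth.planted_logfc[gene] = 2.0
        counts, sheet = sd.generate_paired_counts(
            small_config, truth, n_pairs=200, size_factors=np.ones(400)
        )
        tm = counts.loc[gene, (sheet["condition"] == "tumor").to_numpy()].mean()
        nm = counts.loc[gene, (sheet["condition"] == "normal").to_numpy()].mean()
        assert abs(np.log2(tm / nm) - 2.0) < 0.15

    def test_library_size_factor_doubles_column_total(self, small_config):
        _, _, _, truth = sd.generate_cohort(small_config)
        truth.planted_logfc[:] = 0.0
        ratios = []
        for rep in range(20):
            cfg = sd.SynthConfig(**{**small_config.__dict__, "seed": 100 + rep})
            sf = np.ones(4)
            sf[0] = 2.0
            counts, _ = sd.generate_paired_counts(cfg, truth, n_pairs=2, size_factors=sf)
            # columns 0 (factor 2) and 2 (factor 1) are tumor columns of
            # different patients; patient baselines average out over reps
            ratios.append(counts.iloc[:, 0].sum() / counts.iloc[:, 2].sum())
        assert abs(np.mean(ratios) - 2.0) < 0.25

    def test_empirical_logfc_converges_to_planted(self, small_config):
        """At 200 pairs the per-gene NB sampling error of the empirical log2
        fold change is ~0.065, so the planted values are recovered without
        bias: the average absolute deviation sits well inside +/-0.15 and the
        signed deviations center on zero."""
        _, _, _, truth = sd.generate_cohort(small_config)
        counts, sheet = sd.generate_paired_counts(
            small_config, truth, n_pairs=200, size_factors=np.ones(400)
        )
        tumor = counts.loc[:, (sheet["condition"] == "tumor").to_numpy()]
        normal = counts.loc[:, (sheet["condition"] == "normal").to_numpy()]
        de = truth.planted_logfc[truth.planted_logfc != 0]
        emp = np.log2(tumor.mean(axis=1) / normal.mean(axis=1))
        diffs = emp[de.index] - de
        assert diffs.abs().mean() < 0.15
        assert abs(diffs.mean()) < 0.1


class TestKnockdown:
    def test_no_targets_gives_uniform_pvalues(self, small_cohort):
        _, _, _, truth = small_cohort
        reg = sorted(truth.active_tfs)[0]
        truth = sd.SyntheticTruth(**{**truth.__dict__, "target_map": {reg: {}}})
        p = sd.generate_knockdown(truth, reg, n_genes=2000, seed=5)
        assert stats.kstest(p.to_numpy(), "uniform").pvalue > 0.01

    def test_strong_signal_targets_dominate_smallest_pvalues(self, small_cohort):
        _, _, _, truth = small_cohort
        reg = sorted(truth.active_tfs)[0]
        genes = [f"G{i + 1:04d}" for i in range(2000)]
        targets = {g: -1.0 for g in genes[:50]}
        truth = sd.SyntheticTruth(**{**truth.__dict__, "target_map": {reg: targets}})
        recovered = []
        for seed in range(20):
            p = sd.generate_knockdown(truth, reg, n_genes=2000, seed=seed, target_beta_a=0.01)
            top50 = set(p.nsmallest(50).index)
            recovered.append(len(top50 & set(targets)))
        assert np.median(recovered) >= 45

    def test_same_seed_identical_unknown_regulator_raises(self, small_cohort):
        _, _, _, truth = small_cohort
        reg = sorted(truth.active_tfs)[0]
        a = sd.generate_knockdown(truth, reg, 100, seed=9)
        b = sd.generate_knockdown(truth, reg, 100, seed=9)
        pd.testing.assert_series_equal(a, b)
        with pytest.raises(KeyError, match="NOPE"):
            sd.generate_knockdown(truth, "NOPE", 100, seed=9)


class TestSurvival:
    def test_zero_censoring_all_events(self, small_cohort):
        cohort, _, _, truth = small_cohort
        t = sd.generate_survival(cohort, truth, hazard_ratio=2.0, censor_rate=0.0, seed=4)
        assert (t["event"] == 1).all()
        assert (t["time"] > 0).all()

    def test_same_seed_identical(self, small_cohort):
        cohort, _, _, truth = small_cohort
        a = sd.generate_survival(cohort, truth, 3.0, 0.2, seed=8)
        b = sd.generate_survival(cohort, truth, 3.0, 0.2, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_censor_rate_fraction_censored(self, small_cohort):
        cohort, _, _, truth = small_cohort
        t = sd.generate_survival(cohort, truth, 1.0, censor_rate=0.3, seed=12)
        frac = 1.0 - t["event"].mean()
        assert 0.15 < frac < 0.45


class TestPromoters:
    def test_same_seed_identical_fasta(self):
        pfms = sd.random_pfms(3, seed=1)
        planted = {"G01": [pfms[0].motif_id]}
        p1, e1, o1 = sd.generate_promoters_with_sites(pfms, 5, planted, seed=6, promoter_length=500)
        p2, e2, o2 = sd.generate_promoters_with_sites(pfms, 5, planted, seed=6, promoter_length=500)
        assert p1 == p2 and o1 == o2
        assert np.array_equal(e1.bits, e2.bits)

    def test_planted_site_at_recorded_offset(self):
        pfms = sd.random_pfms(2, seed=2)
        pfm = pfms[0]
        planted = {"G02": [pfm.motif_id]}
        proms, expected, offsets = sd.generate_promoters_with_sites(
            pfms, 3, planted, seed=3, promoter_length=400
        )
        off = offsets[(pfm.motif_id, "G02")]
        assert proms["G02"][off : off + pfm.length] == pfm.consensus()
        assert expected.to_frame().loc[pfm.motif_id, "G02"] == 1
        assert expected.bits.sum() == 1

    def test_site_longer_than_promoter_raises(self):
        pfms = sd.random_pfms(1, length_range=(10, 10), seed=4)
        with pytest.raises(ValueError, match="longer than promoter"):
            sd.generate_promoters_with_sites(pfms, 2, {"G01": [pfms[0].motif_id]}, seed=1, promoter_length=8)
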