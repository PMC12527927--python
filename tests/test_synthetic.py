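"""Tests of the synthetic-cohort generator: LD structure, variance
decomposition of expression, disease model calibration, and the sampling
behaviour of the reference summary statistics."""

import numpy as np
import pandas as pd
import pytest

from gatekit.exceptions import (ConfigurationError, SimulationError,
                                StructuralError)
from gatekit.synthetic import (ArchitectureConfig, reference_summary_stats,
                               sample_architecture, simulate_case_control,
                               simulate_expression, simulate_genotypes,
                               simulate_study, trans_genetic_values)


def _small_cfg(**kw):
    defaults = dict(n_snps=60, n_blocks=20, n_core_genes=2, n_null_genes=1,
                    n_peripheral_loci_per_gene=3, seed=1)
    defaults.update(kw)
    return ArchitectureConfig(**defaults)


class TestGenotypes:
    def test_same_seed_gives_identical_matrices(self):
        cfg = _small_cfg()
        a = simulate_genotypes(cfg, n=200)
        b = simulate_genotypes(cfg, n=200)
        assert np.array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.snp_meta, b.snp_meta)

    def test_zero_block_rho_gives_independent_snps(self):
        cfg = _small_cfg(block_rho=0.0, seed=3)
        g = simulate_genotypes(cfg, n=5000)
        R = np.corrcoef(g.dosages[:, :20].astype(float), rowvar=False)
        off = R[~np.eye(20, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_high_block_rho_gives_calibrated_adjacent_correlation(self):
        """The copula is calibrated so dosage-scale adjacent correlation
        matches block_rho; at 0.9 it must land in [0.75, 0.95]."""
        cfg = _small_cfg(block_rho=0.9, seed=4)
        truth = sample_architecture(cfg)
        g = simulate_genotypes(cfg, truth, n=5000)
        start = 0
        rs = []
        for m in truth.block_sizes:
            d = g.dosages[:, start:start + m].astype(float)
            rs.extend(np.corrcoef(d[:, k], d[:, k + 1])[0, 1]
                      for k in range(m - 1))
            start += m
        rs = np.array(rs)
        assert rs.min() > 0.75 and rs.max() < 0.95
        assert abs(rs.mean() - 0.9) < 0.05

    def test_cross_block_independence(self):
        cfg = _small_cfg(block_rho=0.9, seed=5)
        truth = sample_architecture(cfg)
        g = simulate_genotypes(cfg, truth, n=5000)
        m0 = truth.block_sizes[0]
        r = np.corrcoef(g.dosages[:, m0 - 1].astype(float),
                        g.dosages[:, m0].astype(float))[0, 1]
        assert abs(r) < 0.05

    def test_empirical_maf_within_configured_range(self):
        cfg = _small_cfg(maf_range=(0.1, 0.3), seed=6)
        g = simulate_genotypes(cfg, n=5000)
        af = g.snp_meta["af"].to_numpy()
        maf = np.minimum(af, 1 - af)
        assert maf.min() > 0.1 - 0.03 and maf.max() < 0.3 + 0.03

    @pytest.mark.parametrize("bad", [
        dict(block_rho=1.0), dict(block_rho=-0.1),
        dict(maf_range=(0.01, 0.5)), dict(maf_range=(0.3, 0.6)),
        dict(h2_trans=0.7, h2_cis=0.4), dict(prevalence=0.0),
        dict(n_core_genes=0),
    ])
    def test_invalid_configuration_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            _small_cfg(**bad)


class TestExpression:
    def test_realized_trans_variance_matches_h2(self):
        cfg = ArchitectureConfig(seed=7, h2_trans=0.4)
        truth = sample_architecture(cfg)
        g = simulate_genotypes(cfg, truth, n=10000)
        expr = simulate_expression(g, truth)
        t = trans_genetic_values(g, truth)
        for gene in truth.genes[:4]:
            r = np.corrcoef(expr[gene.gene_id], t[gene.gene_id])[0, 1]
            assert 0.35 < r * r < 0.45

    def test_zero_h2_trans_gene_uncorrelated_with_trans_value(self):
        cfg = _small_cfg(seed=8)
        truth = sample_architecture(cfg)
        for g_ in truth.genes:
            g_.h2_trans = 0.0
        g = simulate_genotypes(cfg, truth, n=4000)
        expr = simulate_expression(g, truth)
        t = trans_genetic_values(g, truth)
        for gene in truth.genes:
            r = np.corrcoef(expr[gene.gene_id], t[gene.gene_id])[0, 1]
            assert abs(r) < 0.05

    def test_noiseless_pure_trans_expression_equals_genetic_value(self):
        cfg = _small_cfg(seed=9, h2_cis=0.0)
        truth = sample_architecture(cfg)
        for g_ in truth.genes:
            g_.h2_trans = 1.0
            g_.h2_cis = 0.0
        g = simulate_genotypes(cfg, truth, n=500)
        expr = simulate_expression(g, truth)
        t = trans_genetic_values(g, truth)
        for gene in truth.genes:
            np.testing.assert_allclose(expr[gene.gene_id], t[gene.gene_id],
                                       atol=1e-12)

    def test_mismatched_panel_rejected(self):
        cfg = _small_cfg(seed=10)
        truth = sample_architecture(cfg)
        other = simulate_genotypes(_small_cfg(seed=10, n_snps=36,
                                              n_blocks=12), n=100)
        with pytest.raises(StructuralError):
            simulate_expression(other, truth)


class TestCaseControl:
    def test_half_prevalence_no_effects_gives_half_case_fraction(self):
        cfg = _small_cfg(seed=12, core_log_or=0.0, prevalence=0.5,
                         hotspot_disease_log_or=0.0)
        truth = sample_architecture(cfg)
        g = simulate_genotypes(cfg, truth, n=6000)
        rng = np.random.default_rng(0)
        # status sampled over the whole pool: request a near-total split
        pheno = simulate_case_control(g, None, truth, 2700, 2700, rng=rng)
        assert len(pheno) == 5400
        assert pheno["STATUS"].sum() == 2700

    def test_exact_design_counts_and_columns(self):
        cfg = _small_cfg(seed=13)
        truth = sample_architecture(cfg)
        g = simulate_genotypes(cfg, truth, n=4000)
        pheno = simulate_case_control(g, None, truth, 300, 500,
                                      rng=np.random.default_rng(1))
        assert (pheno["STATUS"] == 1).sum() == 300
        assert (pheno["STATUS"] == 0).sum() == 500
        for col in ("IID", "SEX", "COHORT", "PC1", "PC10"):
            assert col in pheno.columns

    def test_unreachable_case_count_raises_with_guidance(self):
        cfg = _small_cfg(seed=14, prevalence=0.1)
        truth = sample_architecture(cfg)
        g = simulate_genotypes(cfg, truth, n=500)
        with pytest.raises(SimulationError, match="prevalence"):
            simulate_case_control(g, None, truth, 400, 100,
                                  rng=np.random.default_rng(2))

    def test_logistic_refit_recovers_core_log_or(self):
        """Disease simulated from a single core gene's standardized trans
        value with log OR 0.3 is recovered by a direct logistic refit."""
        import statsmodels.api as sm

        cfg = ArchitectureConfig(seed=15, n_core_genes=1, n_null_genes=0,
                                 core_log_or=0.3, prevalence=0.3,
                                 hotspot_disease_log_or=0.0,
                                 hotspot_trans_share=0.0,
                                 n_snps=120, n_blocks=40)
        truth = sample_architecture(cfg)
        g = simulate_genotypes(cfg, truth, n=10000)
        pheno = simulate_case_control(g, None, truth, 2500, 5500,
                                      rng=np.random.default_rng(3))
        sub = g.subset(pheno["IID"].tolist())
        t = trans_genetic_values(sub, truth).iloc[:, 0].to_numpy()
        X = sm.add_constant(t)
        fit = sm.Logit(pheno["STATUS"].to_numpy(), X).fit(disp=0)
        assert abs(fit.params[1] - 0.3) < 2 * fit.bse[1]


@pytest.fixture(scope="module")
def ref():
    cfg = ArchitectureConfig(seed=16)
    truth = sample_architecture(cfg)
    g = simulate_genotypes(cfg, truth, n=10000)
    expr = simulate_expression(g, truth)
    return truth, g, expr, reference_summary_stats(g, expr, truth)


class TestReferenceSummaryStats:
    def test_null_snps_rarely_beyond_four_se(self, ref):
        truth, g, expr, ss = ref
        gene = truth.genes[0]
        causal = set(truth.snp_meta.loc[gene.trans_indices, "id"])
        causal |= {truth.snp_meta.loc[gene.cis_index, "id"]}
        causal_blocks = set(truth.snp_meta.loc[
            truth.snp_meta["id"].isin(causal), "block"])
        sub = ss[ss["GENE"] == gene.gene_id].merge(
            truth.snp_meta[["id", "block"]], left_on="SNP", right_on="id")
        null = sub[~sub["block"].isin(causal_blocks)
                   & ~sub["SNP"].isin(truth.snp_meta.loc[
                       truth.hotspot_indices, "id"])]
        frac = (null["BETA"].abs() < 4 * null["SE"]).mean()
        assert frac >= 0.99

    def test_effect_estimate_close_to_truth(self):
        """An isolated causal SNP with known standardized effect is
        recovered by the marginal regression within sampling error."""
        cfg = ArchitectureConfig(seed=17, block_rho=0.0, n_core_genes=1,
                                 n_null_genes=0, h2_cis=0.0,
                                 hotspot_trans_share=0.0,
                                 n_peripheral_loci_per_gene=4)
        truth = sample_architecture(cfg)
        g = simulate_genotypes(cfg, truth, n=10000)
        expr = simulate_expression(g, truth)
        ss = reference_summary_stats(g, expr, truth)
        gene = truth.genes[0]
        # expected standardized marginal slope of each causal SNP
        t_raw = trans_genetic_values(g, truth, standardize=False)
        scale = (np.sqrt(gene.h2_trans)
                 / t_raw[gene.gene_id].std())
        for j, snp_i in enumerate(gene.trans_indices):
            snp = truth.snp_meta.loc[snp_i, "id"]
            est = ss[(ss["GENE"] == gene.gene_id)
                     & (ss["SNP"] == snp)]["BETA"].item()
            true_b = gene.trans_betas[j] * scale
            assert abs(est - true_b) < 0.05

    def test_duplicated_individuals_rejected(self, ref):
        truth, g, expr, _ = ref
        dup = g.subset([g.sample_ids[0], g.sample_ids[0], g.sample_ids[1]])
        with pytest.raises(StructuralError, match="duplicated"):
            reference_summary_stats(
                dup, expr.iloc[[0, 0, 1]], truth)

    def test_rmse_decreases_with_reference_size(self):
        cfg = ArchitectureConfig(seed=18, block_rho=0.0, n_core_genes=1,
                                 n_null_genes=0, h2_cis=0.0,
                                 hotspot_trans_share=0.0)
        truth = sample_architecture(cfg)
        gene = truth.genes[0]
        big = simulate_genotypes(cfg, truth, n=17000,
                                 rng=np.random.default_rng(40))
        t_raw = trans_genetic_values(big, truth, standardize=False)
        scale = np.sqrt(gene.h2_trans) / t_raw[gene.gene_id].std()
        true_b = gene.trans_betas * scale
        snps = truth.snp_meta.loc[gene.trans_indices, "id"].tolist()
        rmses = []
        start = 0
        for n in (2000, 5000, 10000):
            sub = big.subset(big.sample_ids[start:start + n])
            start += n
            expr = simulate_expression(sub, truth,
                                       rng=np.random.default_rng(41))
            ss = reference_summary_stats(sub, expr, truth)
            est = (ss[(ss["GENE"] == gene.gene_id) & ss["SNP"].isin(snps)]
                   .set_index("SNP").loc[snps, "BETA"].to_numpy())
            rmses.append(np.sqrt(np.mean((est - true_b) ** 2)))
        assert rmses[2] < rmses[0]


def test_simulate_study_cohorts_are_disjoint_and_deterministic():
    cfg = ArchitectureConfig(seed=19, n_snps=120, n_blocks=40,
                             n_core_genes=2, n_null_genes=1,
                             n_peripheral_loci_per_gene=4)
    a = simulate_study(cfg, n_cases=200, n_controls=200, n_ref=800)
    b = simulate_study(cfg, n_cases=200, n_controls=200, n_ref=800)
    assert not set(a.ref_genotypes.sample_ids) & set(a.cc_genotypes.sample_ids)
    assert np.array_equal(a.cc_genotypes.dosages, b.cc_genotypes.dosages)
    pd.testing.assert_frame_equal(a.summary_stats, b.summary_stats)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
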