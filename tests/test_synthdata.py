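"""Ground-truth properties of the synthetic-cohort generator."""

import numpy as np
import pandas as pd
import pytest

from flowgwas.synthdata import (
    Block,
    SimConfig,
    simulate_covariates,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_protein_table,
)


class TestGenotypes:
    def test_same_seed_bitwise_identical(self):
        cfg = SimConfig(n_samples=200, seed=5, blocks=[Block("1", 10)])
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        assert np.array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_dosages_are_hard_genotypes_in_range(self):
        g = simulate_genotypes(SimConfig(n_samples=300, seed=1, blocks=[Block("1", 15)]))
        assert set(np.unique(g.dosages)) <= {0.0, 1.0, 2.0}

    def test_zero_corr_blocks_are_uncorrelated(self):
        n = 5000
        cfg = SimConfig(
            n_samples=n,
            seed=2,
            blocks=[Block("1", 10, (0.2, 0.4), 0.0), Block("2", 10, (0.2, 0.4), 0.0)],
        )
        g = simulate_genotypes(cfg)
        r = np.corrcoef(g.dosages, rowvar=False)
        off = np.abs(r[np.triu_indices_from(r, k=1)])
        assert off.mean() < 3.0 / np.sqrt(n)

    def test_within_block_correlation_exceeds_across(self):
        cfg = SimConfig(
            n_samples=3000,
            seed=3,
            blocks=[Block("1", 10, (0.2, 0.4), 0.8), Block("2", 10, (0.2, 0.4), 0.8)],
        )
        g = simulate_genotypes(cfg)
        r = np.abs(np.corrcoef(g.dosages, rowvar=False))
        within = r[:10, :10][np.triu_indices(10, k=1)].mean()
        across = r[:10, 10:].mean()
        assert within > 0.3
        assert across < 0.1

    def test_fixed_maf_within_binomial_bound(self):
        n = 4000
        cfg = SimConfig(n_samples=n, seed=4, blocks=[Block("1", 20, (0.3, 0.3), 0.0)])
        g = simulate_genotypes(cfg)
        bound = 3 * np.sqrt(0.3 * 0.7 / (2 * n))
        emp = g.dosages.mean(axis=0) / 2
        assert np.all(np.abs(emp - 0.3) < bound)

    @pytest.mark.parametrize("bad", [dict(n_samples=0), dict(blocks=[Block("1", 0)])])
    def test_invalid_config_raises(self, bad):
        cfg = SimConfig(**{"n_samples": 100, "seed": 0, **bad})
        with pytest.raises(ValueError):
            simulate_genotypes(cfg)


class TestCovariates:
    def test_male_rows_have_male_menopause_level(self):
        cov = simulate_covariates(2000, seed=7)
        assert (cov.loc[cov["sex"] == "M", "meno"] == "male").all()
        assert not (cov.loc[cov["sex"] == "F", "meno"] == "male").any()

    def test_missing_venipuncture_imputed_by_median(self):
        cov = simulate_covariates(2000, seed=8)
        miss = cov["t_ven_imputed"]
        assert miss.any()
        imputed_value = cov.loc[miss, "t_ven"].unique()
        assert len(imputed_value) == 1  # all missing rows share the observed median

    def test_day_of_week_matches_calendar(self):
        cov = simulate_covariates(500, seed=9)
        expected = pd.to_datetime(cov["timestamp"], unit="s", utc=True).dt.day_name().str.lower()
        assert (cov["day_of_week"] == expected).all()


class TestPhenotypes:
    def test_pure_noise_variance(self):
        cfg = SimConfig(n_samples=5000, seed=10, noise_sd=1.0)
        g = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg.n_samples, seed=11)
        pheno, _ = simulate_phenotypes(g, cov, cfg)
        assert pheno["trait1"].var() == pytest.approx(1.0, rel=0.1)

    def test_ols_recovers_injected_beta(self):
        n = 4000
        cfg = SimConfig(
            n_samples=n,
            seed=12,
            blocks=[Block("1", 5, (0.3, 0.3), 0.0)],
            causal_effects=[("1:1000000:A:G", "t", 0.5)],
            noise_sd=1.0,
        )
        g = simulate_genotypes(cfg)
        cov = simulate_covariates(n, seed=13)
        pheno, _ = simulate_phenotypes(g, cov, cfg)
        x = g.column("1:1000000:A:G")
        beta = np.polyfit(x, pheno["t"], 1)[0]
        se = 1.0 / np.sqrt(n * x.var())
        assert abs(beta - 0.5) < 3 * se

    def test_seasonal_term_explains_expected_variance_share(self):
        cfg = SimConfig(
            n_samples=8000,
            seed=14,
            tech_effects=__import__("flowgwas").synthdata.TechEffects(seasonal_amplitude=1.0),
            noise_sd=1.0,
        )
        g = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg.n_samples, seed=15)
        pheno, truth = simulate_phenotypes(g, cov, cfg)
        y = pheno["trait1"].to_numpy()
        seas = truth.technical["seasonal"]
        r2 = np.corrcoef(y, seas)[0, 1] ** 2
        # a unit-amplitude sinusoid has variance 1/2
        assert r2 == pytest.approx(0.5 / (0.5 + 1.0), abs=0.05)

    def test_heritability_matches_injected(self):
        n = 8000
        cfg = SimConfig(
            n_samples=n,
            seed=16,
            blocks=[Block("1", 5, (0.3, 0.3), 0.0), Block("2", 5, (0.2, 0.2), 0.0)],
            causal_effects=[("1:1000000:A:G", "t", 0.4), ("2:1000000:A:G", "t", 0.3)],
            noise_sd=1.0,
        )
        g = simulate_genotypes(cfg)
        cov = simulate_covariates(n, seed=17)
        pheno, _ = simulate_phenotypes(g, cov, cfg)
        h2_inj = (2 * 0.3 * 0.7 * 0.16 + 2 * 0.2 * 0.8 * 0.09) / pheno["t"].var()
        var_g = 0.16 * g.column("1:1000000:A:G").var() + 0.09 * g.column("2:1000000:A:G").var()
        assert var_g / pheno["t"].var() == pytest.approx(h2_inj, rel=0.15)

    def test_technical_terms_independent_of_genotype(self):
        cfg = SimConfig(
            n_samples=5000,
            seed=18,
            tech_effects=__import__("flowgwas").synthdata.TechEffects(1.0, 1.0, 1.0, 0.05),
        )
        g = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg.n_samples, seed=19)
        _, truth = simulate_phenotypes(g, cov, cfg)
        for term in truth.technical.values():
            if term.std() == 0:
                continue
            for j in range(0, g.n_variants, 7):
                assert abs(np.corrcoef(term, g.dosages[:, j])[0, 1]) < 0.05

    def test_unknown_causal_variant_raises(self):
        cfg = SimConfig(n_samples=100, seed=20, causal_effects=[("9:1:A:G", "t", 0.5)])
        g = simulate_genotypes(cfg)
        cov = simulate_covariates(100, seed=21)
        with pytest.raises(ValueError, match="absent"):
            simulate_phenotypes(g, cov, cfg)


class TestProteinTable:
    def test_zero_delta_group_means_close(self):
        t = simulate_protein_table(2000, 400, delta=0.0, seed=22)
        gap = t.loc[t.alpha_granule, "beta"].mean() - t.loc[~t.alpha_granule, "beta"].mean()
        assert abs(gap) < 0.01

    def test_no_granule_proteins_is_handled(self):
        t = simulate_protein_table(100, 0, delta=0.04, seed=23)
        assert not t["alpha_granule"].any()

    def test_granule_exceeding_total_raises(self):
        with pytest.raises(ValueError):
            simulate_protein_table(10, 11, delta=0.0, seed=0)
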