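"""Synthetic cohort generator: pedigree logic, ground truth, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from twinage.exceptions import ConfigurationError
from twinage.io import rank_normalize_matrix, scale_counts
from twinage.simulate import (
    GeneEffectProfile,
    SimulationConfig,
    simulate_cohort,
    write_cohort,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(age_range=(10, 50)), "age_range"),
            (dict(age_range=(60, 50)), "age_range"),
            (dict(n_mz_pairs=0, n_dz_pairs=0), "pair type"),
            (dict(n_genes=-1), "n_genes"),
            (dict(exons_per_gene_range=(0, 3)), "exons_per_gene_range"),
            (dict(exon_counts=[1, 2]), "exon_counts"),
        ],
    )
    def test_bad_config_names_field(self, kwargs, msg):
        cfg = SimulationConfig(**kwargs)
        with pytest.raises(ConfigurationError, match=msg):
            simulate_cohort(cfg)

    def test_profile_fractions_must_sum_to_one(self):
        prof = GeneEffectProfile(sigma2_a=0.5, sigma2_c=0.5, sigma2_e=0.5)
        with pytest.raises(ConfigurationError, match="must be 1"):
            prof.validate()

    def test_gxage_maf_range_checked(self):
        prof = GeneEffectProfile(sigma2_e=0.5, sigma2_a=0.5, sigma2_c=0.0,
                                 gxage=(0.01, 0.1, 0.01))
        with pytest.raises(ConfigurationError, match="maf"):
            prof.validate()


class TestCohortStructure:
    def test_cotwins_share_family_and_age(self, null_cohort):
        df = null_cohort.samples.data
        for _, grp in df.groupby("family_id"):
            assert len(grp) <= 2
            assert grp["age"].nunique() == 1

    def test_seed_determinism(self):
        cfg = dict(n_mz_pairs=10, n_dz_pairs=10, n_genes=5, seed=99)
        a = simulate_cohort(SimulationConfig(**cfg))
        b = simulate_cohort(SimulationConfig(**cfg))
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
        pd.testing.assert_frame_equal(a.genotypes.dosages, b.genotypes.dosages)
        pd.testing.assert_frame_equal(a.samples.data, b.samples.data)

    def test_mz_twins_share_genotypes_dz_share_half(self, null_cohort):
        dos = null_cohort.genotypes.dosages.to_numpy()
        samples = null_cohort.samples
        mz = samples.complete_pairs("MZ")
        for i, j in mz:
            np.testing.assert_array_equal(dos[:, i], dos[:, j])
        # DZ allele sharing: expected IBD correlation ~ 0.5 on average
        dz = samples.complete_pairs("DZ")
        cors = []
        for v in range(dos.shape[0]):
            a = dos[v, [i for i, _ in dz]]
            b = dos[v, [j for _, j in dz]]
            if a.std() > 0 and b.std() > 0:
                cors.append(np.corrcoef(a, b)[0, 1])
        assert np.mean(cors) == pytest.approx(0.5, abs=0.1)

    def test_maf_within_sampling_error(self):
        cfg = SimulationConfig(n_mz_pairs=200, n_dz_pairs=200, n_genes=10,
                               n_variants_per_gene=5, seed=3)
        ds = simulate_cohort(cfg)
        emp = ds.genotypes.maf.to_numpy()
        true = ds.genotypes.annotation["true_maf"].to_numpy()
        # ~1600 founder haplotypes per variant -> binomial se ~ sqrt(pq/1600)
        se = np.sqrt(true * (1 - true) / 1600)
        assert np.all(np.abs(emp - true) < 5 * se + 0.01)

    def test_methylation_in_unit_interval(self, null_cohort):
        b = null_cohort.methylation.betas.to_numpy()
        assert b.min() >= 0.0 and b.max() <= 1.0


class TestGroundTruthEffects:
    def test_pure_additive_genetics_gives_twin_correlations(self):
        prof = GeneEffectProfile(sigma2_a=1.0, sigma2_c=0.0, sigma2_e=0.0)
        ds = simulate_cohort(
            SimulationConfig(n_mz_pairs=500, n_dz_pairs=500, n_genes=30,
                             exons_per_gene_range=(1, 1), exon_corr=1.0,
                             effect_profiles=[prof], seed=2, tech_effect_sd=0.0)
        )
        fm, _ = rank_normalize_matrix(scale_counts(ds.expression))
        Y = fm.values.to_numpy()
        mz = ds.samples.complete_pairs("MZ")
        dz = ds.samples.complete_pairs("DZ")
        i1, j1 = zip(*mz)
        i2, j2 = zip(*dz)
        rmz = np.mean([np.corrcoef(Y[k, list(i1)], Y[k, list(j1)])[0, 1] for k in range(len(Y))])
        rdz = np.mean([np.corrcoef(Y[k, list(i2)], Y[k, list(j2)])[0, 1] for k in range(len(Y))])
        assert rmz == pytest.approx(1.0, abs=0.03)
        assert rdz == pytest.approx(0.5, abs=0.05)

    def test_null_model_residuals_uncorrelated_with_age(self):
        ds = simulate_cohort(
            SimulationConfig(n_mz_pairs=100, n_dz_pairs=100, n_genes=50, seed=8,
                             tech_effect_sd=0.0)
        )
        fm, _ = rank_normalize_matrix(scale_counts(ds.expression))
        from scipy import stats

        ages = ds.samples.ages
        rhos = [
            stats.spearmanr(np.abs(row - row.mean()), ages).statistic
            for row in fm.values.to_numpy()
        ]
        assert abs(np.mean(rhos)) < 0.02

    def test_age_effect_pve_matches_variance_decomposition(self):
        # brute-force oracle: with beta = 0.05 sd/yr and unit residual sd,
        # PVE_age = beta^2 Var(age) / (beta^2 Var(age) + 1)
        beta = 0.05
        # sign-balanced signal genes among nulls keep the library totals
        # age-neutral, so scaling does not eat the per-gene trend
        profs = [GeneEffectProfile(beta_age=beta), GeneEffectProfile(beta_age=-beta)]
        profs += [GeneEffectProfile() for _ in range(30)]
        ds = simulate_cohort(
            SimulationConfig(n_mz_pairs=5000, n_dz_pairs=0, n_genes=32,
                             exons_per_gene_range=(1, 1), exon_corr=1.0,
                             effect_profiles=profs, seed=21, tech_effect_sd=0.0)
        )
        ages = ds.samples.ages
        expected = beta**2 * np.var(ages) / (beta**2 * np.var(ages) + 1.0)
        # signal column variance vs formula numerator
        sig_var = ds.latent.to_numpy()[:2].var(axis=1).mean()
        assert sig_var == pytest.approx(beta**2 * np.var(ages), rel=0.02)
        # empirical share of variance explained by age in the observed data
        fm, _ = rank_normalize_matrix(scale_counts(ds.expression))
        sel = fm.gene_ids.isin(["G0000", "G0001"]).to_numpy()
        Y = fm.values.to_numpy()[sel]
        r2 = np.mean([np.corrcoef(y, ages)[0, 1] ** 2 for y in Y])
        assert r2 == pytest.approx(expected, abs=0.02)


class TestWriteCohort:
    def test_round_trip_via_readers(self, tmp_path, null_cohort):
        from twinage.pipeline import RunConfig, load_cohort

        write_cohort(null_cohort, tmp_path)
        samples, expr, geno, meth = load_cohort(tmp_path, RunConfig())
        np.testing.assert_allclose(
            expr.values.to_numpy(),
            null_cohort.expression.values.loc[expr.feature_ids].to_numpy(),
        )
        np.testing.assert_allclose(
            geno.dosages.to_numpy(), null_cohort.genotypes.dosages.to_numpy()
        )
        np.testing.assert_allclose(
            meth.betas.to_numpy(), null_cohort.methylation.betas.to_numpy(), atol=1e-12
        )
        np.testing.assert_allclose(samples.ages, null_cohort.samples.ages)

    def test_empty_gene_set_writes_headers(self, tmp_path):
        ds = simulate_cohort(SimulationConfig(n_mz_pairs=2, n_dz_pairs=1, n_genes=0, seed=1))
        paths = write_cohort(ds, tmp_path)
        header = open(paths["expression"]).readline()
        assert header.startswith("feature_id")
        assert ds.expression.values.shape[0] == 0

    def test_vcf_parses_with_standard_reader(self, tmp_path, null_cohort):
        # cyvcf2 is the external-format gate; bcftools validated the same
        # writer during development
        from twinage.io import read_vcf

        write_cohort(null_cohort, tmp_path)
        gm = read_vcf(tmp_path / "genotypes.vcf")
        assert gm.dosages.shape == null_cohort.genotypes.dosages.shape
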