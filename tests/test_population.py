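"""Covariate model and inter-individual variability."""

import numpy as np
import pytest

from warfarin_mipd.population import (REFERENCE_COVARIATES, CovariateProfile,
                                      Demographics, sample_cohort,
                                      sample_individual, typical_parameters)


class TestCovariateProfile:
    def test_unknown_genotypes_rejected(self):
        with pytest.raises(ValueError):
            CovariateProfile("*4*4", "GG", 50)
        with pytest.raises(ValueError):
            CovariateProfile("*1*1", "GT", 50)
        with pytest.raises(ValueError):
            CovariateProfile("*1*1", "GG", 12)


class TestTypicalParameters:
    def test_reference_profile_is_identity(self, theta):
        assert typical_parameters(theta, REFERENCE_COVARIATES) \
            == theta.typical

    def test_vkorc1_a_alleles_reduce_ec50(self, theta):
        """Sensitivity ordering: EC50(AA) < EC50(GA) < EC50(GG)."""
        ec50 = {v: typical_parameters(
            theta, CovariateProfile("*1*1", v, 71)).EC50
            for v in ("GG", "GA", "AA")}
        assert ec50["AA"] < ec50["GA"] < ec50["GG"]

    def test_cyp2c9_variant_reduces_elimination(self, theta):
        ke_13 = typical_parameters(
            theta, CovariateProfile("*1*3", "GG", 71)).ke
        ke_11 = typical_parameters(
            theta, CovariateProfile("*1*1", "GG", 71)).ke
        assert ke_13 < ke_11

    def test_age_modulates_elimination(self, theta):
        young = typical_parameters(theta, CovariateProfile("*1*1", "GG", 41))
        old = typical_parameters(theta, CovariateProfile("*1*1", "GG", 91))
        assert young.ke > theta.typical.ke > old.ke


class TestSampleIndividual:
    def test_zero_omegas_reproduce_typical(self, theta):
        from dataclasses import replace
        quiet = replace(theta, omegas={})
        chi = CovariateProfile("*1*2", "GA", 55)
        assert sample_individual(quiet, chi, 1) \
            == typical_parameters(quiet, chi)

    def test_same_seed_same_individual(self, theta):
        chi = CovariateProfile("*1*2", "GA", 55)
        assert sample_individual(theta, chi, 42) \
            == sample_individual(theta, chi, 42)

    def test_log_ke_sd_recovers_omega(self, theta):
        """Moment recovery: SD of log(ke) over many draws matches the
        random-effect SD within 3 Monte-Carlo standard errors."""
        rng = np.random.default_rng(0)
        chi = REFERENCE_COVARIATES
        n = 10_000
        kes = np.log([sample_individual(theta, chi, rng).ke
                      for _ in range(n)])
        omega = theta.omegas["ke"]
        se = omega / np.sqrt(2 * (n - 1))
        assert abs(kes.std(ddof=1) - omega) < 3 * se

    def test_samples_satisfy_invariants(self, theta):
        rng = np.random.default_rng(3)
        for _ in range(200):
            psi = sample_individual(theta, REFERENCE_COVARIATES, rng)
            assert psi.ke > 0 and psi.EC50 > 0 and psi.V > 0


class TestSampleCohort:
    def test_cohort_size(self, theta, demographics):
        cohort = sample_cohort(theta, demographics, 1000, 0)
        assert len(cohort) == 1000

    def test_genotype_frequencies_recovered(self, theta, demographics):
        """Binomial check: observed genotype frequencies of a large cohort
        sit within 3 standard errors of the demographics."""
        n = 100_000
        rng = np.random.default_rng(1)
        chis = demographics.sample_covariates(n, rng)
        for genotype, p in demographics.vkorc1_freqs.items():
            obs = sum(c.vkorc1 == genotype for c in chis) / n
            se = np.sqrt(p * (1 - p) / n)
            assert abs(obs - p) < 3 * se, genotype

    def test_degenerate_demographics(self, theta):
        demo = Demographics(
            cyp2c9_freqs={"*1*1": 0.0, "*1*2": 0.0, "*1*3": 1.0,
                          "*2*2": 0.0, "*2*3": 0.0, "*3*3": 0.0},
            vkorc1_freqs={"GG": 1.0, "GA": 0.0, "AA": 0.0})
        cohort = sample_cohort(theta, demo, 50, 2)
        assert all(chi.cyp2c9 == "*1*3" and chi.vkorc1 == "GG"
                   for chi, _ in cohort)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            Demographics(cyp2c9_freqs={"*1*1": 0.9},
                         vkorc1_freqs={"GG": 1.0, "GA": 0.0, "AA": 0.0})

    def test_ages_respect_truncation(self, demographics):
        rng = np.random.default_rng(5)
        chis = demographics.sample_covariates(5000, rng)
        ages = np.array([c.age for c in chis])
        assert ages.min() >= 18 and ages.max() <= 100


def test_pooled_moments_match_covariate_mixture(theta, demographics):
    """Marginalising over covariates: the pooled mean of log EC50 equals the
    frequency-weighted mixture of per-genotype means."""
    rng = np.random.default_rng(7)
    n = 20_000
    cohort = sample_cohort(theta, demographics, n, rng)
    pooled = np.mean([np.log(psi.EC50) for _, psi in cohort])
    mixture = sum(
        p * np.log(typical_parameters(
            theta, CovariateProfile("*1*1", v, 71)).EC50)
        for v, p in demographics.vkorc1_freqs.items())
    # age and CYP2C9 do not touch EC50; lognormal effects have mean 0 in log
    se = theta.omegas["EC50"] / np.sqrt(n) * 3
    assert abs(pooled - mixture) < se + 0.01
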