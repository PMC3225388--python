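import numpy as np
import pytest
from scipy.stats import binom, binomtest

from collapsim import (
    CaseControlSample,
    FixedEffectModel,
    HeterogeneousModel,
    draw_architecture,
    estimate_or,
    heterogeneous_experiment,
    median_or_experiment,
    rejection_sample_cohort,
    sample_fixed_effect_cohort,
)


class TestSampleFixedEffectCohort:
    def test_counts_sum_to_sample_sizes(self, figure1_model):
        s = sample_fixed_effect_cohort(figure1_model, 1750, 1750, rng_seed=1)
        assert s.case_genotype_counts.sum() == 1750
        assert s.control_genotype_counts.sum() == 1750

    def test_fixed_seed_reproducible(self, figure1_model):
        a = sample_fixed_effect_cohort(figure1_model, 500, 500, rng_seed=7)
        b = sample_fixed_effect_cohort(figure1_model, 500, 500, rng_seed=7)
        np.testing.assert_array_equal(a.case_genotype_counts, b.case_genotype_counts)
        np.testing.assert_array_equal(
            a.control_genotype_counts, b.control_genotype_counts
        )

    def test_null_model_approaches_hwe_in_both_strata(self):
        model = FixedEffectModel(0.1, 0.0, 0.3, 100)
        s = sample_fixed_effect_cohort(model, 200_000, 200_000, rng_seed=2)
        hwe = binom.pmf(np.arange(3), 2, 0.3)
        np.testing.assert_allclose(s.case_genotype_counts / 200_000, hwe, atol=0.005)
        np.testing.assert_allclose(
            s.control_genotype_counts / 200_000, hwe, atol=0.005
        )

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            CaseControlSample(np.array([5, 5, 5]), np.array([5, 5, 5]), 20, 15)


class TestEstimateOR:
    def test_identical_strata_give_one_both_methods(self):
        s = CaseControlSample(np.array([30, 40, 30]), np.array([30, 40, 30]), 100, 100)
        assert estimate_or(s, "logistic") == pytest.approx(1.0, abs=1e-9)
        assert estimate_or(s, "allele_table") == pytest.approx(1.0)

    def test_unknown_method_rejected(self):
        s = CaseControlSample(np.array([30, 40, 30]), np.array([30, 40, 30]), 100, 100)
        with pytest.raises(ValueError):
            estimate_or(s, "probit")

    def test_matrix_sample_returns_per_snp_ors(self):
        rng = np.random.default_rng(5)
        cases = rng.integers(0, 3, size=(400, 7))
        controls = rng.integers(0, 3, size=(400, 7))
        s = CaseControlSample.from_genotype_matrices(cases, controls)
        ors = estimate_or(s, "logistic")
        assert ors.shape == (7,)
        assert np.all(ors > 0)


class TestMedianORExperiment:
    def test_null_effect_median_near_one(self):
        model = FixedEffectModel(0.05, 0.0, 0.25, 100)
        res = median_or_experiment(model, n_replicates=500, rng_seed=3)
        assert res.or_median == pytest.approx(1.0, abs=0.02)

    def test_reproducible_given_seed(self, figure1_model):
        a = median_or_experiment(figure1_model, n_replicates=200, rng_seed=11)
        b = median_or_experiment(figure1_model, n_replicates=200, rng_seed=11)
        assert a.or_median == b.or_median

    def test_replicates_kept_on_request(self, figure1_model):
        res = median_or_experiment(
            figure1_model, n_replicates=50, rng_seed=1, keep_replicates=True
        )
        assert res.replicate_ors.shape == (50,)
        assert np.median(res.replicate_ors) == res.or_median

    def test_null_log_or_centered_at_zero_sign_test(self):
        """Under no association the replicate log ORs are symmetric about 0."""
        model = FixedEffectModel(0.05, 0.0, 0.25, 100)
        res = median_or_experiment(
            model, n_replicates=1000, rng_seed=17, keep_replicates=True
        )
        n_pos = int(np.sum(np.log(res.replicate_ors) > 0))
        assert binomtest(n_pos, 1000, 0.5).pvalue > 0.01

    def test_low_maf_falls_back_rather_than_dropping(self):
        # at p_a=0.005 and n=600 many replicates have empty genotype classes
        model = FixedEffectModel.from_or(0.01, 1.5, 0.005, 100)
        res = median_or_experiment(
            model, n_replicates=300, n_cases=300, n_controls=300, rng_seed=5
        )
        assert res.n_replicates == 300
        assert res.n_fallback > 0
        assert np.isfinite(res.or_median)


class TestDrawArchitecture:
    def test_moments_of_default_architecture(self):
        betas, freqs = draw_architecture(200_000, rng_seed=1)
        assert betas.mean() == pytest.approx(0.2, rel=0.02)
        assert np.exp(betas).mean() == pytest.approx(1.25, rel=0.02)
        assert freqs.min() >= 0.05 and freqs.max() <= 0.95
        assert freqs.mean() == pytest.approx(0.5, abs=0.01)

    def test_fixed_seed_reproducible(self):
        a = draw_architecture(100, rng_seed=4)
        b = draw_architecture(100, rng_seed=4)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_heavy_tailed_rate_warns(self):
        with pytest.warns(RuntimeWarning):
            draw_architecture(10, exp_rate=0.9, rng_seed=0)

    def test_invalid_frequency_range_rejected(self):
        with pytest.raises(ValueError):
            draw_architecture(10, maf_low=0.5, maf_high=0.1)


@pytest.fixture(scope="module")
def small_het_model():
    """5-SNP heterogeneous disease with 20% prevalence (cheap to sample).

    The background effects are sizeable (beta=0.7 at p=0.5) so that the
    non-collapsibility attenuation of the largest SNP (~8% here) clearly
    exceeds Monte-Carlo noise at modest replicate counts.
    """
    betas = np.array([0.0, 0.7, 0.7, 0.7, np.log(2.0)])
    freqs = np.array([0.2, 0.5, 0.5, 0.5, 0.5])
    return HeterogeneousModel(
        0.2, betas, freqs, calibration_draws=200_000, calibration_seed=1
    )


class TestRejectionSampler:
    def test_exact_stratum_sizes(self, small_het_model):
        s = rejection_sample_cohort(small_het_model, 800, 900, rng_seed=2)
        assert s.n_cases == 800 and s.n_controls == 900
        assert np.all(s.case_genotype_counts.sum(axis=1) == 800)
        assert np.all(s.control_genotype_counts.sum(axis=1) == 900)

    def test_reproducible_given_seed(self, small_het_model):
        a = rejection_sample_cohort(small_het_model, 300, 300, rng_seed=6)
        b = rejection_sample_cohort(small_het_model, 300, 300, rng_seed=6)
        np.testing.assert_array_equal(a.case_genotype_counts, b.case_genotype_counts)

    def test_draw_cap_enforced(self, small_het_model):
        with pytest.raises(RuntimeError):
            rejection_sample_cohort(small_het_model, 5000, 5000, rng_seed=1, max_draws=100)

    def test_null_architecture_controls_at_hwe(self):
        model = HeterogeneousModel(
            0.5, np.zeros(3), np.array([0.2, 0.5, 0.7]),
            calibration_draws=1000, calibration_seed=0,
        )
        s = rejection_sample_cohort(model, 20_000, 20_000, rng_seed=8)
        for j, p in enumerate(model.freqs):
            hwe = binom.pmf(np.arange(3), 2, p)
            np.testing.assert_allclose(
                s.control_genotype_counts[j] / 20_000, hwe, atol=0.01
            )


class TestHeterogeneousExperiment:
    def test_null_architecture_medians_near_one(self):
        model = HeterogeneousModel(
            0.3, np.zeros(4), np.array([0.2, 0.4, 0.6, 0.8]),
            calibration_draws=1000, calibration_seed=0,
        )
        results = heterogeneous_experiment(
            model, n_replicates=60, n_cases=600, n_controls=600, rng_seed=9
        )
        for r in results:
            assert r.or_median == pytest.approx(1.0, abs=0.05)

    def test_largest_effect_attenuated_most(self, small_het_model):
        results = heterogeneous_experiment(
            small_het_model, n_replicates=80, n_cases=1000, n_controls=1000, rng_seed=10
        )
        big = results[4]  # true OR 2 under a real polygenic background
        assert big.or_true == pytest.approx(2.0)
        assert big.or_median < big.or_true
        null = results[0]
        assert null.or_median == pytest.approx(1.0, abs=0.06)
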