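import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import seqpoint as sp

# Cumulative counts of the bundled trial: (12/97 vs 27/101) interim,
# (21/134 vs 42/143) final.


class TestPooledInformation:
    def test_reproduces_printed_z_statistics(self, musec_counts):
        interim, final = musec_counts
        i1 = sp.pooled_information(interim)
        i2 = sp.pooled_information(final)
        z1 = sp.wald_z(sp.mle_difference(interim), i1)
        z2 = sp.wald_z(sp.mle_difference(final), i2)
        assert z1 == pytest.approx(2.540, abs=5e-4)
        assert z2 == pytest.approx(2.718, abs=5e-4)

    def test_reproduces_information_fractions(self, musec_counts):
        interim, final = musec_counts
        frac = sp.pooled_information(interim) / sp.pooled_information(final)
        assert frac == pytest.approx(0.795, abs=5e-4)
        assert 1 - frac == pytest.approx(0.205, abs=5e-4)

    def test_equal_arms_closed_form(self):
        # pbar = 0.5, n = 100 per arm: I = 1/(0.25 * 0.02) = 200... with
        # unequal-variance bookkeeping the closed form gives n/(4 pbar qbar)
        counts = sp.AnalysisCounts(50, 100, 50, 100)
        assert sp.pooled_information(counts) == pytest.approx(200.0)

    def test_degenerate_proportion_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sp.pooled_information(sp.AnalysisCounts(0, 10, 0, 10))
        with pytest.raises(ValueError, match="degenerate"):
            sp.pooled_information(sp.AnalysisCounts(10, 10, 10, 10))

    @settings(deadline=None, max_examples=50)
    @given(
        n0=st.integers(5, 500),
        n1=st.integers(5, 500),
        scale=st.integers(2, 5),
    )
    def test_monotone_in_sample_size_at_fixed_proportions(self, n0, n1, scale):
        # doubling both arms at fixed success proportions doubles information
        base = sp.AnalysisCounts(n0, 5 * n0, n1, 5 * n1)
        grown = sp.AnalysisCounts(scale * n0, scale * 5 * n0,
                                  scale * n1, scale * 5 * n1)
        assert sp.pooled_information(grown) > sp.pooled_information(base)


class TestCountReduction:
    def test_overall_and_interim_mle(self, musec_counts):
        interim, final = musec_counts
        assert sp.mle_difference(final) == pytest.approx(0.1370, abs=5e-5)
        assert sp.mle_difference(interim) == pytest.approx(0.1436, abs=5e-5)

    def test_identical_arms_give_zero(self):
        assert sp.mle_difference(sp.AnalysisCounts(7, 50, 7, 50)) == 0.0

    def test_incremental_counts_give_stage2_mle(self, musec_counts):
        interim, final = musec_counts
        stage2 = sp.incremental_counts(interim, final)
        assert (stage2.successes_control, stage2.total_control) == (9, 37)
        assert (stage2.successes_treatment, stage2.total_treatment) == (15, 42)
        assert sp.mle_difference(stage2) == pytest.approx(0.1139, abs=5e-5)

    def test_incremental_counts_arithmetic(self):
        interim = sp.AnalysisCounts(0, 10, 0, 10)
        final = sp.AnalysisCounts(1, 20, 3, 20)
        stage2 = sp.incremental_counts(interim, final)
        assert sp.mle_difference(stage2) == pytest.approx(0.2)

    def test_no_new_subjects_is_an_error(self, musec_counts):
        interim, _ = musec_counts
        with pytest.raises(ValueError, match="stage-2 MLE is undefined"):
            sp.incremental_counts(interim, interim)

    def test_non_monotone_counts_rejected(self):
        interim = sp.AnalysisCounts(5, 20, 5, 20)
        final = sp.AnalysisCounts(4, 30, 8, 30)
        with pytest.raises(ValueError, match="must be >="):
            sp.incremental_counts(interim, final)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            sp.AnalysisCounts(5, 0, 1, 10)
        with pytest.raises(ValueError):
            sp.AnalysisCounts(11, 10, 1, 10)


class TestOBFDesign:
    def test_single_stage_is_the_normal_quantile(self):
        d = sp.obf_design(1, 0.05)
        assert d.z_boundaries[0] == pytest.approx(norm.isf(0.05), abs=1e-10)

    def test_two_stage_alpha_025_matches_printed_boundaries(self):
        d = sp.obf_design(2, 0.025, (0.5, 1.0))
        assert d.z_boundaries[0] == pytest.approx(2.797, abs=2e-3)
        assert d.z_boundaries[1] == pytest.approx(1.977, abs=2e-3)

    def test_two_stage_alpha_05_interim_nominal_pvalue(self):
        d = sp.obf_design(2, 0.05, (0.5, 1.0))
        assert d.interim_nominal_pvalues[0] == pytest.approx(0.0088, abs=5e-5)

    def test_boundaries_non_increasing(self):
        d = sp.obf_design(3, 0.025)
        assert np.all(np.diff(d.z_boundaries) < 0)

    @pytest.mark.parametrize("K", [1, 2, 3])
    @pytest.mark.parametrize("alpha", [0.01, 0.025, 0.05])
    def test_type_one_error_round_trip(self, K, alpha):
        d = sp.obf_design(K, alpha)
        achieved = sp.type_one_error(d.z_boundaries, d.info_fractions)
        assert achieved == pytest.approx(alpha, abs=1e-7)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sp.obf_design(0, 0.05)
        with pytest.raises(ValueError):
            sp.obf_design(2, 0.7)
        with pytest.raises(ValueError):
            sp.obf_design(2, 0.05, (0.9, 0.5))  # not increasing
        with pytest.raises(ValueError):
            sp.obf_design(2, 0.05, (0.25, 0.5))  # last != 1


class TestTypeOneError:
    def test_univariate_tail(self):
        assert sp.type_one_error([1.6449], [1.0]) == pytest.approx(
            norm.sf(1.6449), abs=1e-10
        )

    def test_printed_two_stage_boundaries_spend_alpha_025(self):
        # frozen from two independent oracles (adaptive quadrature of the
        # conditioning integral and scipy's mvn CDF): both 0.0250218056
        got = sp.type_one_error([2.797, 1.977], [0.5, 1.0])
        assert got == pytest.approx(0.0250218056, abs=1e-8)
        assert got == pytest.approx(0.025, abs=1e-4)

    def test_monte_carlo_oracle_two_stage(self):
        rng = np.random.default_rng(42)
        n = 2_000_000
        rho = np.sqrt(0.5)
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        emp = np.mean((z1 >= 2.797) | (z2 >= 1.977))
        got = sp.type_one_error([2.797, 1.977], [0.5, 1.0])
        assert abs(emp - got) < 3 * np.sqrt(0.025 * 0.975 / n)

    def test_with_drift_matches_bivariate_power(self):
        # under drift, crossing probability = 1 - Phi2 on the shifted scale
        theta, t = 3.0, np.array([0.5, 1.0])
        e = np.array([2.797, 1.977])
        from seqpoint._normal import bvn_cdf

        expect = 1.0 - bvn_cdf(
            e[0] - theta * np.sqrt(t[0]), e[1] - theta * np.sqrt(t[1]),
            np.sqrt(0.5),
        )
        got = sp.type_one_error(e, t, theta=theta)
        assert got == pytest.approx(expect, abs=1e-9)


class TestTrialInformation:
    def test_from_counts(self, musec_counts, musec_info):
        assert musec_info.z1 == pytest.approx(2.540, abs=5e-4)
        assert musec_info.z2 == pytest.approx(2.718, abs=5e-4)
        assert musec_info.info_fraction == pytest.approx(0.795, abs=5e-4)
        assert musec_info.effect_scale_boundary == pytest.approx(0.1581, abs=5e-5)

    def test_ordering_invariant(self):
        with pytest.raises(ValueError, match="I1 < I2"):
            sp.TrialInformation(
                i1=200.0, i2=100.0, z1=0.0, z2=0.0,
                theta1=0.0, theta_obs=0.0, e=2.8,
            )

    def test_wald_z_identity(self, musec_info):
        assert sp.wald_z(musec_info.theta1, musec_info.i1) == pytest.approx(
            musec_info.z1
        )
        assert sp.wald_z(0.0, 123.4) == 0.0
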