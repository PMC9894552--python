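"""Parameter validation, model covariance and reconstruction formulas."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import parsec as P
from parsec.fit import prepare
from parsec.model import (
    PARAM_NAMES,
    VAR1,
    VAR2,
    NegativeErrorVarianceError,
    NonPSDError,
    model_covariance,
    reconstruct,
    swap_traits,
)


class TestValidateParameters:
    def test_empty_model_has_unit_error_variances(self):
        v = P.validate_parameters(P.ParameterSet())
        assert v.err_var_1 == 1.0 and v.err_var_2 == 1.0

    def test_correlation_bound_violation_rejected(self):
        # |cov_dir| <= sqrt(var_dir_1 * var_dir_2) = 0.5 by Cauchy-Schwarz
        theta = P.ParameterSet(var_dir_1=0.5, var_dir_2=0.5, cov_dir=0.9)
        with pytest.raises(NonPSDError):
            P.validate_parameters(theta)

    def test_error_variance_arithmetic_var2(self):
        theta = P.ParameterSet(var_dir_1=0.3, var_ind_1=0.1, cov_dir_ind_11=0.05)
        v = P.validate_parameters(theta, VAR2)
        # 1 - 0.3*1 - 0.1*2 - 2*0.05*1
        assert v.err_var_1 == pytest.approx(0.40, abs=1e-12)
        # independent eigen-solver confirms the effect covariance is PSD
        assert np.linalg.eigvalsh(theta.omega()).min() >= -1e-10

    def test_error_variance_arithmetic_var1(self):
        theta = P.ParameterSet(var_dir_1=0.3, var_ind_1=0.1, cov_dir_ind_11=0.05)
        v = P.validate_parameters(theta, VAR1)
        expected = 1.0 - 0.3 - 0.1 - 2 * 0.05 / np.sqrt(2.0)
        assert v.err_var_1 == pytest.approx(expected, abs=1e-12)

    def test_oversized_genetic_variance_rejected(self):
        with pytest.raises(NegativeErrorVarianceError):
            P.validate_parameters(P.ParameterSet(var_dir_1=0.8, var_ind_1=0.2))

    def test_simulator_accepts_exactly_the_validated_sets(self):
        # fuzzed PSD effect covariances validate and simulate without error
        rng = np.random.default_rng(7)
        for _ in range(10):
            f = rng.standard_normal((4, 4)) * 0.2
            omega = f @ f.T
            omega *= 0.5 / max(np.diag(omega).max(), 0.5)
            theta = P.ParameterSet(
                var_dir_1=omega[0, 0],
                var_dir_2=omega[1, 1],
                var_ind_1=omega[2, 2],
                var_ind_2=omega[3, 3],
                cov_dir=omega[0, 1],
                cov_ind=omega[2, 3],
                cov_dir_ind_11=omega[0, 2],
                cov_dir_ind_22=omega[1, 3],
                cov_dir1_ind2=omega[0, 3],
                cov_dir2_ind1=omega[1, 2],
            )
            try:
                v = P.validate_parameters(theta)
            except NegativeErrorVarianceError:
                continue
            cohort = P.simulate_families(40, 8, maf_low=0.2, seed=rng)
            phenos = P.simulate_phenotypes(cohort, v, seed=rng)
            assert np.all(np.isfinite(phenos.y1)) and np.all(np.isfinite(phenos.y2))


class TestReconstruct:
    def test_zero_parameters(self):
        assert reconstruct(P.ParameterSet()) == (0.0, 0.0, 0.0)

    def test_heritability_arithmetic(self):
        theta = P.ParameterSet(var_dir_1=0.2, var_ind_1=0.1, cov_dir_ind_11=0.05)
        h2_1, h2_2, _ = reconstruct(theta)
        assert h2_1 == pytest.approx(0.40)
        assert h2_2 == 0.0

    def test_genetic_covariance_education_income_example(self):
        # direct/indirect covariance estimates reported for the EA-income pair
        theta = P.ParameterSet(cov_dir=0.044, cov_ind=0.032)
        _, _, rho_gc = reconstruct(theta)
        assert rho_gc == pytest.approx(0.076, abs=1e-12)

    @given(
        a=st.floats(-2, 2),
        b=st.floats(-2, 2),
        data=st.lists(st.floats(-0.5, 0.5), min_size=28, max_size=28),
    )
    def test_linearity(self, a, b, data):
        t1 = P.ParameterSet.from_array(np.array(data[:14]))
        t2 = P.ParameterSet.from_array(np.array(data[14:]))
        combo = P.ParameterSet.from_array(a * t1.to_array() + b * t2.to_array())
        lhs = np.array(reconstruct(combo))
        rhs = a * np.array(reconstruct(t1)) + b * np.array(reconstruct(t2))
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_trait_swap_symmetry(self):
        theta = P.FULL_SETTING
        h2_1, h2_2, rho = reconstruct(theta)
        s1, s2, srho = reconstruct(swap_traits(theta))
        assert (s1, s2, srho) == (h2_2, h2_1, rho)


class TestModelCovariance:
    def test_zero_theta_gives_identity(self, small_cohort_phenos):
        cohort, phenos = small_cohort_phenos
        V, _, _ = prepare(cohort, phenos)
        cov = model_covariance(P.ParameterSet(), V)
        assert np.array_equal(cov, np.eye(4 * cohort.n_families))

    def test_symmetry(self, small_cohort_phenos, valid_full):
        cohort, phenos = small_cohort_phenos
        V, _, _ = prepare(cohort, phenos)
        cov = model_covariance(valid_full, V)
        assert np.array_equal(cov, cov.T)

    def test_diagonal_near_one(self, small_cohort_phenos, valid_full):
        cohort, phenos = small_cohort_phenos
        V, _, _ = prepare(cohort, phenos)
        cov = model_covariance(valid_full, V)
        assert np.abs(np.diag(cov) - 1.0).mean() < 3.0 / np.sqrt(cohort.n_snps)

    def test_monte_carlo_family_blocks_match(self, valid_full):
        """E[y y' | genotypes] equals the model covariance on family blocks.

        Phenotypes are regenerated on a fixed cohort; per-repeat family-block
        deviations are averaged and compared entrywise at 3 Monte-Carlo SEs.
        """
        rng = np.random.default_rng(404)
        cohort = P.simulate_families(50, 200, seed=rng)
        probe = P.simulate_phenotypes(cohort, valid_full, seed=rng)
        V, _, _ = prepare(cohort, probe)
        sigma = model_covariance(valid_full, V)
        n = 2 * cohort.n_families
        nf = cohort.n_families
        idx = np.array([[2 * f, 2 * f + 1, n + 2 * f, n + 2 * f + 1] for f in range(nf)])
        reps = 500
        devs = np.empty((reps, 4, 4))
        for r in range(reps):
            ph = P.simulate_phenotypes(
                cohort, valid_full, seed=rng, standardize_traits=False
            )
            y = ph.stacked()
            blocks = np.array(
                [np.outer(y[idx[f]], y[idx[f]]) - sigma[np.ix_(idx[f], idx[f])] for f in range(nf)]
            )
            devs[r] = blocks.mean(axis=0)
        mean_dev = devs.mean(axis=0)
        mc_se = devs.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mean_dev) <= 3.0 * mc_se + 1e-12)


def test_parameter_roundtrip_and_names():
    arr = np.linspace(-0.1, 0.1, 14)
    theta = P.ParameterSet.from_array(arr)
    assert np.array_equal(theta.to_array(), arr)
    assert tuple(PARAM_NAMES) == tuple(theta.__dataclass_fields__)[:14]
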