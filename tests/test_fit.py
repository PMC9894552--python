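"""Normal-equation assembly, the linear solve, and the fit pipeline."""

import numpy as np
import pytest

import parsec as P
from parsec.fit import (
    MoMSystem,
    assemble_system,
    assemble_system_dense,
    covariate_projection,
    leave_block_systems,
    leave_snp_block_systems,
    prepare,
    solve_system,
)
from parsec.inference import _make_blocks
from parsec.model import swap_traits
from parsec.relatedness import RelatednessSet, build_relatedness
from parsec.simulate import PhenotypePair


class TestCovariateProjection:
    def test_intercept_projection_centers(self):
        rng = np.random.default_rng(0)
        Z = np.ones((30, 1))
        Q = covariate_projection(Z)
        assert Q.shape == (29, 30)
        assert np.max(np.abs(Q @ Z)) < 1e-10
        assert np.allclose(Q @ Q.T, np.eye(29), atol=1e-10)
        y = rng.standard_normal(30)
        assert (Q @ y).sum() * 0 == 0  # finite
        # projecting out the intercept annihilates the mean component
        assert abs((Q @ np.ones(30)).max()) < 1e-10

    def test_rank_deficient_rejected(self):
        Z = np.ones((20, 2))
        with pytest.raises(ValueError):
            covariate_projection(Z)


class TestAssembleSystem:
    def test_single_family_sibling_component_by_hand(self):
        # one family, y1 = (1, 1): A[s,s] = tr(S^2) = 2, B[s] = y'Sy = 2
        S = np.array([[0.0, 1.0], [1.0, 0.0]])
        V = RelatednessSet(
            K=np.zeros((2, 2)), G=np.zeros((2, 2)), C=np.zeros((2, 2)), S=S,
            d_X=0.0, d_P=0.0, d_C=0.0, pairs=np.array([[0, 1]]),
        )
        sys = assemble_system(V, np.array([1.0, 1.0]), np.zeros(2))
        i = P.PARAM_NAMES.index("err_sib_cov_1")
        assert sys.A[i, i] == pytest.approx(2.0)
        assert sys.B[i] == pytest.approx(2.0)
        assert sys.B[i] / sys.A[i, i] == pytest.approx(1.0)

    def test_gram_matrix_properties(self, small_cohort_phenos):
        cohort, phenos = small_cohort_phenos
        V, y1, y2 = prepare(cohort, phenos)
        sys = assemble_system(V, y1, y2)
        assert np.array_equal(sys.A, sys.A.T)
        assert np.linalg.eigvalsh(sys.A).min() > -1e-8 * np.abs(sys.A).max()

    def test_block_algebra_matches_dense(self, valid_full):
        rng = np.random.default_rng(30)
        cohort = P.simulate_families(30, 50, seed=rng)
        phenos = P.simulate_phenotypes(cohort, valid_full, seed=rng)
        V, y1, y2 = prepare(cohort, phenos)
        fast = assemble_system(V, y1, y2)
        dense = assemble_system_dense(V, y1, y2)
        assert np.allclose(fast.A, dense.A, rtol=1e-8)
        assert np.allclose(fast.B, dense.B, rtol=1e-8, atol=1e-8)
        assert fast.c0 == pytest.approx(dense.c0, rel=1e-10)


class TestSolveSystem:
    def test_identity_system(self):
        B = np.linspace(-1, 1, 14)
        theta, flagged = solve_system(MoMSystem(A=np.eye(14), B=B, c0=0.0, n_rows=1))
        assert np.allclose(theta, B)
        assert not flagged

    def test_singular_system_falls_back_to_min_norm(self):
        A = np.zeros((14, 14))
        A[0, 0] = A[1, 1] = 1.0
        A[2] = A[1]
        A[:, 2] = A[:, 1]  # duplicated column
        B = np.zeros(14)
        B[0] = 1.0
        theta, flagged = solve_system(MoMSystem(A=A, B=B, c0=0.0, n_rows=1))
        assert flagged
        assert np.all(np.isfinite(theta))


class TestLeaveBlockSystems:
    def test_family_downdate_equals_subset_reassembly(self, small_cohort_phenos):
        cohort, phenos = small_cohort_phenos
        V, y1, y2 = prepare(cohort, phenos)
        blocks = _make_blocks(V.pairs, 8, seed=3)
        A_all, B_all = leave_block_systems(V, y1, y2, blocks)
        all_rows = np.arange(V.n_rows)
        for b, held in enumerate(blocks):
            rows = np.setdiff1d(all_rows, held)
            sub = assemble_system(V.take(rows), y1[rows], y2[rows])
            assert np.allclose(A_all[b], sub.A, rtol=1e-10, atol=1e-8)
            assert np.allclose(B_all[b], sub.B, rtol=1e-10, atol=1e-8)

    def test_snp_downdate_equals_subset_reassembly(self, small_cohort_phenos):
        cohort, phenos = small_cohort_phenos
        V, y1, y2 = prepare(cohort, phenos)
        m = cohort.n_snps
        blocks = [np.sort(g) for g in np.array_split(np.random.default_rng(4).permutation(m), 6)]
        A_all, B_all = leave_snp_block_systems(V, y1, y2, blocks)
        for b, held in enumerate(blocks):
            keep = np.setdiff1d(np.arange(m), held)
            Vb = build_relatedness(V.x_std[:, keep], V.p_std[:, keep], cohort.family_id)
            sub = assemble_system(Vb, y1, y2)
            assert np.allclose(A_all[b], sub.A, rtol=1e-9, atol=1e-8)
            assert np.allclose(B_all[b], sub.B, rtol=1e-9, atol=1e-8)


class TestFitPipeline:
    def test_family_permutation_equivariance(self, small_cohort_phenos):
        cohort, phenos = small_cohort_phenos
        base = P.fit(cohort, phenos).theta.to_array()
        rng = np.random.default_rng(8)
        fam_order = rng.permutation(cohort.n_families)
        rows = np.stack([2 * fam_order, 2 * fam_order + 1], axis=1).ravel()
        import dataclasses

        shuffled = dataclasses.replace(
            cohort,
            sib_geno=cohort.sib_geno[rows],
            parent_sum=cohort.parent_sum[rows],
            family_id=cohort.family_id[rows],
            father=None,
            mother=None,
        )
        perm = P.fit(shuffled, PhenotypePair(y1=phenos.y1[rows], y2=phenos.y2[rows]))
        assert np.allclose(perm.theta.to_array(), base, atol=1e-10)

    def test_snp_permutation_equivariance(self, small_cohort_phenos):
        cohort, phenos = small_cohort_phenos
        base = P.fit(cohort, phenos).theta.to_array()
        rng = np.random.default_rng(9)
        cols = rng.permutation(cohort.n_snps)
        import dataclasses

        shuffled = dataclasses.replace(
            cohort,
            sib_geno=cohort.sib_geno[:, cols],
            parent_sum=cohort.parent_sum[:, cols],
            allele_freq=cohort.allele_freq[cols],
            father=None,
            mother=None,
        )
        assert np.allclose(P.fit(shuffled, phenos).theta.to_array(), base, atol=1e-10)

    def test_trait_swap_maps_estimates_by_symmetry(self, small_cohort_phenos):
        cohort, phenos = small_cohort_phenos
        res = P.fit(cohort, phenos)
        swapped = P.fit(cohort, PhenotypePair(y1=phenos.y2, y2=phenos.y1))
        expected = swap_traits(res.theta).to_array()
        assert np.allclose(swapped.theta.to_array(), expected, atol=1e-8)

    def test_objective_is_locally_minimal(self, small_cohort_phenos):
        cohort, phenos = small_cohort_phenos
        V, y1, y2 = prepare(cohort, phenos)
        sys = assemble_system(V, y1, y2)
        theta, _ = solve_system(sys)
        base = sys.objective(theta)
        rng = np.random.default_rng(10)
        for _ in range(20):
            assert sys.objective(theta + 0.01 * rng.standard_normal(14)) >= base

    def test_reconstruction_consistent_with_model_core(self, small_cohort_phenos):
        cohort, phenos = small_cohort_phenos
        res = P.fit(cohort, phenos)
        h2_1, h2_2, rho = P.reconstruct(res.theta)
        assert (res.h2_1, res.h2_2, res.rho_gc) == (h2_1, h2_2, rho)

    def test_null_error_only_recovery(self):
        """With no genetic signal, mean estimates recover the sibling error
        covariance and leave every genetic parameter at zero."""
        theta = P.ParameterSet(err_sib_cov_1=0.3, err_sib_cov_2=0.3)
        res = P.run_calibration(
            theta, n_families=250, n_snps=150, n_repeats=60, seed=606, jackknife=False
        )
        z = (res.mean() - res.truth) / res.mc_se()
        assert np.all(np.abs(z) <= 3.0)
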