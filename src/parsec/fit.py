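"""Method-of-moments estimation of the 14 variance/covariance parameters.

The estimator minimizes the Frobenius distance between the phenotype
cross-product matrix y y' and the model covariance I + sum_s theta_s V_s.
Setting the gradient to zero gives the normal equations A theta = B with

    A[s, t] = tr(V_s V_t)
    B[s]    = y' V_s y - tr(V_s)

Both are computed by block algebra on the 2N x 2N relatedness blocks; the
within-trait and cross-trait parameter groups decouple (products of a
within-trait and a cross-trait placement have zero diagonal blocks), so A is
block diagonal up to ordering.  A dense 4N x 4N path exists as an oracle.

Leave-block-out refits for the jackknife are computed by downdating the full
sums: for a held-out row set b, every trace and quadratic form restricted to
the retained rows equals the full sum minus the rows/columns touching b plus
the b x b corner, which costs O(N^2) once per matrix pair rather than a full
reassembly per block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .model import (
    Convention,
    VAR2,
    ParameterSet,
    modeled_genetic_variance,
    reconstruct,
)
from .relatedness import RelatednessSet, build_relatedness, standardize

__all__ = [
    "MoMSystem",
    "FitResult",
    "covariate_projection",
    "assemble_system",
    "assemble_system_dense",
    "solve_system",
    "fit",
    "prepare",
    "leave_block_systems",
    "leave_snp_block_systems",
]

# parameter-index groups sharing a placement, in canonical order
_T1 = (0, 2, 6, 10)  # trait-1 within: var_dir_1, var_ind_1, cov_dir_ind_11, err_sib_cov_1
_T2 = (1, 3, 7, 11)
_CROSS = (4, 5, 8, 9, 12, 13)  # cov_dir, cov_ind, cov_dir1_ind2, cov_dir2_ind1, eta, delta
_WITHIN_BASES = ("K-d", "G-d", "CCt-d", "S")
_CROSS_BASES = ("K", "G", "C", "Ct", "I", "S")

COND_THRESHOLD = 1e8


@dataclass
class MoMSystem:
    """Normal equations of the moment-matching objective."""

    A: np.ndarray
    B: np.ndarray
    #: ||yy' - I||_F^2, the theta-free part of the objective
    c0: float
    n_rows: int

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.A))

    def objective(self, theta: np.ndarray) -> float:
        """Frobenius objective L(theta) evaluated through the system."""
        theta = np.asarray(theta, dtype=float)
        return float(self.c0 - 2.0 * theta @ self.B + theta @ self.A @ theta)


@dataclass
class FitResult:
    """Point estimates with implied error variances and reconstructions."""

    theta: ParameterSet
    err_var_1: float
    err_var_2: float
    h2_1: float
    h2_2: float
    rho_gc: float
    model_variance_1: float
    model_variance_2: float
    condition_number: float
    objective: float
    convention: Convention
    ill_conditioned: bool = False
    negative_error_variance: bool = False
    n_families: int = 0
    n_snps: int = 0


def covariate_projection(Z: np.ndarray) -> np.ndarray:
    """Orthonormal basis Q of the left null space of Z, as a (2N-c) x 2N matrix.

    Q Z = 0 and Q Q' = I, so multiplying the model by Q removes fixed
    covariate effects while preserving the additive covariance structure.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] < Z.shape[1]:
        raise ValueError("covariate matrix must be tall (rows = individuals)")
    n, c = Z.shape
    u, s, _ = np.linalg.svd(Z, full_matrices=True)
    rank = int(np.sum(s > s.max() * max(n, c) * np.finfo(float).eps)) if s.size else 0
    if rank < c:
        raise ValueError(f"covariate matrix is rank deficient (rank {rank} < {c} columns)")
    return u[:, c:].T


def _within_mats(V: RelatednessSet) -> list[np.ndarray]:
    return [V.base_matrix(b) for b in _WITHIN_BASES]


def _cross_mats(V: RelatednessSet) -> list[np.ndarray]:
    return [V.base_matrix(b) for b in _CROSS_BASES]


def assemble_system(V: RelatednessSet, y1: np.ndarray, y2: np.ndarray) -> MoMSystem:
    """Build A and B from the block representation (no 4N x 4N products)."""
    n = V.n_rows
    if y1.shape != (n,) or y2.shape != (n,):
        raise ValueError("phenotype vectors must match the relatedness dimension")
    W = _within_mats(V)
    X = _cross_mats(V)
    A = np.zeros((14, 14))
    B = np.zeros(14)

    for i in range(4):
        for j in range(i, 4):
            # both matrices symmetric: tr(Wi Wj) = sum(Wi * Wj)
            t = float(np.vdot(W[i], W[j]))
            for grp in (_T1, _T2):
                A[grp[i], grp[j]] = A[grp[j], grp[i]] = t
    for i in range(6):
        for j in range(i, 6):
            # tr of the product of two cross placements = 2 tr(Xi Xj')
            t = 2.0 * float(np.vdot(X[i], X[j]))
            A[_CROSS[i], _CROSS[j]] = A[_CROSS[j], _CROSS[i]] = t

    for i in range(4):
        tr = float(np.trace(W[i]))
        B[_T1[i]] = float(y1 @ W[i] @ y1) - tr
        B[_T2[i]] = float(y2 @ W[i] @ y2) - tr
    for i in range(6):
        B[_CROSS[i]] = 2.0 * float(y1 @ X[i] @ y2)

    y = np.concatenate([y1, y2])
    yty = float(y @ y)
    c0 = yty * yty - 2.0 * yty + 2.0 * n
    return MoMSystem(A=A, B=B, c0=c0, n_rows=n)


def assemble_system_dense(V: RelatednessSet, y1: np.ndarray, y2: np.ndarray) -> MoMSystem:
    """Oracle path: materialize every 4N x 4N matrix and compute A, B directly."""
    y = np.concatenate([y1, y2])
    mats = [V.materialize(s) for s in range(14)]
    A = np.zeros((14, 14))
    B = np.zeros(14)
    for s in range(14):
        for t in range(s, 14):
            A[s, t] = A[t, s] = float(np.trace(mats[s] @ mats[t]))
        B[s] = float(y @ mats[s] @ y) - float(np.trace(mats[s]))
    resid = np.outer(y, y) - np.eye(y.size)
    c0 = float(np.vdot(resid, resid))
    return MoMSystem(A=A, B=B, c0=c0, n_rows=V.n_rows)


def solve_system(
    system: MoMSystem, cond_threshold: float = COND_THRESHOLD
) -> tuple[np.ndarray, bool]:
    """Solve A theta = B; fall back to minimum-norm least squares when
    ill-conditioned (returns the flag alongside the estimates)."""
    cond = system.condition_number
    if not np.isfinite(cond) or cond > cond_threshold:
        theta, *_ = np.linalg.lstsq(system.A, system.B, rcond=None)
        return theta, True
    theta = scipy.linalg.solve(system.A, system.B, assume_a="sym")
    return theta, False


def _standardize_traits(y1: np.ndarray, y2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return (y1 - y1.mean()) / y1.std(), (y2 - y2.mean()) / y2.std()


def prepare(
    cohort,
    phenos,
    covariates: np.ndarray | None = None,
    conv: Convention = VAR2,
    materialize_threshold: int = 4000,
) -> tuple[RelatednessSet, np.ndarray, np.ndarray]:
    """Standardize, optionally project covariates, and build relatedness.

    Returns the (possibly projected) relatedness set and trait vectors, the
    common front end of :func:`fit` and the block jackknife.
    """
    x_std, p_std = standardize(cohort.sib_geno, cohort.parent_sum, conv)
    V = build_relatedness(
        x_std, p_std, cohort.family_id, conv, materialize_threshold=materialize_threshold
    )
    y1, y2 = _standardize_traits(np.asarray(phenos.y1, float), np.asarray(phenos.y2, float))
    if covariates is not None:
        Q = covariate_projection(covariates)
        V = V.project(Q)
        y1, y2 = Q @ y1, Q @ y2
        # rescale to unit mean square; the projected space carries no intercept
        y1 = y1 / np.sqrt(np.mean(y1**2))
        y2 = y2 / np.sqrt(np.mean(y2**2))
    return V, y1, y2


def _finalize(
    theta_arr: np.ndarray,
    system: MoMSystem,
    conv: Convention,
    flagged: bool,
    n_families: int,
    n_snps: int,
) -> FitResult:
    theta = ParameterSet.from_array(theta_arr)
    g1, g2 = modeled_genetic_variance(theta, conv)
    ev1, ev2 = 1.0 - g1, 1.0 - g2
    negative = ev1 < 0 or ev2 < 0
    if negative:
        warnings.warn(
            "implied error variance is negative; estimates kept unclamped",
            RuntimeWarning,
            stacklevel=3,
        )
    h2_1, h2_2, rho_gc = reconstruct(theta)
    return FitResult(
        theta=theta,
        err_var_1=ev1,
        err_var_2=ev2,
        h2_1=h2_1,
        h2_2=h2_2,
        rho_gc=rho_gc,
        model_variance_1=g1,
        model_variance_2=g2,
        condition_number=system.condition_number,
        objective=system.objective(theta_arr),
        convention=conv,
        ill_conditioned=flagged,
        negative_error_variance=negative,
        n_families=n_families,
        n_snps=n_snps,
    )


def fit(
    cohort,
    phenos,
    covariates: np.ndarray | None = None,
    conv: Convention = VAR2,
    cond_threshold: float = COND_THRESHOLD,
) -> FitResult:
    """Full pipeline: standardize, project, assemble, solve, reconstruct."""
    V, y1, y2 = prepare(cohort, phenos, covariates, conv)
    system = assemble_system(V, y1, y2)
    theta_arr, flagged = solve_system(system, cond_threshold)
    return _finalize(theta_arr, system, conv, flagged, cohort.n_families, cohort.n_snps)


# ---------------------------------------------------------------------------
# leave-block-out systems for the jackknife


def _pair_stats(Mi: np.ndarray, Mj: np.ndarray, blocks, symmetric: bool) -> np.ndarray:
    """Trace of the elementwise product restricted to each leave-block-out set."""
    full = float(np.vdot(Mi, Mj))
    r = np.einsum("ij,ij->i", Mi, Mj)
    c = r if symmetric else np.einsum("ij,ij->j", Mi, Mj)
    out = np.empty(len(blocks))
    for k, b in enumerate(blocks):
        corner = float(np.vdot(Mi[np.ix_(b, b)], Mj[np.ix_(b, b)]))
        out[k] = full - r[b].sum() - c[b].sum() + corner
    return out


def _quad_stats(M: np.ndarray, ya: np.ndarray, yb: np.ndarray, blocks) -> np.ndarray:
    """ya' M yb restricted to each leave-block-out row set."""
    full = float(ya @ M @ yb)
    u = M @ yb
    v = M.T @ ya
    out = np.empty(len(blocks))
    for k, b in enumerate(blocks):
        corner = float(ya[b] @ M[np.ix_(b, b)] @ yb[b])
        out[k] = full - ya[b] @ u[b] - yb[b] @ v[b] + corner
    return out


def leave_block_systems(
    V: RelatednessSet, y1: np.ndarray, y2: np.ndarray, blocks: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Normal equations for every leave-one-block-out subset.

    ``blocks`` are disjoint row-index arrays (whole families).  Returns
    arrays of shape (n_blocks, 14, 14) and (n_blocks, 14) that agree exactly
    with :func:`assemble_system` run on the corresponding row subsets of the
    full-sample relatedness blocks.
    """
    nb = len(blocks)
    W = _within_mats(V)
    X = _cross_mats(V)
    A = np.zeros((nb, 14, 14))
    B = np.zeros((nb, 14))

    for i in range(4):
        for j in range(i, 4):
            t = _pair_stats(W[i], W[j], blocks, symmetric=True)
            for grp in (_T1, _T2):
                A[:, grp[i], grp[j]] = A[:, grp[j], grp[i]] = t
    for i in range(6):
        for j in range(i, 6):
            t = 2.0 * _pair_stats(X[i], X[j], blocks, symmetric=False)
            A[:, _CROSS[i], _CROSS[j]] = A[:, _CROSS[j], _CROSS[i]] = t

    for i in range(4):
        d = np.diag(W[i])
        tr_full = float(d.sum())
        tr = np.array([tr_full - d[b].sum() for b in blocks])
        B[:, _T1[i]] = _quad_stats(W[i], y1, y1, blocks) - tr
        B[:, _T2[i]] = _quad_stats(W[i], y2, y2, blocks) - tr
    for i in range(6):
        B[:, _CROSS[i]] = 2.0 * _quad_stats(X[i], y1, y2, blocks)

    return A, B


# ---------------------------------------------------------------------------
# leave-SNP-block-out systems
#
# Deleting a SNP block rescales K, G and C (S and the identity are untouched).
# Every trace the normal equations need reduces to sums over SNP-space Gram
# matrices, e.g. tr(K_J G_J) = sum_{j,k in J} (x_j' p_k)^2 / |J|^2 for a kept
# SNP set J, so the leave-block-out systems cost one column-space Gram product
# plus O(M^2) bookkeeping rather than a reassembly per block.


def _subset_sums(H: np.ndarray, blocks) -> np.ndarray:
    """sum of H over J x J for each leave-block-out SNP set J."""
    total = float(H.sum())
    r = H.sum(axis=1)
    c = H.sum(axis=0)
    out = np.empty(len(blocks))
    for k, b in enumerate(blocks):
        out[k] = total - r[b].sum() - c[b].sum() + float(H[np.ix_(b, b)].sum())
    return out


def _vector_subset_sums(v: np.ndarray, blocks) -> np.ndarray:
    total = float(v.sum())
    return np.array([total - v[b].sum() for b in blocks])


def leave_snp_block_systems(
    V: RelatednessSet, y1: np.ndarray, y2: np.ndarray, blocks: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Normal equations for every leave-one-SNP-block-out subset.

    ``blocks`` are disjoint SNP-index arrays.  The results agree exactly with
    :func:`assemble_system` run on relatedness blocks rebuilt from the
    corresponding SNP subsets of the standardized data.
    """
    if V.x_std is None or V.p_std is None:
        raise ValueError("relatedness set does not carry standardized matrices")
    x, p = V.x_std, V.p_std
    n2, M = x.shape
    nb = len(blocks)
    a, b_, dc = V.d_X, V.d_P, V.d_C
    S = V.S

    # S-side quantities (S is row-structure only, constant across SNP sets)
    if V.pairs is not None:
        swap = np.empty(n2, dtype=np.intp)
        swap[V.pairs[:, 0]] = V.pairs[:, 1]
        swap[V.pairs[:, 1]] = V.pairs[:, 0]
        Sx, Sp = x[swap], p[swap]
        Sy1, Sy2 = y1[swap], y2[swap]
        trS, trSS = 0.0, float(n2)
    else:
        Sx, Sp = S @ x, S @ p
        Sy1, Sy2 = S @ y1, S @ y2
        trS, trSS = float(np.trace(S)), float(np.vdot(S, S))

    # per-SNP scalars
    nx = np.einsum("ij,ij->j", x, x)
    npp = np.einsum("ij,ij->j", p, p)
    nxp = np.einsum("ij,ij->j", x, p)
    sx = np.einsum("ij,ij->j", x, Sx)
    spp = np.einsum("ij,ij->j", p, Sp)
    sxp = np.einsum("ij,ij->j", x, Sp)
    ax1, ax2 = x.T @ y1, x.T @ y2
    ap1, ap2 = p.T @ y1, p.T @ y2
    y11, y22, y12 = float(y1 @ y1), float(y2 @ y2), float(y1 @ y2)
    ys11, ys22, ys12 = float(y1 @ Sy1), float(y2 @ Sy2), float(y1 @ Sy2)

    # SNP-space Grams
    T = np.hstack([x, p])
    G2 = T.T @ T
    Gxx, Gxp, Gpp = G2[:M, :M], G2[:M, M:], G2[M:, M:]

    m = np.array([M - len(b) for b in blocks], dtype=float)
    trK = _vector_subset_sums(nx, blocks) / m
    trG = _vector_subset_sums(npp, blocks) / m
    trC = _vector_subset_sums(nxp, blocks) / m
    trKS = _vector_subset_sums(sx, blocks) / m
    trGS = _vector_subset_sums(spp, blocks) / m
    trCS = _vector_subset_sums(sxp, blocks) / m
    m2 = m * m
    trKK = _subset_sums(Gxx * Gxx, blocks) / m2
    trKG = _subset_sums(Gxp * Gxp, blocks) / m2
    trGG = _subset_sums(Gpp * Gpp, blocks) / m2
    trKC = _subset_sums(Gxx * Gxp, blocks) / m2  # = tr(K C) = tr(K C')
    trGC = _subset_sums(Gpp * Gxp, blocks) / m2  # = tr(G C) = tr(G C')
    trCCt = _subset_sums(Gxx * Gpp, blocks) / m2
    trCC = _subset_sums(Gxp * Gxp.T, blocks) / m2

    A = np.zeros((nb, 14, 14))
    B = np.zeros((nb, 14))

    # within-trait 4x4 (bases K-aI, G-bI, C+C'-2cI, S), identical for both traits
    tw = np.empty((nb, 4, 4))
    tw[:, 0, 0] = trKK - 2 * a * trK + a * a * n2
    tw[:, 0, 1] = tw[:, 1, 0] = trKG - b_ * trK - a * trG + a * b_ * n2
    tw[:, 0, 2] = tw[:, 2, 0] = 2 * trKC - 2 * dc * trK - 2 * a * trC + 2 * a * dc * n2
    tw[:, 1, 1] = trGG - 2 * b_ * trG + b_ * b_ * n2
    tw[:, 1, 2] = tw[:, 2, 1] = 2 * trGC - 2 * dc * trG - 2 * b_ * trC + 2 * b_ * dc * n2
    tw[:, 2, 2] = 2 * trCCt + 2 * trCC - 8 * dc * trC + 4 * dc * dc * n2
    tw[:, 0, 3] = tw[:, 3, 0] = trKS - a * trS
    tw[:, 1, 3] = tw[:, 3, 1] = trGS - b_ * trS
    tw[:, 2, 3] = tw[:, 3, 2] = 2 * trCS - 2 * dc * trS
    tw[:, 3, 3] = trSS
    for i in range(4):
        for j in range(4):
            A[:, _T1[i], _T1[j]] = tw[:, i, j]
            A[:, _T2[i], _T2[j]] = tw[:, i, j]

    # cross-trait 6x6 (bases K, G, C, C', I, S): entries 2 tr(Xi Xj')
    tc = np.empty((nb, 6, 6))
    tc[:, 0, 0] = trKK
    tc[:, 0, 1] = tc[:, 1, 0] = trKG
    tc[:, 0, 2] = tc[:, 2, 0] = trKC
    tc[:, 0, 3] = tc[:, 3, 0] = trKC
    tc[:, 0, 4] = tc[:, 4, 0] = trK
    tc[:, 0, 5] = tc[:, 5, 0] = trKS
    tc[:, 1, 1] = trGG
    tc[:, 1, 2] = tc[:, 2, 1] = trGC
    tc[:, 1, 3] = tc[:, 3, 1] = trGC
    tc[:, 1, 4] = tc[:, 4, 1] = trG
    tc[:, 1, 5] = tc[:, 5, 1] = trGS
    tc[:, 2, 2] = trCCt
    tc[:, 2, 3] = tc[:, 3, 2] = trCC
    tc[:, 2, 4] = tc[:, 4, 2] = trC
    tc[:, 2, 5] = tc[:, 5, 2] = trCS
    tc[:, 3, 3] = trCCt
    tc[:, 3, 4] = tc[:, 4, 3] = trC
    tc[:, 3, 5] = tc[:, 5, 3] = trCS
    tc[:, 4, 4] = float(n2)
    tc[:, 4, 5] = tc[:, 5, 4] = trS
    tc[:, 5, 5] = trSS
    for i in range(6):
        for j in range(6):
            A[:, _CROSS[i], _CROSS[j]] = 2.0 * tc[:, i, j]

    # B vector
    qx1 = _vector_subset_sums(ax1 * ax1, blocks) / m
    qp1 = _vector_subset_sums(ap1 * ap1, blocks) / m
    qxp1 = _vector_subset_sums(ax1 * ap1, blocks) / m
    qx2 = _vector_subset_sums(ax2 * ax2, blocks) / m
    qp2 = _vector_subset_sums(ap2 * ap2, blocks) / m
    qxp2 = _vector_subset_sums(ax2 * ap2, blocks) / m
    B[:, _T1[0]] = qx1 - a * y11 - trK + a * n2
    B[:, _T1[1]] = qp1 - b_ * y11 - trG + b_ * n2
    B[:, _T1[2]] = 2 * qxp1 - 2 * dc * y11 - 2 * trC + 2 * dc * n2
    B[:, _T1[3]] = ys11 - trS
    B[:, _T2[0]] = qx2 - a * y22 - trK + a * n2
    B[:, _T2[1]] = qp2 - b_ * y22 - trG + b_ * n2
    B[:, _T2[2]] = 2 * qxp2 - 2 * dc * y22 - 2 * trC + 2 * dc * n2
    B[:, _T2[3]] = ys22 - trS
    B[:, _CROSS[0]] = 2 * _vector_subset_sums(ax1 * ax2, blocks) / m
    B[:, _CROSS[1]] = 2 * _vector_subset_sums(ap1 * ap2, blocks) / m
    B[:, _CROSS[2]] = 2 * _vector_subset_sums(ax1 * ap2, blocks) / m
    B[:, _CROSS[3]] = 2 * _vector_subset_sums(ap1 * ax2, blocks) / m
    B[:, _CROSS[4]] = 2 * y12
    B[:, _CROSS[5]] = 2 * ys12

    return A, B
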