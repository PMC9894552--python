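"""Uncertainty quantification: block jackknife, Wald tests, FDR.

Analytic variances of the moment estimator can be unstable (and even turn
negative) at realistic sample sizes, so standard errors come from a
delete-one-block jackknife over families: var = (B-1)/B * sum_b
(theta_b - theta_bar)^2 across the B leave-block-out refits.  Blocks hold
whole families (both siblings co-assigned) and are contiguous after a
seeded shuffle so that ordered input data still yields exchangeable blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .fit import (
    FitResult,
    _finalize,
    assemble_system,
    covariate_projection,
    leave_block_systems,
    leave_snp_block_systems,
    prepare,
    solve_system,
)
from .model import Convention, VAR2, PARAM_NAMES, ParameterSet, reconstruct

__all__ = [
    "JackknifeResult",
    "jackknife_variance",
    "block_jackknife",
    "wald_test",
    "bh_fdr",
]


@dataclass
class JackknifeResult:
    """Jackknife SEs and tests for one fit."""

    fit: FitResult
    n_blocks: int
    block_estimates: np.ndarray  # (B, 14)
    se: np.ndarray  # (14,)
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    recon_se: np.ndarray  # SEs for (h2_1, h2_2, rho_gc)

    def as_dict(self) -> dict[str, dict[str, float]]:
        out = {}
        theta = self.fit.theta.to_array()
        for i, name in enumerate(PARAM_NAMES):
            out[name] = {
                "estimate": float(theta[i]),
                "se": float(self.se[i]),
                "z": float(self.z[i]),
                "p": float(self.p[i]),
                "q": float(self.q[i]),
            }
        for name, est, se in zip(
            ("h2_1", "h2_2", "rho_gc"),
            (self.fit.h2_1, self.fit.h2_2, self.fit.rho_gc),
            self.recon_se,
        ):
            z = est / se if se > 0 else np.nan
            p = 2.0 * norm.sf(abs(z)) if se > 0 else np.nan
            out[name] = {"estimate": float(est), "se": float(se), "z": float(z), "p": float(p)}
        return out


def jackknife_variance(block_estimates: np.ndarray, axis: int = 0) -> np.ndarray:
    """Delete-one-block jackknife variance, (B-1)/B * sum (est_b - mean)^2."""
    est = np.asarray(block_estimates, dtype=float)
    b = est.shape[axis]
    if b < 2:
        raise ValueError("jackknife needs at least 2 blocks")
    dev = est - est.mean(axis=axis, keepdims=True)
    return (b - 1) / b * np.sum(dev**2, axis=axis)


def _make_blocks(
    pairs: np.ndarray, n_blocks: int, seed: int | np.random.Generator | None
) -> list[np.ndarray]:
    """Partition families into near-equal contiguous blocks after a shuffle."""
    n_fam = pairs.shape[0]
    if not 2 <= n_blocks <= n_fam:
        raise ValueError(f"n_blocks must be in [2, {n_fam}], got {n_blocks}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_fam)
    return [pairs[fams].ravel() for fams in np.array_split(order, n_blocks)]


def block_jackknife(
    cohort,
    phenos,
    covariates: np.ndarray | None = None,
    conv: Convention = VAR2,
    n_blocks: int | None = None,
    seed: int | np.random.Generator | None = 0,
    cond_threshold: float = 1e8,
    axis: str = "snp",
) -> JackknifeResult:
    """Fit, then jackknife the fit over blocks of SNPs or of families.

    ``axis="snp"`` (default) deletes blocks of SNPs, rebuilding the
    relatedness blocks from the retained markers; this matches the moment
    structure of the estimator (the random effects are per-SNP) and gives
    calibrated standard errors for the covariance parameters, whose
    identification rests on cross-family realized-relatedness contrasts.
    ``axis="family"`` deletes blocks of whole families (both siblings
    co-assigned); it is exact for family-local parameters but over-counts
    the variance of cross-family product terms (up to twofold), making
    tests on the genetic covariance parameters conservative — see the
    methods notes.  Leave-block-out refits reuse the full-sample
    standardization and are computed by downdating; with covariates on the
    family axis each refit re-derives the projection on the retained rows.
    """
    if axis not in ("snp", "family"):
        raise ValueError(f"unknown jackknife axis {axis!r}")
    n_fam = cohort.n_families
    if n_blocks is None:
        n_blocks = min(100, cohort.n_snps if axis == "snp" else n_fam)

    V, y1, y2 = prepare(cohort, phenos, covariates=None, conv=conv)

    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != 2 * n_fam:
            covariates = covariates.T

    if axis == "snp":
        M = cohort.n_snps
        if not 2 <= n_blocks <= M:
            raise ValueError(f"n_blocks must be in [2, {M}], got {n_blocks}")
        rng = np.random.default_rng(seed)
        blocks = [np.sort(g) for g in np.array_split(rng.permutation(M), n_blocks)]
        if covariates is not None:
            Q = covariate_projection(covariates)
            V = V.project(Q)
            y1, y2 = Q @ y1, Q @ y2
            y1 = y1 / np.sqrt(np.mean(y1**2))
            y2 = y2 / np.sqrt(np.mean(y2**2))
        system = assemble_system(V, y1, y2)
        theta_arr, flagged = solve_system(system, cond_threshold)
        full = _finalize(theta_arr, system, conv, flagged, n_fam, cohort.n_snps)
        A_all, B_all = leave_snp_block_systems(V, y1, y2, blocks)
        thetas = np.empty((n_blocks, 14))
        for b in range(n_blocks):
            thetas[b], _ = solve_system(_SystemView(A_all[b], B_all[b]), cond_threshold)
    elif covariates is None:
        blocks = _make_blocks(V.pairs, n_blocks, seed)
        system = assemble_system(V, y1, y2)
        theta_arr, flagged = solve_system(system, cond_threshold)
        full = _finalize(theta_arr, system, conv, flagged, n_fam, cohort.n_snps)
        A_all, B_all = leave_block_systems(V, y1, y2, blocks)
        thetas = np.empty((n_blocks, 14))
        for b in range(n_blocks):
            sys_b = _SystemView(A_all[b], B_all[b])
            thetas[b], _ = solve_system(sys_b, cond_threshold)
    else:
        blocks = _make_blocks(V.pairs, n_blocks, seed)
        Q = covariate_projection(covariates)
        Vp = V.project(Q)
        y1p, y2p = Q @ y1, Q @ y2
        y1p = y1p / np.sqrt(np.mean(y1p**2))
        y2p = y2p / np.sqrt(np.mean(y2p**2))
        system = assemble_system(Vp, y1p, y2p)
        theta_arr, flagged = solve_system(system, cond_threshold)
        full = _finalize(theta_arr, system, conv, flagged, n_fam, cohort.n_snps)
        thetas = np.empty((n_blocks, 14))
        all_rows = np.arange(2 * n_fam)
        for b, held in enumerate(blocks):
            rows = np.setdiff1d(all_rows, held)
            Vb = V.take(rows)
            Qb = covariate_projection(covariates[rows])
            Vb = Vb.project(Qb)
            y1b, y2b = Qb @ y1[rows], Qb @ y2[rows]
            y1b = y1b / np.sqrt(np.mean(y1b**2))
            y2b = y2b / np.sqrt(np.mean(y2b**2))
            system = assemble_system(Vb, y1b, y2b)
            thetas[b], _ = solve_system(system, cond_threshold)

    se = np.sqrt(jackknife_variance(thetas))
    z, p = wald_test(full.theta.to_array(), se)
    q = bh_fdr(p)
    recon_blocks = np.array([reconstruct(ParameterSet.from_array(t)) for t in thetas])
    recon_se = np.sqrt(jackknife_variance(recon_blocks))
    return JackknifeResult(
        fit=full,
        n_blocks=n_blocks,
        block_estimates=thetas,
        se=se,
        z=z,
        p=p,
        q=q,
        recon_se=recon_se,
    )


class _SystemView:
    """Minimal stand-in exposing what solve_system needs."""

    def __init__(self, A: np.ndarray, B: np.ndarray):
        self.A = A
        self.B = B

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.A))


def wald_test(theta: np.ndarray, se: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """z = theta / SE and two-sided normal p-values; p is NaN where SE = 0."""
    theta = np.asarray(theta, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, theta / se, np.nan)
    p = np.where(np.isfinite(z), 2.0 * norm.sf(np.abs(z)), np.nan)
    return z, p


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvals, dtype=float)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
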