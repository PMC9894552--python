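"""Synthetic nuclear families under random mating and the two-trait model.

Families consist of two parents drawn under Hardy-Weinberg equilibrium and
two full siblings produced by explicit Mendelian transmission (each parent
passes one allele per SNP to each child independently, with probability of
the alternative allele equal to dosage / 2).  SNPs are independent (no LD)
with allele frequencies uniform on a MAF window.  Phenotypes follow the
additive model of :mod:`parsec.model`: per-SNP effect 4-vectors drawn from
N(0, Omega / M) and per-family error 4-vectors from the sibling/trait error
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Convention, VAR2, ValidatedParameters
from .relatedness import standardize

__all__ = [
    "FamilyCohort",
    "PhenotypePair",
    "simulate_families",
    "simulate_phenotypes",
    "impute_parental_sum",
]


@dataclass
class FamilyCohort:
    """Sibling genotypes and parental sums for N two-child families.

    Rows are ordered (sib1, sib2) per family, families contiguous.  The two
    rows of a family carry identical ``parent_sum`` (integer 0..4 when
    observed, real-valued when imputed).
    """

    sib_geno: np.ndarray
    parent_sum: np.ndarray
    allele_freq: np.ndarray
    family_id: np.ndarray
    father: np.ndarray | None = None
    mother: np.ndarray | None = None

    @property
    def n_families(self) -> int:
        return self.sib_geno.shape[0] // 2

    @property
    def n_snps(self) -> int:
        return self.sib_geno.shape[1]

    def with_imputed_parents(self) -> "FamilyCohort":
        """Replace parental sums by their single-SNP posterior expectation."""
        from .relatedness import family_blocks

        pairs = family_blocks(self.family_id)
        g1 = self.sib_geno[pairs[:, 0]]
        g2 = self.sib_geno[pairs[:, 1]]
        imp = impute_parental_sum(g1, g2, self.allele_freq[None, :])
        parent_sum = np.empty(self.sib_geno.shape, dtype=float)
        parent_sum[pairs[:, 0]] = imp
        parent_sum[pairs[:, 1]] = imp
        return FamilyCohort(
            sib_geno=self.sib_geno,
            parent_sum=parent_sum,
            allele_freq=self.allele_freq,
            family_id=self.family_id,
            father=self.father,
            mother=self.mother,
        )


@dataclass
class PhenotypePair:
    """Two standardized trait vectors aligned to the cohort rows."""

    y1: np.ndarray
    y2: np.ndarray

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.y1, self.y2])


def simulate_families(
    n_families: int,
    n_snps: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int | np.random.Generator | None = None,
) -> FamilyCohort:
    """Draw a cohort of two-sibling families by Mendelian transmission."""
    if not (0.0 < maf_low <= maf_high < 1.0):
        raise ValueError(f"invalid MAF bounds ({maf_low}, {maf_high})")
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=n_snps)
    father = rng.binomial(2, p, size=(n_families, n_snps))
    mother = rng.binomial(2, p, size=(n_families, n_snps))
    sibs = np.empty((2 * n_families, n_snps), dtype=np.int64)
    for child in range(2):
        from_f = rng.binomial(1, father / 2.0)
        from_m = rng.binomial(1, mother / 2.0)
        sibs[child::2] = from_f + from_m
    parent_sum = np.repeat(father + mother, 2, axis=0)
    family_id = np.repeat([f"F{i:06d}" for i in range(n_families)], 2)
    return FamilyCohort(
        sib_geno=sibs,
        parent_sum=parent_sum,
        allele_freq=p,
        family_id=np.asarray(family_id),
        father=father,
        mother=mother,
    )


def _psd_sqrt(cov: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(cov)
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_phenotypes(
    cohort: FamilyCohort,
    theta: ValidatedParameters,
    conv: Convention = VAR2,
    seed: int | np.random.Generator | None = None,
    split_parent: tuple[float, float] | None = None,
    standardize_traits: bool = True,
) -> PhenotypePair:
    """Generate the two traits for a cohort under validated parameters.

    With ``split_parent=(var_ind_pat, var_ind_mat)`` the trait-1 indirect
    path uses separate paternal and maternal effects on the separately
    standardized parental genotypes (requires parental truth in the cohort);
    the combined-model trait-1 indirect parameters in ``theta`` are ignored
    and the trait-1 error variance is rederived from the split variances.

    ``standardize_traits=False`` skips the final in-sample standardization,
    leaving traits on the scale whose covariance is exactly
    I + sum_s theta_s V_s conditional on the genotypes.
    """
    rng = np.random.default_rng(seed)
    n2, m = cohort.sib_geno.shape
    x_std, p_std = standardize(cohort.sib_geno, cohort.parent_sum, conv)

    effects = _psd_sqrt(theta.omega() / m) @ rng.standard_normal(size=(4, m))
    a1, a2, b1, b2 = effects
    g1 = x_std @ a1 + p_std @ b1
    g2 = x_std @ a2 + p_std @ b2

    err_var_1 = theta.err_var_1
    if split_parent is not None:
        if cohort.father is None or cohort.mother is None:
            raise ValueError("split-parent generation requires parental truth")
        var_pat, var_mat = split_parent
        fp = np.repeat(cohort.father, 2, axis=0)
        fm = np.repeat(cohort.mother, 2, axis=0)
        from .relatedness import _standardize_columns

        fp_std = _standardize_columns(fp, 1.0)
        fm_std = _standardize_columns(fm, 1.0)
        bp = rng.standard_normal(m) * np.sqrt(var_pat / m)
        bm = rng.standard_normal(m) * np.sqrt(var_mat / m)
        g1 = x_std @ a1 + fp_std @ bp + fm_std @ bm
        err_var_1 = 1.0 - theta.var_dir_1 * conv.d_X - var_pat - var_mat
        if err_var_1 < 0:
            raise ValueError("split-parent variances exceed unit trait variance")

    ecov = theta.error_covariance(err_var_1, theta.err_var_2)
    # per-family 4-vector (sib1 t1, sib2 t1, sib1 t2, sib2 t2)
    eps = rng.standard_normal(size=(n2 // 2, 4)) @ _psd_sqrt(ecov).T
    e1 = eps[:, :2].reshape(n2)
    e2 = eps[:, 2:].reshape(n2)

    y1 = g1 + e1
    y2 = g2 + e2
    if standardize_traits:
        y1 = (y1 - y1.mean()) / y1.std()
        y2 = (y2 - y2.mean()) / y2.std()
    return PhenotypePair(y1=y1, y2=y2)


def _transmission_prob(child: np.ndarray, g_f: int, g_m: int) -> np.ndarray:
    """P(child dosage | parental genotypes) under Mendelian transmission."""
    pf, pm = g_f / 2.0, g_m / 2.0
    child = np.asarray(child, dtype=float)
    # a missing child dosage is uninformative about the parents
    default = np.where(np.isnan(child), 1.0, 0.0)
    probs = np.select(
        [child == 0, child == 1, child == 2],
        [
            (1 - pf) * (1 - pm),
            pf * (1 - pm) + (1 - pf) * pm,
            pf * pm,
        ],
        default=0.0,
    )
    return probs + default


def impute_parental_sum(g1, g2, p):
    """E[father + mother dosage | two sibling dosages] under HWE priors.

    Exact enumeration over the nine parental genotype pairs with HWE prior
    {(1-p)^2, 2p(1-p), p^2} per parent and conditionally independent
    Mendelian transmission to the two siblings.  Broadcasts over arrays.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequency must lie strictly inside (0, 1)")
    hwe = [(1 - p) ** 2, 2 * p * (1 - p), p ** 2]
    num = np.zeros(np.broadcast(g1, g2, p).shape)
    den = np.zeros_like(num)
    for gf in range(3):
        for gm in range(3):
            w = hwe[gf] * hwe[gm] * _transmission_prob(g1, gf, gm) * _transmission_prob(g2, gf, gm)
            num = num + w * (gf + gm)
            den = den + w
    return num / den
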