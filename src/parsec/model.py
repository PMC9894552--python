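"""Statistical model for the direct/indirect decomposition of two traits.

The model assumes, for each sibling in a nuclear family,

    y1 = X a1 + (Xp + Xm) b1 + e1
    y2 = X a2 + (Xp + Xm) b2 + e2

where ``X`` is the individual's own standardized genotype, ``Xp + Xm`` the
standardized sum of parental genotypes, ``a`` direct and ``b`` indirect
(parental) per-SNP random effects, and ``e`` an error term correlated both
across siblings (shared environment) and across traits.  The per-SNP effect
4-vector (a1, a2, b1, b2) is i.i.d. N(0, Omega / M); Omega is assembled from
the ten genetic parameters.  The error 4-vector of a sibling pair and trait
pair is N(0, [[S1, S12], [S12', S2]]) with

    Sk  = [[s2_ek, r_ek], [r_ek, s2_ek]]      (within trait k)
    S12 = [[eta, delta], [delta, eta]]        (across traits)

Error variances s2_e1, s2_e2 are not free: phenotypes are standardized to
unit variance, so each is one minus the trait's modeled genetic variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "Convention",
    "VAR2",
    "VAR1",
    "ParameterSet",
    "ValidatedParameters",
    "NonPSDError",
    "NegativeErrorVarianceError",
    "validate_parameters",
    "model_covariance",
    "reconstruct",
]

#: canonical parameter order used for vectors, the normal equations and reports
PARAM_NAMES = (
    "var_dir_1",
    "var_dir_2",
    "var_ind_1",
    "var_ind_2",
    "cov_dir",
    "cov_ind",
    "cov_dir_ind_11",
    "cov_dir_ind_22",
    "cov_dir1_ind2",
    "cov_dir2_ind1",
    "err_sib_cov_1",
    "err_sib_cov_2",
    "err_cross_same",
    "err_cross_sib",
)

#: PSD slack for eigenvalue checks
PSD_TOL = 1e-10


@dataclass(frozen=True)
class Convention:
    """Standardization convention for the parental genotype sum.

    ``var2`` scales the parental-sum columns to in-sample variance 2 (the
    natural scale of a sum of two independent unit-variance genotypes under
    random mating); ``var1`` scales them to variance 1.  The choice fixes the
    nominal diagonals of the three relatedness matrices: d_X for X X'/M,
    d_P for P P'/M and d_C for X P'/M.
    """

    parental_scale: str = "var2"

    def __post_init__(self) -> None:
        if self.parental_scale not in ("var2", "var1"):
            raise ValueError(f"unknown parental_scale {self.parental_scale!r}")

    @property
    def d_X(self) -> float:
        return 1.0

    @property
    def d_P(self) -> float:
        return 2.0 if self.parental_scale == "var2" else 1.0

    @property
    def d_C(self) -> float:
        # corr(child, parental sum) = 1 on the var-2 scale, 1/sqrt(2) on var-1
        return 1.0 if self.parental_scale == "var2" else 1.0 / math.sqrt(2.0)


VAR2 = Convention("var2")
VAR1 = Convention("var1")


@dataclass(frozen=True)
class ParameterSet:
    """The 14 free parameters, all on the standardized-trait scale.

    Genetic block (first ten): per-trait direct/indirect effect variances,
    the direct-direct and indirect-indirect cross-trait covariances, and the
    four direct-indirect covariances.  Error block (last four): sibling
    shared-environment covariance per trait, and the same-individual /
    cross-sibling cross-trait error covariances.
    """

    var_dir_1: float = 0.0
    var_dir_2: float = 0.0
    var_ind_1: float = 0.0
    var_ind_2: float = 0.0
    cov_dir: float = 0.0
    cov_ind: float = 0.0
    cov_dir_ind_11: float = 0.0
    cov_dir_ind_22: float = 0.0
    cov_dir1_ind2: float = 0.0
    cov_dir2_ind1: float = 0.0
    err_sib_cov_1: float = 0.0
    err_sib_cov_2: float = 0.0
    err_cross_same: float = 0.0
    err_cross_sib: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "ParameterSet":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (14,):
            raise ValueError(f"expected 14 parameters, got shape {theta.shape}")
        return cls(**dict(zip(PARAM_NAMES, theta.tolist())))

    def omega(self) -> np.ndarray:
        """4x4 joint covariance of per-SNP effects, order (a1, a2, b1, b2)."""
        return np.array(
            [
                [self.var_dir_1, self.cov_dir, self.cov_dir_ind_11, self.cov_dir1_ind2],
                [self.cov_dir, self.var_dir_2, self.cov_dir2_ind1, self.cov_dir_ind_22],
                [self.cov_dir_ind_11, self.cov_dir2_ind1, self.var_ind_1, self.cov_ind],
                [self.cov_dir1_ind2, self.cov_dir_ind_22, self.cov_ind, self.var_ind_2],
            ]
        )

    def error_covariance(self, err_var_1: float, err_var_2: float) -> np.ndarray:
        """4x4 error covariance of a sibling pair, order (s1t1, s2t1, s1t2, s2t2)."""
        s1 = np.array([[err_var_1, self.err_sib_cov_1], [self.err_sib_cov_1, err_var_1]])
        s2 = np.array([[err_var_2, self.err_sib_cov_2], [self.err_sib_cov_2, err_var_2]])
        s12 = np.array(
            [[self.err_cross_same, self.err_cross_sib], [self.err_cross_sib, self.err_cross_same]]
        )
        return np.block([[s1, s12], [s12.T, s2]])


@dataclass(frozen=True)
class ValidatedParameters(ParameterSet):
    """A :class:`ParameterSet` that passed validation, with the implied
    error variances attached."""

    err_var_1: float = 1.0
    err_var_2: float = 1.0


class NonPSDError(ValueError):
    """A model covariance block is not positive semi-definite."""


class NegativeErrorVarianceError(ValueError):
    """Modeled genetic variance exceeds the unit phenotypic variance."""


def modeled_genetic_variance(theta: ParameterSet, conv: Convention) -> tuple[float, float]:
    """Per-trait genetic variance implied by the model under ``conv``.

    This is the quantity subtracted from 1 to obtain the error variance:
    s2_a * d_X + s2_b * d_P + 2 * r_ab * d_C for each trait.
    """
    g1 = (
        theta.var_dir_1 * conv.d_X
        + theta.var_ind_1 * conv.d_P
        + 2.0 * theta.cov_dir_ind_11 * conv.d_C
    )
    g2 = (
        theta.var_dir_2 * conv.d_X
        + theta.var_ind_2 * conv.d_P
        + 2.0 * theta.cov_dir_ind_22 * conv.d_C
    )
    return g1, g2


def validate_parameters(
    theta: ParameterSet, conv: Convention = VAR2, tol: float = PSD_TOL
) -> ValidatedParameters:
    """Check model validity and derive the implied error variances.

    Raises :class:`NonPSDError` if the 4x4 effect covariance or the 4x4
    error covariance has an eigenvalue below ``-tol``, and
    :class:`NegativeErrorVarianceError` if a trait's modeled genetic
    variance exceeds 1.
    """
    arr = theta.to_array()
    if not np.all(np.isfinite(arr)):
        raise ValueError("parameters must be finite")

    omega = theta.omega()
    w = np.linalg.eigvalsh(omega)
    if w.min() < -tol:
        raise NonPSDError(f"effect covariance has eigenvalue {w.min():.3g} < 0")

    g1, g2 = modeled_genetic_variance(theta, conv)
    ev1, ev2 = 1.0 - g1, 1.0 - g2
    if ev1 < -tol or ev2 < -tol:
        raise NegativeErrorVarianceError(
            f"implied error variances ({ev1:.4f}, {ev2:.4f}) are negative"
        )
    ev1, ev2 = max(ev1, 0.0), max(ev2, 0.0)

    ecov = theta.error_covariance(ev1, ev2)
    w = np.linalg.eigvalsh(ecov)
    if w.min() < -tol:
        raise NonPSDError(f"error covariance has eigenvalue {w.min():.3g} < 0")

    return ValidatedParameters(
        **{n: getattr(theta, n) for n in PARAM_NAMES}, err_var_1=ev1, err_var_2=ev2
    )


def model_covariance(theta: ParameterSet, relatedness) -> np.ndarray:
    """Model-implied covariance of the stacked phenotype vector y = [y1; y2].

    Returns the dense 4N x 4N matrix I + sum_s theta_s V_s, where the V_s are
    the per-parameter relatedness matrices of ``relatedness``
    (a :class:`parsec.relatedness.RelatednessSet`).
    """
    n = 2 * relatedness.n_rows
    cov = np.eye(n)
    for s, th in enumerate(theta.to_array()):
        if th != 0.0:
            cov += th * relatedness.materialize(s)
    return (cov + cov.T) / 2.0


def reconstruct(theta: ParameterSet) -> tuple[float, float, float]:
    """Total heritabilities and genetic covariance from the decomposition.

    h2_k = s2_ak + s2_bk + 2 r_akbk for each trait, and
    rho_gc = r_a + r_b + r_a1b2 + r_a2b1.
    """
    h2_1 = theta.var_dir_1 + theta.var_ind_1 + 2.0 * theta.cov_dir_ind_11
    h2_2 = theta.var_dir_2 + theta.var_ind_2 + 2.0 * theta.cov_dir_ind_22
    rho_gc = theta.cov_dir + theta.cov_ind + theta.cov_dir1_ind2 + theta.cov_dir2_ind1
    return h2_1, h2_2, rho_gc


def swap_traits(theta: ParameterSet) -> ParameterSet:
    """Map parameters under a (trait1, trait2) relabeling."""
    return replace(
        theta,
        var_dir_1=theta.var_dir_2,
        var_dir_2=theta.var_dir_1,
        var_ind_1=theta.var_ind_2,
        var_ind_2=theta.var_ind_1,
        cov_dir_ind_11=theta.cov_dir_ind_22,
        cov_dir_ind_22=theta.cov_dir_ind_11,
        cov_dir1_ind2=theta.cov_dir2_ind1,
        cov_dir2_ind1=theta.cov_dir1_ind2,
        err_sib_cov_1=theta.err_sib_cov_2,
        err_sib_cov_2=theta.err_sib_cov_1,
    )
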