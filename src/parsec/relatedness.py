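"""Genotype standardization and per-parameter relatedness matrices.

Each of the 14 model parameters has an associated 4N x 4N relatedness matrix
V_s such that cov(y) = I + sum_s theta_s V_s for the stacked phenotype
vector y = [y1; y2].  All of them are built from four 2N x 2N blocks:

    K = X X' / M      own-genotype relatedness (GRM)
    G = P P' / M      parental-sum relatedness
    C = X P' / M      child-parent cross relatedness
    S                 sibling indicator (1 between the two sibs of a family)

plus the convention's nominal diagonals (d_X, d_P, d_C), subtracted on the
diagonal of within-trait components so that the error-variance substitution
(unit phenotypic variance) holds.  The set is stored in this block form;
full 4N x 4N matrices are materialized only for moderate N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PARAM_NAMES, Convention, VAR2

__all__ = [
    "MonomorphicColumnError",
    "standardize",
    "RelatednessSet",
    "build_relatedness",
    "family_blocks",
]

# placement of each parameter: ("11"|"22") within-trait or "12" cross-trait,
# and which base matrix it carries.  Within-trait bases subtract the nominal
# diagonal; cross-trait bases do not.
_PLACEMENT = {
    "var_dir_1": ("11", "K-d"),
    "var_dir_2": ("22", "K-d"),
    "var_ind_1": ("11", "G-d"),
    "var_ind_2": ("22", "G-d"),
    "cov_dir": ("12", "K"),
    "cov_ind": ("12", "G"),
    "cov_dir_ind_11": ("11", "CCt-d"),
    "cov_dir_ind_22": ("22", "CCt-d"),
    "cov_dir1_ind2": ("12", "C"),
    "cov_dir2_ind1": ("12", "Ct"),
    "err_sib_cov_1": ("11", "S"),
    "err_sib_cov_2": ("22", "S"),
    "err_cross_same": ("12", "I"),
    "err_cross_sib": ("12", "S"),
}


class MonomorphicColumnError(ValueError):
    """A genotype column has zero in-sample variance and cannot be standardized."""


def _standardize_columns(mat: np.ndarray, target_var: float) -> np.ndarray:
    """Center columns, scale to in-sample variance ``target_var``, zero missing.

    Means and variances are computed over observed (non-NaN) entries; missing
    entries become exactly 0 after centering.
    """
    mat = np.asarray(mat, dtype=float)
    mean = np.nanmean(mat, axis=0)
    var = np.nanvar(mat, axis=0)
    bad = ~(var > 0)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise MonomorphicColumnError(
            f"column {idx} is monomorphic (zero variance); filter before standardizing"
        )
    out = (mat - mean) / np.sqrt(var / target_var)
    return np.nan_to_num(out, nan=0.0, copy=False)


def standardize(
    sib_geno: np.ndarray, parent_sum: np.ndarray, conv: Convention = VAR2
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize sibling genotypes to variance 1 and parental sums to d_P."""
    x_std = _standardize_columns(sib_geno, 1.0)
    p_std = _standardize_columns(parent_sum, conv.d_P)
    return x_std, p_std


def family_blocks(family_id: np.ndarray) -> np.ndarray:
    """Row-index pairs (n_families x 2) grouping rows by family label.

    Every family must contribute exactly two rows.
    """
    family_id = np.asarray(family_id)
    order = {}
    for i, fid in enumerate(family_id):
        order.setdefault(fid, []).append(i)
    pairs = []
    for fid, rows in order.items():
        if len(rows) != 2:
            raise ValueError(f"family {fid!r} has {len(rows)} rows; exactly 2 required")
        pairs.append(rows)
    return np.asarray(pairs, dtype=np.intp)


def _sibling_indicator(pairs: np.ndarray, n: int) -> np.ndarray:
    s = np.zeros((n, n))
    s[pairs[:, 0], pairs[:, 1]] = 1.0
    s[pairs[:, 1], pairs[:, 0]] = 1.0
    return s


@dataclass
class RelatednessSet:
    """The block representation of all 14 relatedness matrices."""

    K: np.ndarray
    G: np.ndarray
    C: np.ndarray
    S: np.ndarray
    d_X: float
    d_P: float
    d_C: float
    #: n_families x 2 row indices, or None after covariate projection
    pairs: np.ndarray | None = None
    materialize_threshold: int = 4000
    #: standardized genotype / parental-sum matrices behind K, G, C
    #: (projected along with the blocks; needed for SNP-block resampling)
    x_std: np.ndarray | None = None
    p_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.K.shape[0]
        for name in ("K", "G", "C", "S"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise ValueError(f"{name} has shape {m.shape}, expected {(n, n)}")

    @property
    def n_rows(self) -> int:
        return self.K.shape[0]

    def base_matrix(self, s: int | str) -> np.ndarray:
        """The 2N x 2N block carried by parameter ``s`` (index, name, or base
        code such as ``"K-d"``; dense copy for the ``-d`` forms)."""
        if isinstance(s, int):
            base = _PLACEMENT[PARAM_NAMES[s]][1]
        elif s in _PLACEMENT:
            base = _PLACEMENT[s][1]
        else:
            base = s
        n = self.n_rows
        if base == "K":
            return self.K
        if base == "G":
            return self.G
        if base == "C":
            return self.C
        if base == "Ct":
            return self.C.T
        if base == "S":
            return self.S
        if base == "I":
            return np.eye(n)
        if base == "K-d":
            return self.K - self.d_X * np.eye(n)
        if base == "G-d":
            return self.G - self.d_P * np.eye(n)
        if base == "CCt-d":
            return self.C + self.C.T - 2.0 * self.d_C * np.eye(n)
        raise AssertionError(base)

    def placement(self, s: int | str) -> str:
        name = PARAM_NAMES[s] if isinstance(s, int) else s
        return _PLACEMENT[name][0]

    def materialize(self, s: int | str) -> np.ndarray:
        """Dense 4N x 4N relatedness matrix for parameter ``s``.

        Guarded by ``materialize_threshold`` on the row count: every trace and
        quadratic form needed for fitting reduces to block operations, so the
        dense form exists for oracle tests and small-sample inspection only.
        """
        n = self.n_rows
        if n > self.materialize_threshold:
            raise ValueError(
                f"refusing to materialize a {2 * n} x {2 * n} matrix "
                f"(threshold {self.materialize_threshold} rows)"
            )
        a = self.base_matrix(s)
        out = np.zeros((2 * n, 2 * n))
        place = self.placement(s)
        if place == "11":
            out[:n, :n] = a
        elif place == "22":
            out[n:, n:] = a
        else:
            out[:n, n:] = a
            out[n:, :n] = a.T
        return out

    def project(self, Q: np.ndarray) -> "RelatednessSet":
        """Replace every block A by Q A Q' (covariate projection).

        The identity block stays the identity because Q has orthonormal rows,
        so the same assembly rules apply in the projected space.  Family
        pairing is no longer meaningful afterwards.
        """
        return RelatednessSet(
            K=Q @ self.K @ Q.T,
            G=Q @ self.G @ Q.T,
            C=Q @ self.C @ Q.T,
            S=Q @ self.S @ Q.T,
            d_X=self.d_X,
            d_P=self.d_P,
            d_C=self.d_C,
            pairs=None,
            materialize_threshold=self.materialize_threshold,
            x_std=Q @ self.x_std if self.x_std is not None else None,
            p_std=Q @ self.p_std if self.p_std is not None else None,
        )

    def take(self, rows: np.ndarray) -> "RelatednessSet":
        """Restrict to a row subset (used by leave-block-out refits)."""
        ix = np.ix_(rows, rows)
        sub = RelatednessSet(
            K=self.K[ix],
            G=self.G[ix],
            C=self.C[ix],
            S=self.S[ix],
            d_X=self.d_X,
            d_P=self.d_P,
            d_C=self.d_C,
            pairs=None,
            materialize_threshold=self.materialize_threshold,
            x_std=self.x_std[rows] if self.x_std is not None else None,
            p_std=self.p_std[rows] if self.p_std is not None else None,
        )
        return sub


def build_relatedness(
    x_std: np.ndarray,
    p_std: np.ndarray,
    family_id: np.ndarray,
    conv: Convention = VAR2,
    materialize_threshold: int = 4000,
) -> RelatednessSet:
    """Assemble K, G, C and the sibling indicator from standardized data."""
    if x_std.shape != p_std.shape:
        raise ValueError("genotype and parental-sum matrices must share a shape")
    n, m = x_std.shape
    if len(family_id) != n:
        raise ValueError("family_id length must match the number of rows")
    pairs = family_blocks(family_id)
    # one symmetric rank-k update yields all three products
    stacked = np.vstack([x_std, p_std])
    prod = (stacked @ stacked.T) / m
    K = prod[:n, :n]
    G = prod[n:, n:]
    C = prod[:n, n:]
    return RelatednessSet(
        K=K,
        G=G,
        C=C,
        S=_sibling_indicator(pairs, n),
        d_X=conv.d_X,
        d_P=conv.d_P,
        d_C=conv.d_C,
        pairs=pairs,
        materialize_threshold=materialize_threshold,
        x_std=x_std,
        p_std=p_std,
    )
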