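"""Text formats: PLINK .raw-style genotype tables, phenotype TSVs, configs.

Genotypes travel as whitespace-delimited text with the PLINK additive-coding
header (FID IID PAT MAT SEX PHENOTYPE, then one column per SNP named
SNP_ALLELE) and dosages in {0, 1, 2, NA}; parental sums use the same dialect
with values in [0, 4].  Phenotypes and covariates are TSVs keyed by
(FID, IID).  Missing phenotypes drop the whole family, preserving the
sibling-pair structure the estimator relies on.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import PARAM_NAMES, ParameterSet
from .simulate import FamilyCohort, PhenotypePair

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "filter_snps",
    "read_parameter_file",
    "config_hash",
]

logger = logging.getLogger("parsec")

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class GenotypeTable:
    """A parsed .raw-style file: dosage matrix plus identifiers."""

    dosages: np.ndarray  # (n, m), float with NaN for missing
    fid: np.ndarray
    iid: np.ndarray
    snp_names: list[str]


def read_genotypes(path: str | Path, max_dosage: float = 2.0) -> GenotypeTable:
    """Read a .raw-style dosage table; NA entries become NaN.

    ``max_dosage`` is 2 for individual genotypes, 4 for parental-sum files.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", dtype={"FID": str, "IID": str})
    missing = [c for c in _RAW_META if c not in df.columns[: len(_RAW_META)].tolist()]
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {missing}")
    snp_cols = [c for c in df.columns if c not in _RAW_META]
    if not snp_cols:
        raise ValueError(f"{path}: no SNP columns after the six metadata columns")
    dup = df.duplicated(subset=["FID", "IID"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (FID, IID) at row {int(dup.idxmax())}")
    dosages = df[snp_cols].to_numpy(dtype=float)
    finite = dosages[np.isfinite(dosages)]
    if finite.size and (finite.min() < 0 or finite.max() > max_dosage):
        bad = np.argwhere(
            np.isfinite(dosages) & ((dosages < 0) | (dosages > max_dosage))
        )[0]
        raise ValueError(
            f"{path}: dosage {dosages[tuple(bad)]} outside [0, {max_dosage}] at "
            f"row {bad[0]} column {snp_cols[bad[1]]}"
        )
    return GenotypeTable(
        dosages=dosages,
        fid=df["FID"].to_numpy(),
        iid=df["IID"].to_numpy(),
        snp_names=snp_cols,
    )


def write_genotypes(
    path: str | Path,
    dosages: np.ndarray,
    fid: np.ndarray,
    iid: np.ndarray,
    snp_names: list[str] | None = None,
) -> None:
    dosages = np.asarray(dosages)
    n, m = dosages.shape
    if snp_names is None:
        snp_names = [f"snp{j}_A" for j in range(m)]
    df = pd.DataFrame(
        {
            "FID": fid,
            "IID": iid,
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENOTYPE": -9,
        }
    )
    body = pd.DataFrame(dosages, columns=snp_names)
    pd.concat([df, body], axis=1).to_csv(path, sep=" ", index=False, na_rep="NA")


def write_phenotypes(
    path: str | Path,
    fid: np.ndarray,
    iid: np.ndarray,
    y1: np.ndarray,
    y2: np.ndarray,
    trait_names: tuple[str, str] = ("trait1", "trait2"),
    covariates: pd.DataFrame | None = None,
) -> None:
    df = pd.DataFrame({"FID": fid, "IID": iid, trait_names[0]: y1, trait_names[1]: y2})
    if covariates is not None:
        df = pd.concat([df, covariates.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(
    path: str | Path,
    geno: GenotypeTable,
    trait_cols: tuple[str, str] | None = None,
    covariate_cols: list[str] | None = None,
) -> tuple[np.ndarray, PhenotypePair, np.ndarray | None, np.ndarray]:
    """Read a phenotype TSV and align it to the genotype rows.

    Families with any missing phenotype (either sibling, either trait) are
    dropped entirely.  Returns (row_index_into_geno, phenotypes, covariate
    matrix or None, family_id).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    for c in ("FID", "IID"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing required column {c}")
    value_cols = [c for c in df.columns if c not in ("FID", "IID")]
    if trait_cols is None:
        if len(value_cols) < 2:
            raise ValueError(f"{path}: need at least two trait columns")
        trait_cols = (value_cols[0], value_cols[1])
    for c in trait_cols + tuple(covariate_cols or ()):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c}")

    key = pd.DataFrame({"FID": geno.fid, "IID": geno.iid, "_row": np.arange(len(geno.fid))})
    merged = key.merge(df, on=["FID", "IID"], how="left", validate="one_to_one")
    if merged["_row"].isna().any():
        raise ValueError(f"{path}: phenotype rows do not match genotype IDs")

    used = list(trait_cols) + list(covariate_cols or ())
    bad_row = merged[used].isna().any(axis=1)
    bad_fam = set(merged.loc[bad_row, "FID"])
    if bad_fam:
        logger.info("dropping %d families with missing phenotypes", len(bad_fam))
    keep = merged[~merged["FID"].isin(bad_fam)]
    counts = keep.groupby("FID")["IID"].transform("size")
    incomplete = set(keep.loc[counts != 2, "FID"])
    if incomplete:
        logger.info("dropping %d families without a complete sibling pair", len(incomplete))
        keep = keep[~keep["FID"].isin(incomplete)]
    if keep.empty:
        raise ValueError(f"{path}: no complete families remain after filtering")

    rows = keep["_row"].to_numpy(dtype=np.intp)
    phenos = PhenotypePair(
        y1=keep[trait_cols[0]].to_numpy(dtype=float),
        y2=keep[trait_cols[1]].to_numpy(dtype=float),
    )
    covar = keep[covariate_cols].to_numpy(dtype=float) if covariate_cols else None
    return rows, phenos, covar, keep["FID"].to_numpy()


def filter_snps(
    dosages: np.ndarray,
    maf_threshold: float = 0.05,
    missing_threshold: float = 0.01,
) -> np.ndarray:
    """Boolean mask of SNP columns passing MAF and missingness filters."""
    if not (0 <= maf_threshold <= 1 and 0 <= missing_threshold <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    miss = np.mean(~np.isfinite(dosages), axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosages, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    return (maf >= maf_threshold) & (miss < missing_threshold)


def cohort_from_tables(
    geno: GenotypeTable, parents: GenotypeTable | None, rows: np.ndarray, family_id: np.ndarray
) -> FamilyCohort:
    """Assemble a cohort from parsed tables, aligned to phenotype rows."""
    sib = geno.dosages[rows]
    if parents is not None:
        if parents.snp_names != geno.snp_names:
            raise ValueError("parental-sum file must carry the same SNP columns")
        pkey = {(f, i): r for r, (f, i) in enumerate(zip(parents.fid, parents.iid))}
        prow = []
        for r in rows:
            k = (geno.fid[r], geno.iid[r])
            if k not in pkey:
                raise ValueError(f"parental sums missing for individual {k}")
            prow.append(pkey[k])
        psum = parents.dosages[prow]
    else:
        psum = np.full_like(sib, np.nan, dtype=float)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(sib, axis=0) / 2.0
    return FamilyCohort(
        sib_geno=sib, parent_sum=psum, allele_freq=freq, family_id=family_id
    )


def read_parameter_file(path: str | Path) -> ParameterSet:
    """Flat key: value YAML with the 14 parameter names (missing keys -> 0)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    return ParameterSet(**{k: float(v) for k, v in raw.items()})


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
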