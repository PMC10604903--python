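"""Readers and writers for the package's interchange formats.

The canonical dialect is tab-separated text with a header row of column
labels and a first column of individual labels.  PLINK ``.raw`` export
(whitespace-separated, ``FID IID PAT MAT SEX PHENOTYPE`` then one column
per marker) is accepted for genotypes, as is plain-text VCF (GT field,
biallelic sites only).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Coding, GenotypeMatrix, KinshipMatrix, TraitMatrix

__all__ = ["read_table", "write_table", "read_plink_raw", "read_vcf"]

logger = logging.getLogger(__name__)

_KINDS = ("traits", "genotypes", "kinship")


def _read_tsv(path, dialect: dict | None):
    opts = {"sep": "\t", "index_col": 0}
    if dialect:
        opts.update(dialect)
    try:
        df = pd.read_csv(path, **opts)
    except pd.errors.ParserError as exc:  # malformed header / ragged rows
        raise ValueError(f"{path}: malformed delimited file: {exc}") from exc
    if df.columns.size == 0:
        raise ValueError(f"{path}: malformed header (no data columns)")
    # Locate the first non-numeric cell for a useful parse error.
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna() & (df.astype(str) != "")
    if bad.any().any():
        j = bad.any(axis=0).idxmax()
        i = bad[j].idxmax()
        raise ValueError(
            f"{path}: non-numeric cell at row {i!r}, column {j!r}: {df.loc[i, j]!r}")
    numeric.index = df.index.astype(str)
    numeric.columns = df.columns.astype(str)
    return numeric


def read_table(path, kind: str, dialect: dict | None = None):
    """Read a phenotype, genotype or kinship matrix from delimited text.

    Parameters
    ----------
    path
        Path to the file.  Tab-separated by default; pass e.g.
        ``dialect={"sep": ","}`` for other delimiters.  For
        ``kind="genotypes"`` a PLINK ``.raw`` file is auto-detected from
        its extension/header.
    kind
        One of ``"traits"``, ``"genotypes"``, ``"kinship"``.

    Returns
    -------
    TraitMatrix | GenotypeMatrix | KinshipMatrix

    Notes
    -----
    Individuals with any missing phenotype are dropped (complete-case
    analysis) and the dropped count is logged.  Missing genotypes are
    mean-imputed per marker.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")

    if kind == "genotypes":
        if path.suffix == ".raw" or _looks_like_plink_raw(path):
            return read_plink_raw(path)
        if path.suffix == ".vcf":
            return read_vcf(path)

    df = _read_tsv(path, dialect)

    if kind == "traits":
        keep = df.notna().all(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("read_table: dropped %d individual(s) with missing "
                        "phenotypes from %s", n_dropped, path)
        df = df.loc[keep]
        return TraitMatrix(df.to_numpy(float), df.index.to_numpy(),
                           df.columns.to_numpy())
    if kind == "genotypes":
        values = _mean_impute(df.to_numpy(float))
        return GenotypeMatrix(values, df.index.to_numpy(), df.columns.to_numpy())
    # kinship
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"{path}: kinship must be square, got {df.shape[0]} rows x "
            f"{df.shape[1]} columns")
    values = df.to_numpy(float)
    values = 0.5 * (values + values.T) if np.allclose(values, values.T,
                                                     atol=1e-10) else values
    return KinshipMatrix(values, df.index.to_numpy())


def write_table(obj, path) -> None:
    """Write a container back to canonical tab-separated text."""
    obj.to_dataframe().to_csv(path, sep="\t")


def _mean_impute(values: np.ndarray) -> np.ndarray:
    """Impute missing genotype entries with the per-marker mean dosage.

    Imputed values are rounded to the nearest dosage in {0, 1, 2} so the
    raw012 invariant holds; exact frequencies are re-estimated downstream.
    """
    if not np.isnan(values).any():
        return values
    values = values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(values, axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    idx = np.argwhere(np.isnan(values))
    values[idx[:, 0], idx[:, 1]] = np.clip(np.rint(col_mean[idx[:, 1]]), 0, 2)
    return values


_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _looks_like_plink_raw(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline().split()
    return first[:6] == _PLINK_META


def read_plink_raw(path) -> GenotypeMatrix:
    """Read a PLINK ``--recode A`` (.raw) additive-dosage export."""
    df = pd.read_csv(path, sep=r"\s+")
    if df.columns[:6].tolist() != _PLINK_META:
        raise ValueError(f"{path}: not a PLINK .raw file (header mismatch)")
    ids = df["IID"].astype(str).to_numpy()
    geno = df.drop(columns=_PLINK_META)
    values = _mean_impute(geno.to_numpy(float))
    return GenotypeMatrix(values, ids, geno.columns.to_numpy())


def read_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a VCF, counting ALT alleles as 0/1/2 dosage.

    Multi-allelic sites are skipped with a warning; missing calls are
    mean-imputed per marker.
    """
    from cyvcf2 import VCF  # local import: only needed for VCF input

    vcf = VCF(str(path), gts012=True)
    samples = np.asarray(vcf.samples, dtype=str)
    columns, ids = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        # with gts012: gt_types is the ALT dosage 0/1/2, 3 = missing
        dosage = np.asarray(var.gt_types, dtype=float)
        dosage[dosage == 3] = np.nan
        columns.append(dosage)
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        ids.append(name)
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} multi-allelic site(s)")
    if not columns:
        raise ValueError(f"{path}: no usable biallelic sites")
    values = _mean_impute(np.column_stack(columns))
    return GenotypeMatrix(values, samples, np.asarray(ids, dtype=str))
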