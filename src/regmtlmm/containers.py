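"""Labeled data containers for the multi-trait mixed-model toolkit.

All containers wrap plain numpy arrays plus string labels and validate
their invariants at construction time.  Individuals index rows throughout;
traits and markers index columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Coding",
    "TraitMatrix",
    "GenotypeMatrix",
    "KinshipMatrix",
    "AlignedDataset",
    "KinshipEigen",
    "CovariancePair",
    "EffectMatrix",
    "RotatedDataset",
]


class Coding(str, Enum):
    """Genotype coding: raw minor-allele dosages or column-standardized scores."""

    raw012 = "raw012"
    standardized = "standardized"


def _as_labels(labels, n: int, what: str) -> np.ndarray:
    arr = np.asarray(labels, dtype=str)
    if arr.shape != (n,):
        raise ValueError(f"{what}: expected {n} labels, got shape {arr.shape}")
    if len(set(arr.tolist())) != n:
        raise ValueError(f"{what}: labels must be unique")
    return arr


@dataclass
class TraitMatrix:
    """n x q phenotype matrix Y with individual and trait labels."""

    values: np.ndarray
    individual_ids: np.ndarray
    trait_names: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trait values must be 2-D (individuals x traits)")
        n, q = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 individuals")
        if q < 1:
            raise ValueError("need at least 1 trait")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trait matrix contains missing/non-finite values; "
                             "apply the complete-case filter first")
        self.individual_ids = _as_labels(self.individual_ids, n, "individual_ids")
        self.trait_names = _as_labels(self.trait_names, q, "trait_names")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individual_ids,
                            columns=self.trait_names)


@dataclass
class GenotypeMatrix:
    """n x p marker matrix X, raw 0/1/2 dosages or standardized columns.

    ``allele_freqs`` holds the per-marker ALT/minor allele frequency
    estimated from the data (column mean / 2); it is populated for raw
    coding and carried along after standardization.
    """

    values: np.ndarray
    individual_ids: np.ndarray
    marker_ids: np.ndarray
    coding: Coding = Coding.raw012
    allele_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (individuals x markers)")
        n, p = self.values.shape
        self.individual_ids = _as_labels(self.individual_ids, n, "individual_ids")
        self.marker_ids = _as_labels(self.marker_ids, p, "marker_ids")
        self.coding = Coding(self.coding)
        if self.coding is Coding.raw012:
            bad = ~np.isin(self.values, (0.0, 1.0, 2.0)) & np.isfinite(self.values)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"raw genotype entry not in {{0,1,2}} at individual "
                    f"{self.individual_ids[i]!r}, marker {self.marker_ids[j]!r}")
            if self.allele_freqs is None:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    self.allele_freqs = np.nanmean(self.values, axis=0) / 2.0
        if self.allele_freqs is not None:
            self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
            if self.allele_freqs.shape != (p,):
                raise ValueError("allele_freqs must have one entry per marker")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individual_ids,
                            columns=self.marker_ids)


@dataclass
class KinshipMatrix:
    """n x n symmetric PSD genomic relationship matrix K."""

    values: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(
                f"kinship must be square, got shape {self.values.shape}")
        n = self.values.shape[0]
        if not np.allclose(self.values, self.values.T, atol=1e-10, rtol=0.0):
            raise ValueError("kinship matrix is not symmetric (tolerance 1e-10)")
        self.individual_ids = _as_labels(self.individual_ids, n, "individual_ids")
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -1e-8:
            raise ValueError(
                f"kinship is not PSD up to numerical noise "
                f"(min eigenvalue {w.min():.3e} < -1e-8)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individual_ids,
                            columns=self.individual_ids)


@dataclass
class AlignedDataset:
    """Phenotypes, genotypes and kinship restricted to one individual ordering."""

    traits: TraitMatrix
    genotypes: GenotypeMatrix
    kinship: KinshipMatrix

    def __post_init__(self) -> None:
        ids = self.traits.individual_ids
        if not (np.array_equal(ids, self.genotypes.individual_ids)
                and np.array_equal(ids, self.kinship.individual_ids)):
            raise ValueError("traits, genotypes and kinship must share identical "
                             "individual ids in identical order; use align()")

    @property
    def n(self) -> int:
        return self.traits.n

    @property
    def q(self) -> int:
        return self.traits.q

    @property
    def p(self) -> int:
        return self.genotypes.p

    def subset(self, idx: np.ndarray) -> "AlignedDataset":
        """Restrict to the individuals at positions ``idx`` (order kept)."""
        idx = np.asarray(idx)
        return AlignedDataset(
            traits=TraitMatrix(self.traits.values[idx],
                               self.traits.individual_ids[idx],
                               self.traits.trait_names),
            genotypes=GenotypeMatrix(self.genotypes.values[idx],
                                     self.genotypes.individual_ids[idx],
                                     self.genotypes.marker_ids,
                                     coding=self.genotypes.coding,
                                     allele_freqs=self.genotypes.allele_freqs),
            kinship=KinshipMatrix(self.kinship.values[np.ix_(idx, idx)],
                                  self.kinship.individual_ids[idx]),
        )


@dataclass
class KinshipEigen:
    """Eigendecomposition K = U diag(s) U' with s descending and clamped at 0."""

    U: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        n = self.U.shape[0]
        if self.U.shape != (n, n) or self.s.shape != (n,):
            raise ValueError("inconsistent eigendecomposition shapes")
        if np.any(self.s < 0):
            raise ValueError("eigenvalues must be clamped at 0")
        if np.any(np.diff(self.s) > 1e-12):
            raise ValueError("eigenvalues must be in descending order")
        if not np.allclose(self.U.T @ self.U, np.eye(n), atol=1e-10):
            raise ValueError("U is not orthonormal within 1e-10")


@dataclass
class CovariancePair:
    """Trait-by-trait genetic (Cg, PSD) and residual (Ce, PD) covariances."""

    Cg: np.ndarray
    Ce: np.ndarray
    eps_pd: float = 1e-8

    def __post_init__(self) -> None:
        self.Cg = np.asarray(self.Cg, dtype=float)
        self.Ce = np.asarray(self.Ce, dtype=float)
        q = self.Cg.shape[0]
        if self.Cg.shape != (q, q) or self.Ce.shape != (q, q):
            raise ValueError("Cg and Ce must be square with matching size")
        for name, C in (("Cg", self.Cg), ("Ce", self.Ce)):
            if not np.allclose(C, C.T, atol=1e-10, rtol=0.0):
                raise ValueError(f"{name} is not symmetric within 1e-10")
        if np.linalg.eigvalsh(self.Cg).min() < -1e-10:
            raise ValueError("Cg must be PSD")
        if np.linalg.eigvalsh(self.Ce).min() < self.eps_pd - 1e-12:
            raise ValueError(f"Ce must be PD with eigenvalues >= {self.eps_pd}")

    @property
    def q(self) -> int:
        return self.Cg.shape[0]


@dataclass
class EffectMatrix:
    """p x q matrix of per-marker, per-trait fixed effect sizes."""

    values: np.ndarray
    marker_ids: np.ndarray
    trait_names: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("effect matrix must be 2-D (markers x traits)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("effect matrix contains non-finite entries")
        p, q = self.values.shape
        self.marker_ids = _as_labels(self.marker_ids, p, "marker_ids")
        self.trait_names = _as_labels(self.trait_names, q, "trait_names")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.marker_ids,
                            columns=self.trait_names)


@dataclass
class RotatedDataset:
    """Data rotated into the kinship eigenbasis.

    Rows of ``Ytil = U'Y`` are independent q-variate Gaussians with
    covariance ``V_i = s_i * Cg + Ce``; ``Xtil = U'X`` and ``itil = U'1``
    (the rotated intercept column).
    """

    Ytil: np.ndarray
    Xtil: np.ndarray
    itil: np.ndarray
    s: np.ndarray
    trait_names: np.ndarray = field(default=None)
    marker_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.Ytil = np.asarray(self.Ytil, dtype=float)
        self.Xtil = np.asarray(self.Xtil, dtype=float)
        self.itil = np.asarray(self.itil, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        n = self.Ytil.shape[0]
        if self.Xtil.shape[0] != n or self.s.shape != (n,) or self.itil.shape != (n,):
            raise ValueError("rotated arrays have inconsistent leading dimension")

    @property
    def n(self) -> int:
        return self.Ytil.shape[0]

    @property
    def q(self) -> int:
        return self.Ytil.shape[1]

    @property
    def p(self) -> int:
        return self.Xtil.shape[1]
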