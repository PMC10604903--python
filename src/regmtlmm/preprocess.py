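"""Kinship computation, genotype standardization and dataset alignment."""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .containers import (AlignedDataset, Coding, GenotypeMatrix, KinshipMatrix,
                         TraitMatrix)

__all__ = ["compute_vanraden_kinship", "standardize_genotypes", "align"]

logger = logging.getLogger(__name__)


class DegenerateMarkerError(ValueError):
    """A marker is monomorphic / has zero variance where variation is required."""


def compute_vanraden_kinship(genotypes: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from raw 0/1/2 dosages.

    K = W W' / (2 * sum_j p_j (1 - p_j)) with W = X - 2p, allele
    frequencies p estimated as column mean / 2.  Negative eigenvalues
    arising from numerical noise are clamped to zero.
    """
    if genotypes.coding is not Coding.raw012:
        raise ValueError("VanRaden kinship requires raw 0/1/2 coding")
    X = genotypes.values
    freqs = X.mean(axis=0) / 2.0
    mono = (X == X[0]).all(axis=0)
    if mono.any():
        names = genotypes.marker_ids[mono]
        if not (X[:, mono] == 1.0).all():
            raise DegenerateMarkerError(
                f"monomorphic marker(s) give a zero denominator term: "
                f"{', '.join(names[:5])}")
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    W = X - 2.0 * freqs
    if denom == 0.0:
        K = np.zeros((genotypes.n, genotypes.n))
    else:
        K = (W @ W.T) / denom
    K = 0.5 * (K + K.T)
    w, U = np.linalg.eigh(K)
    if w.min() < -1e-6:
        warnings.warn(f"kinship eigenvalue {w.min():.3e} clamped to 0; the "
                      "relationship matrix was noticeably indefinite")
    if w.min() < 0:
        K = (U * np.clip(w, 0.0, None)) @ U.T
        K = 0.5 * (K + K.T)
    return KinshipMatrix(K, genotypes.individual_ids)


def standardize_genotypes(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Center each marker column to mean 0 and scale to population sd 1.

    Standardizing puts every marker on the same scale so a single L1
    weight penalizes all of them uniformly.
    """
    if genotypes.coding is Coding.standardized:
        raise ValueError("genotypes are already standardized")
    X = genotypes.values
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = sd == 0.0
    if zero.any():
        names = ", ".join(genotypes.marker_ids[zero][:5])
        raise DegenerateMarkerError(f"zero-variance marker(s): {names}")
    return GenotypeMatrix((X - mean) / sd, genotypes.individual_ids,
                          genotypes.marker_ids, coding=Coding.standardized,
                          allele_freqs=genotypes.allele_freqs)


def align(traits: TraitMatrix, genotypes: GenotypeMatrix,
          kinship: KinshipMatrix) -> AlignedDataset:
    """Restrict all three inputs to their common individuals, sorted by id."""
    common = sorted(set(traits.individual_ids)
                    & set(genotypes.individual_ids)
                    & set(kinship.individual_ids))
    if not common:
        raise ValueError("alignment error: the individual-id sets of traits, "
                         "genotypes and kinship have empty intersection")
    common = np.asarray(common, dtype=str)
    for name, container in (("traits", traits), ("genotypes", genotypes),
                            ("kinship", kinship)):
        dropped = len(container.individual_ids) - len(common)
        if dropped:
            logger.info("align: dropped %d individual(s) from %s", dropped, name)

    def pos(container):
        lookup = {iid: i for i, iid in enumerate(container.individual_ids)}
        return np.asarray([lookup[iid] for iid in common])

    it, ig, ik = pos(traits), pos(genotypes), pos(kinship)
    return AlignedDataset(
        traits=TraitMatrix(traits.values[it], common, traits.trait_names),
        genotypes=GenotypeMatrix(genotypes.values[ig], common,
                                 genotypes.marker_ids,
                                 coding=genotypes.coding,
                                 allele_freqs=genotypes.allele_freqs),
        kinship=KinshipMatrix(kinship.values[np.ix_(ik, ik)], common),
    )
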