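"""Shared fixtures and dense-matrix oracles for the test suite.

The oracles here deliberately build the full nq x nq Kronecker covariance
and call generic dense linear algebra, independent of the package's
block-rotated code paths.
"""

import numpy as np
import pytest

from regmtlmm.containers import (AlignedDataset, CovariancePair,
                                 GenotypeMatrix, KinshipMatrix, TraitMatrix)


def random_psd(q, rng, jitter=0.3):
    A = rng.standard_normal((q, q))
    return A @ A.T + jitter * np.eye(q)


def random_instance(rng, n=10, q=3, p=4):
    """Random kinship/phenotype/genotype/covariance instance (unlabeled)."""
    A = rng.standard_normal((n, n))
    K = A @ A.T / n
    Y = rng.standard_normal((n, q))
    X = rng.standard_normal((n, p))
    Cg = random_psd(q, rng, jitter=0.0)
    Ce = random_psd(q, rng, jitter=0.5)
    return K, Y, X, CovariancePair(Cg, Ce)


def dense_nll(Y, X, B, K, cov, intercept=None):
    """-log L via the explicit nq-dimensional Gaussian (vec stacks columns)."""
    n, q = Y.shape
    mean = X @ B
    if intercept is not None:
        mean = mean + intercept
    S = np.kron(cov.Cg, K) + np.kron(cov.Ce, np.eye(n))
    r = (Y - mean).ravel(order="F")
    sign, logdet = np.linalg.slogdet(S)
    assert sign > 0
    return 0.5 * (n * q * np.log(2 * np.pi) + logdet
                  + r @ np.linalg.solve(S, r))


def dense_gls(Y, D, K, cov):
    """GLS of vec(Y) on kron(I_q, D); returns (coef q-blocks stacked, cov)."""
    n, q = Y.shape
    S = np.kron(cov.Cg, K) + np.kron(cov.Ce, np.eye(n))
    Si = np.linalg.inv(S)
    Dk = np.kron(np.eye(q), D)
    A = Dk.T @ Si @ Dk
    beta = np.linalg.solve(A, Dk.T @ Si @ Y.ravel(order="F"))
    return beta, np.linalg.inv(A)


def labeled_dataset(K, Y, X, coding="standardized"):
    n, q = Y.shape
    p = X.shape[1]
    ids = np.asarray([f"i{i}" for i in range(n)])
    return AlignedDataset(
        traits=TraitMatrix(Y, ids, [f"t{j}" for j in range(q)]),
        genotypes=GenotypeMatrix(X, ids, [f"m{j}" for j in range(p)],
                                 coding=coding,
                                 allele_freqs=np.full(p, 0.5)),
        kinship=KinshipMatrix(0.5 * (K + K.T), ids),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def small_dataset():
    """A small structured synthetic dataset with planted sparse effects."""
    from regmtlmm import (ScenarioSpec, make_synthetic_dataset)
    spec = ScenarioSpec(scenario=2, q=6, p=40, qtn_per_trait=5, seed=99)
    data, truth, cov = make_synthetic_dataset(spec, n=80,
                                              rng=np.random.default_rng(99))
    return data, truth, cov
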