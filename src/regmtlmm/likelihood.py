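"""Likelihood of the multi-trait linear mixed model in the kinship eigenbasis.

The model is Y = X B + G + E with G ~ N_{n x q}(0, Cg, K) and
E ~ N_{n x q}(0, Ce, I_n), i.e. vec(Y) ~ N_nq(vec(XB), Cg (x) K + Ce (x) I).
Rotating Y and X by the eigenvectors of K = U diag(s) U' turns the nq x nq
covariance into n independent q x q blocks V_i = s_i Cg + Ce.  A further
congruence transform T that simultaneously diagonalizes (Cg, Ce) —
T V_i T' = diag(s_i d + 1) — reduces every likelihood quantity to
elementwise operations on an n x q weight array, which is what makes the
penalized fit scale to genome-wide marker counts.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .containers import (AlignedDataset, CovariancePair, GenotypeMatrix,
                         KinshipEigen, KinshipMatrix, RotatedDataset,
                         TraitMatrix)

__all__ = [
    "eigendecompose_kinship",
    "rotate",
    "CovarianceTransform",
    "negative_log_likelihood",
    "gradient_wrt_effects",
    "gradient_wrt_covariances",
    "gls_effects",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def eigendecompose_kinship(kinship: KinshipMatrix | np.ndarray) -> KinshipEigen:
    """Eigendecompose K with eigenvalues clamped at 0, descending order,
    and a deterministic sign convention (largest-magnitude entry of each
    eigenvector positive)."""
    K = kinship.values if isinstance(kinship, KinshipMatrix) else np.asarray(kinship)
    if not np.allclose(K, K.T, atol=1e-8, rtol=0.0):
        raise ValueError("kinship matrix is asymmetric beyond 1e-8")
    w, U = np.linalg.eigh(0.5 * (K + K.T))
    order = np.argsort(-w, kind="stable")
    w, U = w[order], U[:, order]
    w = np.clip(w, 0.0, None)
    # sign convention: flip each column so its largest-|.| entry is positive
    amax = np.abs(U).argmax(axis=0)
    signs = np.sign(U[amax, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return KinshipEigen(U * signs, w)


def rotate(eig: KinshipEigen, traits: TraitMatrix | np.ndarray,
           genotypes: GenotypeMatrix | np.ndarray) -> RotatedDataset:
    """Rotate phenotypes and genotypes into the kinship eigenbasis.

    After rotation, row i of U'Y is an independent q-variate Gaussian with
    mean (U'X B)_i and covariance V_i = s_i Cg + Ce.
    """
    Y = traits.values if isinstance(traits, TraitMatrix) else np.asarray(traits)
    X = genotypes.values if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    if Y.shape[0] != eig.U.shape[0] or X.shape[0] != eig.U.shape[0]:
        raise ValueError("dimension mismatch between eigenbasis and data")
    trait_names = traits.trait_names if isinstance(traits, TraitMatrix) else None
    marker_ids = genotypes.marker_ids if isinstance(genotypes, GenotypeMatrix) else None
    Ut = eig.U.T
    return RotatedDataset(Ytil=Ut @ Y, Xtil=Ut @ X,
                          itil=Ut @ np.ones(eig.U.shape[0]), s=eig.s,
                          trait_names=trait_names, marker_ids=marker_ids)


class CovarianceTransform:
    """Simultaneous diagonalization of a covariance pair (Cg, Ce).

    Factor Ce = Le Le', solve the symmetric eigenproblem of
    Le^-1 Cg Le^-T = Q diag(d) Q', and set T = Q' Le^-1.  Then
    T V_i T' = diag(s_i d + 1) for every block V_i = s_i Cg + Ce, and
    log|V_i| = log|Ce| + sum_k log(s_i d_k + 1).
    """

    def __init__(self, cov: CovariancePair):
        Ce = cov.Ce
        try:
            Le = np.linalg.cholesky(Ce)
        except np.linalg.LinAlgError:
            # jitter once; CovariancePair already guarantees near-PD
            Le = np.linalg.cholesky(Ce + 10 * cov.eps_pd * np.eye(cov.q))
        M = scipy.linalg.solve_triangular(Le, cov.Cg, lower=True)
        M = scipy.linalg.solve_triangular(Le, M.T, lower=True)
        d, Q = np.linalg.eigh(0.5 * (M + M.T))
        self.d = np.clip(d, 0.0, None)
        self.T = Q.T @ scipy.linalg.solve_triangular(
            Le, np.eye(cov.q), lower=True)
        self.logdet_Ce = 2.0 * np.sum(np.log(np.diag(Le)))
        self.q = cov.q

    def weights(self, s: np.ndarray) -> np.ndarray:
        """n x q array w_ik = 1 / (s_i d_k + 1) = diag of (T V_i T')^-1."""
        denom = np.outer(s, self.d) + 1.0
        if np.any(denom <= 0):
            i = int(np.argwhere((denom <= 0).any(axis=1))[0])
            raise np.linalg.LinAlgError(
                f"covariance block V_{i} is numerically singular")
        return 1.0 / denom

    def logdets(self, s: np.ndarray) -> np.ndarray:
        """log|V_i| for each block."""
        return self.logdet_Ce + np.log1p(np.outer(s, self.d)).sum(axis=1)


def _residual(rot: RotatedDataset, B: np.ndarray,
              intercept: np.ndarray | None) -> np.ndarray:
    R = rot.Ytil - rot.Xtil @ B
    if intercept is not None:
        R = R - np.outer(rot.itil, intercept)
    return R


def negative_log_likelihood(rot: RotatedDataset, B: np.ndarray,
                            cov: CovariancePair,
                            intercept: np.ndarray | None = None,
                            transform: CovarianceTransform | None = None) -> float:
    """Exact -log L of the mtLMM, evaluated blockwise in the eigenbasis.

    Equals the dense nq-dimensional Gaussian negative log-likelihood with
    covariance Cg (x) K + Ce (x) I_n.
    """
    tr = transform if transform is not None else CovarianceTransform(cov)
    W = tr.weights(rot.s)
    R = _residual(rot, np.asarray(B, float), intercept) @ tr.T.T
    quad = float(np.sum(R * R * W))
    return 0.5 * (rot.n * rot.q * _LOG_2PI + float(tr.logdets(rot.s).sum()) + quad)


def gradient_wrt_effects(rot: RotatedDataset, B: np.ndarray,
                         cov: CovariancePair,
                         intercept: np.ndarray | None = None,
                         transform: CovarianceTransform | None = None,
                         with_intercept_grad: bool = False):
    """Gradient of the negative log-likelihood with respect to B.

    Returns the p x q array -Xtil' [ (R T') o W ] T; optionally also the
    q-vector gradient for the unpenalized intercept.
    """
    tr = transform if transform is not None else CovarianceTransform(cov)
    W = tr.weights(rot.s)
    M = (_residual(rot, np.asarray(B, float), intercept) @ tr.T.T) * W
    # rows of M @ T are r_i V_i^-1
    RVinv = M @ tr.T
    grad_B = -rot.Xtil.T @ RVinv
    if with_intercept_grad:
        return grad_B, -rot.itil @ RVinv
    return grad_B


def gradient_wrt_covariances(rot: RotatedDataset, B: np.ndarray,
                             cov: CovariancePair,
                             intercept: np.ndarray | None = None,
                             transform: CovarianceTransform | None = None):
    """Gradients of -LL with respect to Cg and Ce (both symmetrized).

    d(-LL)/dCg = 1/2 sum_i s_i (V_i^-1 - V_i^-1 r_i' r_i V_i^-1); the Ce
    gradient replaces the weight s_i by 1.
    """
    tr = transform if transform is not None else CovarianceTransform(cov)
    W = tr.weights(rot.s)
    R = _residual(rot, np.asarray(B, float), intercept) @ tr.T.T
    M = R * W
    # sum_i c_i V_i^-1 = T' diag(sum_i c_i w_i.) T for any scalar weights c_i
    a_g = (rot.s[:, None] * W).sum(axis=0)
    a_e = W.sum(axis=0)
    Sg = (M * rot.s[:, None]).T @ M
    Se = M.T @ M
    Gg = 0.5 * tr.T.T @ (np.diag(a_g) - Sg) @ tr.T
    Ge = 0.5 * tr.T.T @ (np.diag(a_e) - Se) @ tr.T
    return 0.5 * (Gg + Gg.T), 0.5 * (Ge + Ge.T)


def gls_effects(rot: RotatedDataset, cov: CovariancePair,
                columns: np.ndarray | list | None = None,
                return_cov: bool = True):
    """Exact GLS solution for a subset of marker effects plus the intercept.

    All effects outside ``columns`` are fixed at zero.  Returns
    ``(B_sub, intercept, cov_of_estimates)`` where ``B_sub`` is
    (len(columns)) x q, and the sampling covariance is over
    vec([intercept; B_sub]) stacked column-major (trait by trait blocks
    transformed back to the original trait basis).
    """
    columns = np.arange(rot.p) if columns is None else np.asarray(columns)
    c = len(columns) + 1
    if c >= rot.n + 1 and c > rot.n:
        raise np.linalg.LinAlgError("more fixed effects than observations")
    tr = CovarianceTransform(cov)
    W = tr.weights(rot.s)                      # n x q weights per transformed trait
    D = np.column_stack([rot.itil, rot.Xtil[:, columns]])   # n x c design
    Z = rot.Ytil @ tr.T.T                      # transformed traits, independent cols
    q = rot.q
    Theta = np.empty((c, q))
    blocks = []
    for k in range(q):
        Dw = D * W[:, k][:, None]
        A = D.T @ Dw  # fisher information for transformed trait k
        # rank check
        if np.linalg.matrix_rank(A) < c:
            raise np.linalg.LinAlgError("rank-deficient GLS design")
        Ainv = np.linalg.inv(A)
        Theta[:, k] = Ainv @ (Dw.T @ Z[:, k])
        blocks.append(Ainv)
    # back to original trait coordinates: B = Theta T^-T
    Tinv = np.linalg.inv(tr.T)
    Beta = Theta @ Tinv.T
    intercept = Beta[0]
    B_sub = Beta[1:]
    if not return_cov:
        return B_sub, intercept, None
    # Cov(vec(Beta)) with vec stacking trait-blocks: (Tinv (x) I_c) blkdiag (Tinv (x) I_c)'
    blk = scipy.linalg.block_diag(*blocks)
    Kron = np.kron(Tinv, np.eye(c))
    cov_est = Kron @ blk @ Kron.T
    return B_sub, intercept, cov_est


def dense_covariance(cov: CovariancePair, K: np.ndarray) -> np.ndarray:
    """Dense nq x nq covariance Cg (x) K + Ce (x) I (test oracle / tiny n)."""
    n = K.shape[0]
    return np.kron(cov.Cg, K) + np.kron(cov.Ce, np.eye(n))


def null_rotated(data: AlignedDataset):
    """Convenience: eigendecompose the kinship and rotate an aligned dataset."""
    eig = eigendecompose_kinship(data.kinship)
    return eig, rotate(eig, data.traits, data.genotypes)
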