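"""Genomic prediction: GEBVs from a fitted model, cross-validation, RR-BLUP.

A genomic estimated breeding value for an unobserved (test) individual
combines the fixed marker effects with the best linear predictor of the
genetic random effect given the training residuals:

    Yhat_test = X_test Bhat + Ghat_test,
    vec(Ghat_test) = (Cg (x) K_ts) (Cg (x) K_tt + Ce (x) I)^-1
                     vec(Y_train - X_train Bhat - 1 mu'),

computed in the eigenbasis of the training kinship block so the dense
Kronecker matrix is never formed.  Prediction accuracy is the per-trait
Pearson correlation between observed test phenotypes and GEBVs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import AlignedDataset, CovariancePair
from .estimation import (FitOptions, FitResult, PenaltySpec,
                         default_lambda_grid, fit_regularized_mtlmm,
                         fit_univariate_ml, select_regularization)
from .likelihood import CovarianceTransform, eigendecompose_kinship, rotate

__all__ = ["CVResult", "predict_gebv", "pearson_accuracy", "cross_validate",
           "rrblup_baseline", "CV_METHODS"]

CV_METHODS = ("mtLMM-L1", "mtLM-L1", "mtLMM-clust", "mtLM-clust", "rrblup-uni")


@dataclass
class CVResult:
    """Per-split and aggregate prediction accuracies."""

    per_split_correlation: np.ndarray   # n_splits x q
    mean: np.ndarray                    # q
    sd: np.ndarray                      # q
    split_seeds: list
    trait_names: np.ndarray
    method: str


def predict_gebv(fit: FitResult, data_full: AlignedDataset,
                 train_idx, test_idx) -> np.ndarray:
    """Predict test-set phenotypes (GEBVs) from a fitted model.

    For the mixed model the genetic effect is the conditional mean given
    the training residuals; for ``model="mtLM"`` (Cg = 0) the prediction
    is the fixed part alone.
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test index sets overlap")
    X = data_full.genotypes.values
    Y = data_full.traits.values
    K = data_full.kinship.values
    B = fit.B_hat.values
    fixed_test = X[test_idx] @ B + fit.intercept
    cov = fit.cov_hat
    if fit.model == "mtLM" or np.allclose(cov.Cg, 0.0):
        return fixed_test
    R_train = Y[train_idx] - X[train_idx] @ B - fit.intercept
    K_tt = K[np.ix_(train_idx, train_idx)]
    K_ts = K[np.ix_(test_idx, train_idx)]
    eig = eigendecompose_kinship(K_tt)
    tr = CovarianceTransform(cov)
    W = tr.weights(eig.s)
    # rows of A are r_i V_i^-1, back-rotated: (Cg (x) K_tt + Ce (x) I)^-1 applied
    Rtil = eig.U.T @ R_train
    A = eig.U @ (((Rtil @ tr.T.T) * W) @ tr.T)
    # (Cg (x) K_ts) vec(A) = vec(K_ts A Cg)
    return fixed_test + K_ts @ A @ cov.Cg


def pearson_accuracy(observed: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Per-trait Pearson correlation; NaN where either column is constant."""
    observed = np.atleast_2d(np.asarray(observed, float))
    predicted = np.atleast_2d(np.asarray(predicted, float))
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have the same shape")
    if observed.shape[0] < 3:
        raise ValueError("need at least 3 test individuals")
    out = np.full(observed.shape[1], np.nan)
    for j in range(observed.shape[1]):
        o, p = observed[:, j], predicted[:, j]
        if o.std() == 0 or p.std() == 0:
            continue
        out[j] = float(np.corrcoef(o, p)[0, 1])
    return out


def rrblup_baseline(train: AlignedDataset, X_test: np.ndarray) -> np.ndarray:
    """Univariate ridge-regression BLUP fitted separately to each trait.

    Marker effects are  u_hat = X' (X X' + (se2/su2) I)^-1 (y - mu_hat)
    with the variance ratio from a univariate ML fit on the marker-derived
    relationship X X' / p; predictions are  X_test u_hat + mu_hat.
    """
    X = train.genotypes.values
    n, p = X.shape
    G = X @ X.T / p
    eig = eigendecompose_kinship(0.5 * (G + G.T))
    Ut = eig.U.T
    itil = Ut @ np.ones(n)
    preds = np.empty((X_test.shape[0], train.q))
    for j in range(train.q):
        y = train.traits.values[:, j]
        sg2, se2, beta, _ = fit_univariate_ml(eig.s, Ut @ y, itil[:, None])
        mu = float(beta[0])
        su2 = sg2 / p  # per-marker effect variance under the RR-BLUP prior
        ratio = se2 / max(su2, 1e-12)
        core = X @ X.T + ratio * np.eye(n)
        u = X.T @ np.linalg.solve(core, y - mu)
        preds[:, j] = X_test @ u + mu
    return preds


def _default_grid(train: AlignedDataset, method: str,
                  n_lam: int = 5) -> list[PenaltySpec]:
    eig = eigendecompose_kinship(train.kinship)
    rot = rotate(eig, train.traits, train.genotypes)
    from .estimation import _init_cov
    cov0 = _init_cov(train.traits.values)
    gammas = (0.0,)
    if method.endswith("clust"):
        gammas = (0.1, 0.5)
    grid = default_lambda_grid(rot, cov0, n_lam=n_lam, lam_min_ratio=0.05,
                               gammas=(0.0,))
    if method.endswith("clust"):
        out = []
        for spec in grid:
            for g in gammas:
                out.append(PenaltySpec(lam=spec.lam, gamma=g * spec.lam))
        return out
    return grid


def cross_validate(data: AlignedDataset, method: str, n_splits: int = 50,
                   test_fraction: float = 0.2,
                   grid: list[PenaltySpec] | None = None,
                   opts: FitOptions | None = None, seed: int = 0,
                   holdout_fraction: float = 0.2) -> CVResult:
    """Repeated random train/test split evaluation of genomic prediction.

    For each of ``n_splits`` seeded splits, penalty weights are chosen on a
    single inner holdout of the training data (regularized methods), the
    model is refitted on the full training set, GEBVs are predicted for
    the untouched test individuals (all traits masked), and per-trait
    Pearson accuracies are recorded.
    """
    if method not in CV_METHODS:
        raise ValueError(f"method must be one of {CV_METHODS}")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    model = "mtLMM" if method.startswith("mtLMM") else "mtLM"
    rng = np.random.default_rng(seed)
    n = data.n
    n_test = max(3, int(round(test_fraction * n)))
    if n - n_test < data.q + 2:
        raise ValueError("split leaves fewer than q + 2 training individuals")
    corr = np.empty((n_splits, data.q))
    split_seeds = []
    for split in range(n_splits):
        split_seed = int(rng.integers(2 ** 31 - 1))
        split_seeds.append(split_seed)
        srng = np.random.default_rng(split_seed)
        perm = srng.permutation(n)
        test_idx = np.sort(perm[:n_test])
        train_idx = np.sort(perm[n_test:])
        train = data.subset(train_idx)
        if method == "rrblup-uni":
            pred = rrblup_baseline(train, data.genotypes.values[test_idx])
        else:
            use_grid = grid if grid is not None else _default_grid(train, method)
            best, _ = select_regularization(train, use_grid, opts,
                                            holdout_fraction, seed=split_seed,
                                            model=model)
            fit = fit_regularized_mtlmm(train, best, opts, model=model)
            pred = predict_gebv(fit, data, train_idx, test_idx)
        corr[split] = pearson_accuracy(data.traits.values[test_idx], pred)
    return CVResult(per_split_correlation=corr,
                    mean=np.nanmean(corr, axis=0),
                    sd=np.nanstd(corr, axis=0, ddof=1) if n_splits > 1
                    else np.zeros(data.q),
                    split_seeds=split_seeds,
                    trait_names=data.traits.trait_names,
                    method=method)
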