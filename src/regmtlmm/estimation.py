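"""Penalized maximum-likelihood fitting of the multi-trait mixed model.

The penalized criterion  -LL(B, Cg, Ce) + R(B)  is minimized by block
alternation:

* **B-step** — accelerated proximal gradient (FISTA with adaptive restart
  and backtracking) on the rotated negative log-likelihood, using the L1 /
  L1+clustering proximal operators.  The trait-specific intercept rides
  along as an extra unpenalized row.
* **covariance-step** — L-BFGS on Cholesky factors Cg = Lg Lg' and
  Ce = Le Le' + eps*I, holding B fixed (the intercept is profiled out
  exactly, so envelope differentiation applies).

Every accepted outer iteration leaves the penalized objective no larger
than before; the trace is recorded on the fit result.

``model="mtLM"`` freezes Cg at zero, which removes the genetic random
effect and recovers the regularized multi-trait linear model comparators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .containers import (AlignedDataset, CovariancePair, EffectMatrix,
                         RotatedDataset)
from .likelihood import (CovarianceTransform, eigendecompose_kinship,
                         gradient_wrt_covariances, gradient_wrt_effects,
                         negative_log_likelihood, rotate)
from .penalties import PenaltySpec, penalty_value, prox_combined

__all__ = ["FitOptions", "FitResult", "fit_regularized_mtlmm",
           "fit_variance_components_null", "fit_univariate_ml",
           "lambda_max", "default_lambda_grid", "select_regularization"]

EPS_PD = 1e-8
NONZERO_TOL = 1e-8  # |B_ij| above this counts as a detected effect


@dataclass
class FitOptions:
    """Iteration caps and tolerances for the alternating optimizer."""

    outer_max: int = 50
    outer_tol: float = 1e-6
    fista_max: int = 500
    fista_tol: float = 1e-7
    backtrack: float = 0.5
    cov_maxiter: int = 60
    prox_tol: float = 1e-6
    prox_max_iter: int = 200
    seed: int = 0

    def __post_init__(self):
        if min(self.outer_max, self.fista_max, self.cov_maxiter) <= 0:
            raise ValueError("iteration caps must be positive")
        if min(self.outer_tol, self.fista_tol, self.prox_tol) <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 < self.backtrack < 1:
            raise ValueError("backtracking factor must lie in (0, 1)")


@dataclass
class FitResult:
    """Solution of the penalized fit."""

    B_hat: EffectMatrix
    intercept: np.ndarray
    cov_hat: CovariancePair
    objective_trace: list
    converged: bool
    spec: PenaltySpec
    n_outer: int
    model: str = "mtLMM"

    @property
    def support(self) -> np.ndarray:
        return np.abs(self.B_hat.values) > NONZERO_TOL


# ---------------------------------------------------------------------------
# covariance parameterization


def _pack_tril(L: np.ndarray) -> np.ndarray:
    return L[np.tril_indices(L.shape[0])]


def _unpack_tril(x: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    L[np.tril_indices(q)] = x
    return L


def _chol_psd(C: np.ndarray) -> np.ndarray:
    """Cholesky-like factor of a PSD matrix (eigenvalue-clipped)."""
    w, V = np.linalg.eigh(0.5 * (C + C.T))
    w = np.clip(w, 0.0, None)
    A = (V * np.sqrt(w)) @ V.T
    # reduce to lower triangular via QR of A'
    _, R = np.linalg.qr(A.T)
    L = R.T
    sign = np.sign(np.diag(L))
    sign[sign == 0] = 1.0
    return L * sign


def _build_cov(x: np.ndarray, q: int, fix_cg_zero: bool) -> tuple:
    ntri = q * (q + 1) // 2
    if fix_cg_zero:
        Lg = np.zeros((q, q))
        Le = _unpack_tril(x, q)
    else:
        Lg = _unpack_tril(x[:ntri], q)
        Le = _unpack_tril(x[ntri:], q)
    Cg = Lg @ Lg.T
    Ce = Le @ Le.T + EPS_PD * np.eye(q)
    return CovariancePair(Cg, Ce), Lg, Le


def _profiled_intercept(rot: RotatedDataset, B: np.ndarray,
                        tr: CovarianceTransform) -> np.ndarray:
    """Exact GLS intercept given B and covariances (q-vector)."""
    W = tr.weights(rot.s)
    Z = (rot.Ytil - rot.Xtil @ B) @ tr.T.T
    i2 = rot.itil[:, None] ** 2
    theta = (W * rot.itil[:, None] * Z).sum(axis=0) / (W * i2).sum(axis=0)
    return np.linalg.solve(tr.T, theta)  # theta -> original trait basis


def _cov_step(rot: RotatedDataset, B: np.ndarray, cov0: CovariancePair,
              fix_cg_zero: bool, maxiter: int,
              profile_effects: bool = False) -> tuple:
    """Minimize the NLL over (Cg, Ce) at fixed B, intercept profiled.

    With ``profile_effects`` (only valid for p + 1 <= n, used by the
    unpenalized fit) the whole effect matrix is re-solved by exact GLS at
    every covariance evaluation; by the envelope theorem the covariance
    gradients at the GLS optimum are unchanged.
    """
    q = rot.q

    def split(x):
        return _build_cov(x, q, fix_cg_zero)

    def objective(x):
        try:
            cov, Lg, Le = split(x)
            tr = CovarianceTransform(cov)
        except (np.linalg.LinAlgError, ValueError):
            return 1e30, np.zeros_like(x)
        if profile_effects:
            from .likelihood import gls_effects
            B_loc, mu, _ = gls_effects(rot, cov, return_cov=False)
        else:
            B_loc = B
            mu = _profiled_intercept(rot, B, tr)
        nll = negative_log_likelihood(rot, B_loc, cov, intercept=mu,
                                      transform=tr)
        Gg, Ge = gradient_wrt_covariances(rot, B_loc, cov, intercept=mu,
                                          transform=tr)
        gLe = _pack_tril(2.0 * Ge @ Le)
        if fix_cg_zero:
            return nll, gLe
        gLg = _pack_tril(2.0 * Gg @ Lg)
        return nll, np.concatenate([gLg, gLe])

    Lg0 = _chol_psd(cov0.Cg)
    Le0 = _chol_psd(cov0.Ce - EPS_PD * np.eye(q))
    x0 = (_pack_tril(Le0) if fix_cg_zero
          else np.concatenate([_pack_tril(Lg0), _pack_tril(Le0)]))
    res = scipy.optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                                  options={"maxiter": maxiter})
    f0 = objective(x0)[0]
    if res.fun <= f0:
        cov, _, _ = split(res.x)
    else:  # L-BFGS may return a worse point on pathological surfaces
        cov = cov0
    tr = CovarianceTransform(cov)
    mu = _profiled_intercept(rot, B, tr)
    return cov, mu, min(float(res.fun), f0)


# ---------------------------------------------------------------------------
# B-step


def _design_norm(rot: RotatedDataset) -> float:
    """sigma_max of the rotated design [itil Xtil] (covariance-independent)."""
    D = np.column_stack([rot.itil, rot.Xtil])
    if min(D.shape) <= 400:
        return float(np.linalg.norm(D, 2))
    # power iteration for wide designs
    v = np.ones(D.shape[1]) / np.sqrt(D.shape[1])
    for _ in range(50):
        w = D.T @ (D @ v)
        nrm = np.linalg.norm(w)
        v = w / nrm
    return float(np.sqrt(nrm))


def _lipschitz(rot: RotatedDataset, cov: CovariancePair,
               smax: float | None = None) -> float:
    """Upper bound on the Lipschitz constant of grad_B(-LL):
    sigma_max([itil Xtil])^2 * max_i lambda_max(V_i^-1)."""
    if smax is None:
        smax = _design_norm(rot)
    V = rot.s[:, None, None] * cov.Cg + cov.Ce
    lam_min = np.linalg.eigvalsh(V)[:, 0].min()
    return smax ** 2 / max(lam_min, 1e-12)


def _fista(rot, cov, tr, B0, mu0, spec, opts: FitOptions, smax=None):
    """Monotone FISTA on Bfull = [intercept; B] with prox on the marker rows."""
    p, q = rot.p, rot.q
    Bfull = np.vstack([mu0[None, :], B0])

    def f(Bf):
        return negative_log_likelihood(rot, Bf[1:], cov, intercept=Bf[0],
                                       transform=tr)

    def grad(Bf):
        gB, gmu = gradient_wrt_effects(rot, Bf[1:], cov, intercept=Bf[0],
                                       transform=tr, with_intercept_grad=True)
        return np.vstack([gmu[None, :], gB])

    prox_state = {"state": None}

    def prox(Bf, step_):
        P, info = prox_combined(Bf[1:], spec, step_, tol=opts.prox_tol,
                                max_iter=opts.prox_max_iter,
                                warm_start=prox_state["state"])
        prox_state["state"] = info.get("state")
        return np.vstack([Bf[0][None, :], P])

    def F(Bf):
        return f(Bf) + penalty_value(Bf[1:], spec)

    step = 1.0 / _lipschitz(rot, cov, smax=smax)
    Yk = Bfull.copy()
    B_prev = Bfull.copy()
    t_prev = 1.0
    best = Bfull.copy()
    F_best = F(Bfull)
    F_prev = F_best
    for it in range(opts.fista_max):
        fy = f(Yk)
        gy = grad(Yk)
        while True:
            Bnew = prox(Yk - step * gy, step)
            diff = Bnew - Yk
            if (f(Bnew) <= fy + float(np.sum(gy * diff))
                    + float(np.sum(diff * diff)) / (2.0 * step) + 1e-12):
                break
            step *= opts.backtrack
            if step < 1e-18:
                Bnew = Yk
                break
        F_new = F(Bnew)
        if F_new < F_best:
            F_best, best = F_new, Bnew.copy()
        # adaptive restart on objective increase
        if F_new > F_prev:
            t_prev = 1.0
            Yk = best.copy()
            B_prev = best.copy()
            F_prev = F_best
            continue
        t = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_prev ** 2))
        Yk = Bnew + ((t_prev - 1.0) / t) * (Bnew - B_prev)
        rel = abs(F_prev - F_new) / max(1.0, abs(F_prev))
        B_prev, t_prev, F_prev = Bnew, t, F_new
        if rel < opts.fista_tol:
            break
    return best[1:], best[0], F_best


# ---------------------------------------------------------------------------
# public fitting API


def _init_cov(Y: np.ndarray) -> CovariancePair:
    S = np.cov(Y, rowvar=False)
    S = np.atleast_2d(S)
    if np.all(np.diag(S) == 0):
        raise ValueError("degenerate input: phenotypes have zero variance")
    half = 0.5 * S + EPS_PD * np.eye(S.shape[0])
    return CovariancePair(half.copy(), half.copy())


def lambda_max(rot: RotatedDataset, cov: CovariancePair) -> float:
    """Smallest L1 weight at which the whole effect matrix is zero
    (intercept aside), at the given covariances."""
    tr = CovarianceTransform(cov)
    mu = _profiled_intercept(rot, np.zeros((rot.p, rot.q)), tr)
    g = gradient_wrt_effects(rot, np.zeros((rot.p, rot.q)), cov,
                             intercept=mu, transform=tr)
    return float(np.abs(g).max())


def lambda_noise_floor(rot: RotatedDataset, cov: CovariancePair,
                       seed: int = 0, n_perm: int = 2) -> float:
    """Permutation-calibrated noise level of the effect gradient at B = 0.

    Residuals from the intercept-only model are standardized in the
    doubly-rotated coordinates (where they are exchangeable under the
    null), permuted within each transformed trait, and the gradient
    infinity-norm is recomputed.  The mean over permutations estimates
    the largest gradient entry produced by noise alone: an L1 weight at
    or above this level screens out null markers.
    """
    rng = np.random.default_rng(seed)
    tr = CovarianceTransform(cov)
    W = tr.weights(rot.s)
    mu = _profiled_intercept(rot, np.zeros((rot.p, rot.q)), tr)
    R = (rot.Ytil - np.outer(rot.itil, mu)) @ tr.T.T
    E = R * np.sqrt(W)  # standardized: iid N(0,1) per entry under the null
    vals = []
    for _ in range(n_perm):
        Ep = np.empty_like(E)
        for k in range(E.shape[1]):
            Ep[:, k] = E[rng.permutation(E.shape[0]), k]
        Rp = Ep / np.sqrt(W)
        g = -rot.Xtil.T @ ((Rp * W) @ tr.T)
        vals.append(float(np.abs(g).max()))
    return float(np.mean(vals))


def default_lambda_grid(rot: RotatedDataset, cov: CovariancePair,
                        n_lam: int = 10, lam_min_ratio: float = 0.01,
                        gammas=(0.0,)) -> list[PenaltySpec]:
    """Log-spaced lambda path from lambda_max down, crossed with gammas."""
    lmax = lambda_max(rot, cov)
    lams = np.geomspace(lmax, lam_min_ratio * lmax, n_lam)
    return [PenaltySpec(lam=float(l), gamma=float(g))
            for l in lams for g in gammas]


def fit_regularized_mtlmm(data: AlignedDataset, spec: PenaltySpec,
                          opts: FitOptions | None = None,
                          model: str = "mtLMM") -> FitResult:
    """Fit the penalized multi-trait (mixed) model.

    Parameters
    ----------
    data
        Aligned phenotypes, genotypes and kinship.  Genotypes should be
        standardized so the L1 weight acts uniformly across markers.
    spec
        Penalty weights (lam, gamma) and optional clustering edges.
    model
        ``"mtLMM"`` fits the full mixed model; ``"mtLM"`` freezes the
        genetic covariance Cg at zero (fixed-effects-only comparator).
    """
    if model not in ("mtLMM", "mtLM"):
        raise ValueError("model must be 'mtLMM' or 'mtLM'")
    opts = opts or FitOptions()
    spec = spec.resolve(data.q)
    eig = eigendecompose_kinship(data.kinship)
    rot = rotate(eig, data.traits, data.genotypes)
    fix_cg = model == "mtLM"

    cov = _init_cov(data.traits.values)
    if fix_cg:
        cov = CovariancePair(np.zeros((data.q, data.q)), 2.0 * cov.Ce)
    B = np.zeros((rot.p, rot.q))
    tr = CovarianceTransform(cov)
    mu = _profiled_intercept(rot, B, tr)
    smax = _design_norm(rot)

    trace = []
    obj = negative_log_likelihood(rot, B, cov, intercept=mu, transform=tr) \
        + penalty_value(B, spec)
    converged = False
    n_outer = 0
    unpenalized_exact = (spec.lam == 0.0 and spec.gamma == 0.0
                         and rot.p + 1 <= rot.n)
    for n_outer in range(1, opts.outer_max + 1):
        if unpenalized_exact:
            from .likelihood import gls_effects
            B_new, mu_new, _ = gls_effects(rot, cov, return_cov=False)
            obj_b = negative_log_likelihood(rot, B_new, cov,
                                            intercept=mu_new, transform=tr)
        else:
            B_new, mu_new, obj_b = _fista(rot, cov, tr, B, mu, spec,
                                           opts, smax=smax)
        if obj_b <= obj:
            B, mu, obj = B_new, mu_new, obj_b
        cov_new, mu_c, nll_c = _cov_step(rot, B, cov, fix_cg, opts.cov_maxiter,
                                         profile_effects=unpenalized_exact)
        if unpenalized_exact:
            from .likelihood import gls_effects
            tr_new = CovarianceTransform(cov_new)
            B_c, mu_c, _ = gls_effects(rot, cov_new, return_cov=False)
            obj_c = negative_log_likelihood(rot, B_c, cov_new, intercept=mu_c,
                                            transform=tr_new)
            if obj_c <= obj:
                B, cov, mu, obj, tr = B_c, cov_new, mu_c, obj_c, tr_new
        else:
            obj_c = nll_c + penalty_value(B, spec)
            if obj_c <= obj:
                cov, mu, obj = cov_new, mu_c, obj_c
                tr = CovarianceTransform(cov)
        trace.append(obj)
        if len(trace) > 1:
            rel = (trace[-2] - trace[-1]) / max(1.0, abs(trace[-2]))
            if rel < opts.outer_tol:
                converged = True
                break
    if len(trace) > 1 and np.any(np.diff(trace) > 1e-8):
        raise RuntimeError(f"penalized objective increased along the outer "
                           f"trace: {trace}")
    B_hat = EffectMatrix(B, data.genotypes.marker_ids,
                         data.traits.trait_names)
    return FitResult(B_hat=B_hat, intercept=mu, cov_hat=cov,
                     objective_trace=trace, converged=converged, spec=spec,
                     n_outer=n_outer, model=model)


def fit_variance_components_null(data: AlignedDataset,
                                 cov_maxiter: int = 200) -> CovariancePair:
    """ML estimates of (Cg, Ce) under the intercept-only null model."""
    Y = data.traits.values
    if np.all(Y.std(axis=0) == 0):
        raise ValueError("degenerate input: phenotypes have zero variance")
    K = data.kinship.values
    n = data.n
    if np.allclose(K, np.eye(n), atol=1e-10):
        warnings.warn("kinship is the identity: Cg and Ce are not separately "
                      "identifiable; forcing Cg = 0")
        resid = Y - Y.mean(axis=0)
        Ce = resid.T @ resid / n + EPS_PD * np.eye(data.q)
        return CovariancePair(np.zeros((data.q, data.q)), Ce)
    eig = eigendecompose_kinship(data.kinship)
    rot = rotate(eig, data.traits, data.genotypes)
    B = np.zeros((rot.p, rot.q))
    cov, _, _ = _cov_step(rot, B, _init_cov(Y), fix_cg_zero=False,
                          maxiter=cov_maxiter)
    return cov


def fit_univariate_ml(s: np.ndarray, ytil: np.ndarray, Dtil: np.ndarray):
    """Univariate LMM ML fit in the eigenbasis by 1-D heritability profiling.

    Model: ytil ~ N(Dtil beta, sg2 * diag(s) + se2 * I).  Profiles beta and
    the total variance in closed form and optimizes the variance ratio
    h = sg2 / (sg2 + se2) numerically.  Returns (sg2, se2, beta, nll).
    """
    n = ytil.shape[0]
    Dtil = np.atleast_2d(Dtil.T).T

    def profile(h):
        w = 1.0 / (h * s + (1.0 - h))
        DW = Dtil * w[:, None]
        A = Dtil.T @ DW
        beta = np.linalg.solve(A, DW.T @ ytil)
        r = ytil - Dtil @ beta
        sigma2 = float(np.sum(w * r * r)) / n
        sigma2 = max(sigma2, 1e-300)
        nll = 0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2)
                     - float(np.sum(np.log(w))) + n)
        return nll, beta, sigma2

    res = scipy.optimize.minimize_scalar(lambda h: profile(h)[0],
                                         bounds=(0.0, 1.0 - 1e-8),
                                         method="bounded",
                                         options={"xatol": 1e-10})
    h = float(res.x)
    # guard against a boundary minimum at h = 0
    nll0 = profile(0.0)[0]
    if nll0 < profile(h)[0]:
        h = 0.0
    nll, beta, sigma2 = profile(h)
    return h * sigma2, (1.0 - h) * sigma2, beta, nll


def select_regularization(train: AlignedDataset, grid: list[PenaltySpec],
                          opts: FitOptions | None = None,
                          holdout_fraction: float = 0.2,
                          seed: int = 0, model: str = "mtLMM"):
    """Pick penalty weights by accuracy on a single inner holdout split.

    Each candidate is fitted on the inner training part; genomic breeding
    values are predicted for the held-out individuals and scored by the
    mean per-trait Pearson correlation.  Ties prefer stronger
    regularization (larger lam, then larger gamma).  The caller refits the
    winner on the full training set.
    """
    from .prediction import pearson_accuracy, predict_gebv

    if not grid:
        raise ValueError("empty regularization grid")
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = train.n
    n_hold = max(2, int(round(holdout_fraction * n)))
    perm = rng.permutation(n)
    hold_idx, fit_idx = np.sort(perm[:n_hold]), np.sort(perm[n_hold:])
    inner = train.subset(fit_idx)
    rows = []
    for spec in grid:
        try:
            fit = fit_regularized_mtlmm(inner, spec, opts, model=model)
            pred = predict_gebv(fit, train, fit_idx, hold_idx)
            accs = pearson_accuracy(train.traits.values[hold_idx], pred)
            score = (np.nan if np.all(np.isnan(accs))
                     else float(np.nanmean(accs)))
        except (np.linalg.LinAlgError, RuntimeError, ValueError):
            score = np.nan
        rows.append((spec, score))
    if all(np.isnan(score) for _, score in rows):
        raise RuntimeError("regularization selection failed for every "
                           "candidate in the grid")
    best = max(rows, key=lambda r: (np.nan_to_num(r[1], nan=-np.inf),
                                    r[0].lam, r[0].gamma))
    return best[0], rows
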