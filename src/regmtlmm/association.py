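"""Single-marker association scans, FDR control, and stability counting.

Two single-marker engines are provided: the univariate LMM scan fitted to
one trait at a time (stLMM-sm) and the multi-trait LMM scan (mtLMM-sm).
Both estimate variance components once under the marker-free null model
and reuse them for every marker, testing each marker's effect with a Wald
chi-square (1 df per trait for the univariate scan, q df for the joint
scan).  Markers pass through Benjamini-Hochberg FDR control across the
scan.  Regularized detectors declare a (marker, trait) pair detected when
its fitted coefficient is non-zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .containers import AlignedDataset, CovariancePair, EffectMatrix
from .estimation import (NONZERO_TOL, FitOptions, PenaltySpec,
                         fit_regularized_mtlmm, fit_univariate_ml,
                         fit_variance_components_null, lambda_max)
from .likelihood import (CovarianceTransform, eigendecompose_kinship, rotate)

__all__ = ["ScanResult", "SupportMatrix", "StabilityCounts",
           "benjamini_hochberg", "scan_single_trait", "scan_multi_trait",
           "detected_support", "stability_counts", "METHODS"]

METHODS = ("stLMM-sm", "mtLMM-sm", "mtLMM-L1", "mtLM-L1",
           "mtLMM-clust", "mtLM-clust")


@dataclass
class ScanResult:
    """Per-marker Wald statistics, p-values and post-BH rejections."""

    marker_ids: np.ndarray
    statistic: np.ndarray
    pvalue: np.ndarray
    df: int
    rejected: np.ndarray
    fdr: float


@dataclass
class SupportMatrix:
    """Boolean p x q detection matrix."""

    values: np.ndarray
    marker_ids: np.ndarray
    trait_names: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)


@dataclass
class StabilityCounts:
    """Detection frequencies over repeated subsampling experiments."""

    frequency: np.ndarray          # p x q in [0, 1]
    max_frequency: np.ndarray      # p, rowwise max over traits
    n_subsamples: int
    marker_ids: np.ndarray
    trait_names: np.ndarray


def benjamini_hochberg(pvalues, fdr: float) -> np.ndarray:
    """BH step-up rule: reject all p <= p_(k), k = max{i : p_(i) <= i*fdr/m}.

    NaN entries (undefined tests) are excluded from m and never rejected.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    out = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p.ravel())
    pv = p.ravel()[ok]
    m = pv.size
    if m == 0:
        return out
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="stable")
    ranked = pv[order]
    passed = np.nonzero(ranked <= (np.arange(1, m + 1) * fdr / m))[0]
    flat = np.zeros(m, dtype=bool)
    if passed.size:
        flat[order[: passed[-1] + 1]] = True
    out.ravel()[np.nonzero(ok)[0]] = flat
    return out


def _marker_wald_1d(w: np.ndarray, itil: np.ndarray, Xtil: np.ndarray,
                    z: np.ndarray):
    """Vectorized per-marker Wald chi2(1) for one (transformed) trait.

    Weighted regression of z on [intercept, marker], weights w; returns
    (slope, var_slope) arrays over markers, NaN where the weighted marker
    variance vanishes.
    """
    sw = w.sum()
    i1 = float(w @ itil)
    i2 = float(w @ (itil * itil))
    zi = float(w @ (itil * z))
    Xw = Xtil * w[:, None]
    xx = np.einsum("ij,ij->j", Xtil, Xw)
    xi = itil @ Xw
    xz = z @ Xw
    denom = xx - xi * xi / i2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (xz - xi * zi / i2) / denom
        var = 1.0 / denom
    bad = denom <= 1e-12
    slope[bad] = np.nan
    var[bad] = np.nan
    return slope, var


def scan_single_trait(data: AlignedDataset, trait: int,
                      fdr: float = 0.05) -> ScanResult:
    """Univariate LMM single-marker scan for one trait.

    Variance components (sg2, se2) come from the intercept-only null fit
    for that trait; each marker is then tested by GLS with a Wald
    chi-square on 1 df, followed by BH across the scan's markers.
    """
    if not 0 <= trait < data.q:
        raise IndexError("trait index out of range")
    eig = eigendecompose_kinship(data.kinship)
    rot = rotate(eig, data.traits, data.genotypes)
    y = rot.Ytil[:, trait]
    sg2, se2, _, _ = fit_univariate_ml(rot.s, y, rot.itil[:, None])
    total = max(sg2 + se2, 1e-300)
    h = sg2 / total
    w = 1.0 / (total * (h * rot.s + (1.0 - h)))
    slope, var = _marker_wald_1d(w, rot.itil, rot.Xtil, y)
    stat = slope * slope / var
    pval = scipy.stats.chi2.sf(stat, df=1)
    rejected = benjamini_hochberg(pval, fdr)
    return ScanResult(data.genotypes.marker_ids, stat, pval, 1, rejected, fdr)


def scan_multi_trait(data: AlignedDataset, fdr: float = 0.05,
                     cov: CovariancePair | None = None) -> ScanResult:
    """Multi-trait LMM single-marker scan: one Wald chi2(q) per marker.

    (Cg, Ce) are estimated once under the null and reused; per marker the
    q-vector of effects is estimated by GLS (with intercept) and tested
    jointly.
    """
    eig = eigendecompose_kinship(data.kinship)
    rot = rotate(eig, data.traits, data.genotypes)
    if cov is None:
        if data.q == 1:
            # the 1-D profile fit is exact on the flat sg2 ~ 0 ridge
            sg2, se2, _, _ = fit_univariate_ml(rot.s, rot.Ytil[:, 0],
                                               rot.itil[:, None])
            cov = CovariancePair([[sg2]], [[max(se2, 1e-8)]])
        else:
            cov = fit_variance_components_null(data)
    tr = CovarianceTransform(cov)
    W = tr.weights(rot.s)
    Z = rot.Ytil @ tr.T.T
    q = rot.q
    slopes = np.empty((rot.p, q))
    variances = np.empty((rot.p, q))
    for k in range(q):
        slopes[:, k], variances[:, k] = _marker_wald_1d(
            W[:, k], rot.itil, rot.Xtil, Z[:, k])
    # transformed-trait estimates are independent, so the joint Wald for the
    # original-basis effect vector b = T^-1 theta collapses to a weighted sum
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.nansum(slopes * slopes / variances, axis=1)
    stat[np.isnan(slopes).all(axis=1)] = np.nan
    pval = scipy.stats.chi2.sf(stat, df=q)
    rejected = benjamini_hochberg(pval, fdr)
    return ScanResult(data.genotypes.marker_ids, stat, pval, q, rejected, fdr)


def detected_support(B_hat: EffectMatrix, tol: float = NONZERO_TOL) -> SupportMatrix:
    """Mark (marker, trait) pairs with |effect| above tol as detected."""
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    return SupportMatrix(np.abs(B_hat.values) > tol, B_hat.marker_ids,
                         B_hat.trait_names)


def _regularized_support(data: AlignedDataset, method: str,
                         opts: FitOptions | None,
                         lam_frac: float, gamma_frac: float,
                         seed: int = 0) -> np.ndarray:
    """Fit a regularized detector with data-driven penalty weights and
    return its boolean support (p x q).

    The L1 weight is lam_frac * lambda_max, floored at the
    permutation-calibrated noise level of the gradient so that null data
    (where lambda_max itself is pure noise) yields an empty model instead
    of cascading into the p >> n interpolation regime.
    """
    from .containers import CovariancePair
    from .estimation import _init_cov, lambda_noise_floor
    model = "mtLMM" if method.startswith("mtLMM") else "mtLM"
    eig = eigendecompose_kinship(data.kinship)
    rot = rotate(eig, data.traits, data.genotypes)
    cov0 = _init_cov(data.traits.values)
    if model == "mtLM":
        # match the fit's own starting covariance (no genetic component)
        cov0 = CovariancePair(np.zeros_like(cov0.Cg), 2.0 * cov0.Ce)
    lmax = lambda_max(rot, cov0)
    lam = max(lam_frac * lmax, lambda_noise_floor(rot, cov0, seed=seed))
    gamma = gamma_frac * lmax if method.endswith("clust") else 0.0
    spec = PenaltySpec(lam=lam, gamma=gamma)
    fit = fit_regularized_mtlmm(data, spec, opts, model=model)
    return fit.support


def _detect(data: AlignedDataset, method: str, fdr: float,
            opts: FitOptions | None = None, lam_frac: float = 0.2,
            gamma_frac: float = 0.2, seed: int = 0) -> np.ndarray:
    """Run one detector, returning a boolean p x q detection matrix.

    The marker-level mtLMM-sm verdict is replicated across traits so every
    method shares the (marker, trait) detection geometry.
    """
    p, q = data.p, data.q
    if method == "stLMM-sm":
        out = np.zeros((p, q), dtype=bool)
        for j in range(q):
            out[:, j] = scan_single_trait(data, j, fdr).rejected
        return out
    if method == "mtLMM-sm":
        rej = scan_multi_trait(data, fdr).rejected
        return np.repeat(rej[:, None], q, axis=1)
    if method in METHODS:
        return _regularized_support(data, method, opts, lam_frac, gamma_frac,
                                    seed=seed)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def stability_counts(data: AlignedDataset, method: str,
                     n_subsamples: int = 50, subsample_fraction: float = 0.8,
                     fdr: float = 0.05, seed: int = 0,
                     opts: FitOptions | None = None) -> StabilityCounts:
    """Detection frequency of each marker over repeated random subsamples.

    Draws ``n_subsamples`` subsets of ``subsample_fraction`` of the
    individuals (without replacement), runs the chosen detector on each,
    and reports the per-(marker, trait) detection frequency together with
    the per-marker maximum over traits.
    """
    if not 0 < subsample_fraction < 1:
        raise ValueError("subsample_fraction must lie in (0, 1)")
    if n_subsamples < 1:
        raise ValueError("need at least one subsample")
    n_keep = int(round(subsample_fraction * data.n))
    if n_keep < data.q + 2:
        raise ValueError("subsample smaller than q + 2 individuals")
    rng = np.random.default_rng(seed)
    counts = np.zeros((data.p, data.q))
    for _ in range(n_subsamples):
        idx = np.sort(rng.choice(data.n, size=n_keep, replace=False))
        counts += _detect(data.subset(idx), method, fdr, opts=opts,
                          seed=int(rng.integers(2 ** 31 - 1)))
    freq = counts / n_subsamples
    return StabilityCounts(freq, freq.max(axis=1), n_subsamples,
                           data.genotypes.marker_ids, data.traits.trait_names)
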