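"""Phenotype and genotype simulation for benchmarking QTN detection.

Phenotypes are drawn from the multi-trait mixed model Y = X B + G + E with
matrix-variate G ~ N(0, Cg, K) and E ~ N(0, Ce, I).  The fixed-effect
matrix B follows one of four architectures:

1. **random** — each trait receives its own random set of QTNs with iid
   N(0, 1) effects;
2. **clustered** — traits are partitioned into groups; traits within a
   group share one QTN support, with effects mu_i(group) + eps_ij
   (group-shared mean, trait-specific N(0, 0.25) wiggle, mu ~ U[-1, 1]);
3. **mixed** — the sum of a random draw (20 QTNs/trait) and a clustered
   draw (80 QTNs/group);
4. **null** — no fixed effects at all (false-positive-rate scenario).

Synthetic genotypes come from a Balding-Nichols subpopulation model so the
panel carries the population structure that the kinship random effect must
correct for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .containers import (AlignedDataset, CovariancePair, EffectMatrix,
                         GenotypeMatrix, KinshipMatrix, TraitMatrix)
from .association import SupportMatrix, _detect
from .preprocess import compute_vanraden_kinship, standardize_genotypes

__all__ = [
    "ScenarioSpec", "GroundTruth", "DetectionMetrics",
    "generate_effect_matrix", "sample_matrix_normal", "simulate_phenotypes",
    "generate_structured_genotypes", "evaluate_detection",
    "default_covariances", "make_synthetic_dataset", "run_scenario_benchmark",
]


def default_groups(q: int) -> list[list[int]]:
    """Trait partition for the clustered scenarios: two groups of three and
    one group holding the remaining q - 6 traits (dropped when empty)."""
    if q < 6:
        raise ValueError("clustered scenarios need at least 6 traits")
    groups = [list(range(0, 3)), list(range(3, 6))]
    if q > 6:
        groups.append(list(range(6, q)))
    return groups


@dataclass
class ScenarioSpec:
    """Configuration of one simulated trait architecture."""

    scenario: int                      # 1 random, 2 clustered, 3 mixed, 4 null
    q: int
    p: int
    qtn_per_trait: int = 100
    mixed_split: tuple = (20, 80)
    groups: list | None = None
    eps_sd: float = 0.5                # trait-specific wiggle sd (variance 0.25)
    shared_mu: bool = True             # group-shared mu_i vs per-entry mu_ij
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in (1, 2, 3, 4):
            raise ValueError("scenario must be 1, 2, 3 or 4")
        if self.scenario != 4 and self.qtn_per_trait > self.p:
            raise ValueError("more QTNs requested than markers available")
        if self.scenario in (2, 3) and self.groups is None:
            self.groups = default_groups(self.q)
        if self.groups is not None:
            flat = sorted(i for g in self.groups for i in g)
            if flat != list(range(self.q)):
                raise ValueError("groups must partition the trait indices")
        if self.scenario == 3 and sum(self.mixed_split) > self.p:
            raise ValueError("mixed split exceeds marker count")


@dataclass
class GroundTruth:
    """True effect matrix, its support, and the generating scenario."""

    B_true: EffectMatrix
    support: SupportMatrix
    scenario: ScenarioSpec


@dataclass
class DetectionMetrics:
    """Confusion-matrix summaries over (marker, trait) pairs."""

    precision: float
    recall: float
    f1: float
    fpr: float
    tp: int
    fp: int
    fn: int


def _labels(prefix: str, k: int) -> np.ndarray:
    return np.asarray([f"{prefix}{i}" for i in range(k)], dtype=str)


def _random_effects(p: int, q: int, qtn: int, rng) -> np.ndarray:
    B = np.zeros((p, q))
    for j in range(q):
        rows = rng.choice(p, size=qtn, replace=False)
        B[rows, j] = rng.standard_normal(qtn)
    return B


def _clustered_effects(p: int, q: int, qtn: int, groups, eps_sd: float,
                       shared_mu: bool, rng) -> np.ndarray:
    B = np.zeros((p, q))
    for group in groups:
        rows = rng.choice(p, size=qtn, replace=False)
        if shared_mu:
            mu = rng.uniform(-1.0, 1.0, size=qtn)
            for j in group:
                B[rows, j] = mu + rng.normal(0.0, eps_sd, size=qtn)
        else:
            for j in group:
                B[rows, j] = (rng.uniform(-1.0, 1.0, size=qtn)
                              + rng.normal(0.0, eps_sd, size=qtn))
    return B


def generate_effect_matrix(spec: ScenarioSpec,
                           rng: np.random.Generator | None = None,
                           marker_ids=None, trait_names=None) -> GroundTruth:
    """Draw the ground-truth effect matrix for a scenario."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    p, q = spec.p, spec.q
    if spec.scenario == 1:
        B = _random_effects(p, q, spec.qtn_per_trait, rng)
    elif spec.scenario == 2:
        B = _clustered_effects(p, q, spec.qtn_per_trait, spec.groups,
                               spec.eps_sd, spec.shared_mu, rng)
    elif spec.scenario == 3:
        B = (_random_effects(p, q, spec.mixed_split[0], rng)
             + _clustered_effects(p, q, spec.mixed_split[1], spec.groups,
                                  spec.eps_sd, spec.shared_mu, rng))
    else:
        B = np.zeros((p, q))
    marker_ids = marker_ids if marker_ids is not None else _labels("m", p)
    trait_names = trait_names if trait_names is not None else _labels("t", q)
    eff = EffectMatrix(B, marker_ids, trait_names)
    return GroundTruth(eff, SupportMatrix(B != 0.0, marker_ids, trait_names),
                       spec)


def sample_matrix_normal(row_cov: np.ndarray, col_cov: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """One draw of N_{n x q}(0, col_cov, row_cov): vec-covariance
    col_cov (x) row_cov."""
    row_cov = np.asarray(row_cov, float)
    col_cov = np.asarray(col_cov, float)
    for name, C in (("row_cov", row_cov), ("col_cov", col_cov)):
        if np.linalg.eigvalsh(0.5 * (C + C.T)).min() < -1e-8:
            raise ValueError(f"{name} is not PSD")
    n, q = row_cov.shape[0], col_cov.shape[0]
    if not col_cov.any():
        return np.zeros((n, q))
    L_row = _psd_factor(row_cov)
    L_col = _psd_factor(col_cov)
    Z = rng.standard_normal((n, q))
    return L_row @ Z @ L_col.T


def _psd_factor(C: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(0.5 * (C + C.T))
        return V * np.sqrt(np.clip(w, 0.0, None))


def simulate_phenotypes(genotypes: GenotypeMatrix, kinship: KinshipMatrix,
                        truth: GroundTruth, cov: CovariancePair,
                        rng: np.random.Generator) -> TraitMatrix:
    """Draw Y = X B_true + G + E from the generating model."""
    X = genotypes.values
    B = truth.B_true.values
    if X.shape[1] != B.shape[0] or kinship.n != X.shape[0]:
        raise ValueError("shape mismatch between genotypes, kinship and truth")
    G = sample_matrix_normal(kinship.values, cov.Cg, rng)
    E = sample_matrix_normal(np.eye(X.shape[0]), cov.Ce, rng)
    return TraitMatrix(X @ B + G + E, genotypes.individual_ids,
                       truth.B_true.trait_names)


def generate_structured_genotypes(n: int, p: int, n_subpops: int = 3,
                                  fst: float = 0.2,
                                  maf_range: tuple = (0.05, 0.5),
                                  rng: np.random.Generator | None = None
                                  ) -> GenotypeMatrix:
    """Balding-Nichols genotypes with subpopulation structure.

    Ancestral frequencies are uniform on ``maf_range``; each subpopulation
    draws its frequency from Beta(pi (1-fst)/fst, (1-pi)(1-fst)/fst), and
    genotypes are Binomial(2, freq).  Monomorphic columns are resampled.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if not 0 <= fst < 1:
        raise ValueError("fst must lie in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo < hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
    sizes = np.full(n_subpops, n // n_subpops)
    sizes[: n % n_subpops] += 1
    membership = np.repeat(np.arange(n_subpops), sizes)
    X = np.empty((n, p))
    for j in range(p):
        for _ in range(100):
            anc = rng.uniform(lo, hi)
            if fst == 0.0:
                freqs = np.full(n_subpops, anc)
            else:
                a = anc * (1.0 - fst) / fst
                b = (1.0 - anc) * (1.0 - fst) / fst
                freqs = rng.beta(a, b, size=n_subpops)
            col = rng.binomial(2, freqs[membership]).astype(float)
            if col.std() > 0:
                X[:, j] = col
                break
        else:
            raise RuntimeError("could not draw a polymorphic marker")
    return GenotypeMatrix(X, _labels("ind", n), _labels("m", p))


def evaluate_detection(estimated: SupportMatrix | np.ndarray,
                       truth: SupportMatrix | np.ndarray) -> DetectionMetrics:
    """Score one detection replicate over (marker, trait) pairs.

    precision defaults to 1 when nothing is detected; f1 is 0 when there
    are no true positives but errors exist; fpr divides false positives by
    the number of truly-null pairs.
    """
    est = estimated.values if isinstance(estimated, SupportMatrix) else np.asarray(estimated, bool)
    tru = truth.values if isinstance(truth, SupportMatrix) else np.asarray(truth, bool)
    if est.shape != tru.shape:
        raise ValueError("shape mismatch between estimated and true support")
    tp = int(np.sum(est & tru))
    fp = int(np.sum(est & ~tru))
    fn = int(np.sum(~est & tru))
    n_null = int(np.sum(~tru))
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    if tp == 0 and (fp or fn):
        f1 = 0.0
    fpr = fp / n_null if n_null else 0.0
    return DetectionMetrics(precision, recall, f1, fpr, tp, fp, fn)


def default_covariances(genotypes: GenotypeMatrix, kinship: KinshipMatrix,
                        truth: GroundTruth, groups=None,
                        within_corr: float = 0.5) -> CovariancePair:
    """Synthetic-mode trait covariances scaled to the fixed-effect signal.

    Cg has unit variances with correlation ``within_corr`` inside each
    trait group; Ce is diagonal.  Both are rescaled together so the total
    random variance matches the total variance of X B_true (fixed-effect
    heritability approximately one half).  For the null scenario the base
    covariances are returned unscaled.
    """
    q = truth.B_true.q
    Cg = np.eye(q)
    use_groups = groups
    if use_groups is None:
        use_groups = truth.scenario.groups if truth.scenario.groups else [list(range(q))]
    for g in use_groups:
        for a in g:
            for b in g:
                if a != b:
                    Cg[a, b] = within_corr
    Ce = np.eye(q)
    signal = (genotypes.values @ truth.B_true.values).var(axis=0).sum()
    if signal > 0:
        noise = float(np.diag(Cg).sum() * np.mean(np.diag(kinship.values))
                      + np.diag(Ce).sum())
        scale = signal / noise
        Cg = Cg * scale
        Ce = Ce * scale
    return CovariancePair(Cg, Ce + 1e-8 * np.eye(q))


def make_synthetic_dataset(spec: ScenarioSpec, n: int,
                           cov: CovariancePair | None = None,
                           n_subpops: int = 3, fst: float = 0.2,
                           rng: np.random.Generator | None = None):
    """Generate a full aligned dataset (genotypes, kinship, phenotypes)
    plus the ground truth for one scenario replicate.

    Genotypes are standardized (the fitting scale); the kinship comes from
    the raw dosages via the VanRaden estimator.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    raw = generate_structured_genotypes(n, spec.p, n_subpops=n_subpops,
                                        fst=fst, rng=rng)
    kin = compute_vanraden_kinship(raw)
    geno = standardize_genotypes(raw)
    truth = generate_effect_matrix(spec, rng, marker_ids=geno.marker_ids)
    if cov is None:
        cov = default_covariances(geno, kin, truth)
    traits = simulate_phenotypes(geno, kin, truth, cov, rng)
    data = AlignedDataset(traits=traits, genotypes=geno, kinship=kin)
    return data, truth, cov


def run_scenario_benchmark(genotypes: GenotypeMatrix, kinship: KinshipMatrix,
                           cov: CovariancePair | None,
                           scenarios: list[ScenarioSpec], methods: list[str],
                           n_replicates: int = 50, fdr: float = 0.05,
                           seed: int = 0, opts=None, lam_frac: float = 0.2,
                           gamma_frac: float = 0.2) -> pd.DataFrame:
    """Simulate phenotype replicates per scenario and score each detector.

    For every replicate, phenotypes are drawn on the fixed genotype panel,
    each method produces a (marker, trait) detection matrix (BH-controlled
    p-values for the single-marker scans, non-zero coefficients for the
    regularized fits), and precision/recall/F1/FPR are recorded.  Returns
    a tidy per-replicate table; aggregate with
    ``df.groupby(["scenario", "method"]).mean()``.
    """
    from .association import METHODS
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    rows = []
    ss = np.random.SeedSequence(seed)
    for spec in scenarios:
        scen_rng = np.random.default_rng(ss.spawn(1)[0])
        for rep in range(n_replicates):
            truth = generate_effect_matrix(spec, scen_rng,
                                           marker_ids=genotypes.marker_ids)
            rep_cov = cov if cov is not None else default_covariances(
                genotypes, kinship, truth)
            traits = simulate_phenotypes(genotypes, kinship, truth,
                                         rep_cov, scen_rng)
            data = AlignedDataset(traits=traits, genotypes=genotypes,
                                  kinship=kinship)
            det_seed = (seed * 100003 + spec.scenario * 1009 + rep) % (2 ** 31)
            for method in methods:
                det = _detect(data, method, fdr, opts=opts,
                              lam_frac=lam_frac, gamma_frac=gamma_frac,
                              seed=det_seed)
                m = evaluate_detection(det, truth.support.values)
                rows.append({"scenario": spec.scenario, "replicate": rep,
                             "method": method, "precision": m.precision,
                             "recall": m.recall, "f1": m.f1, "fpr": m.fpr,
                             "tp": m.tp, "fp": m.fp, "fn": m.fn})
    return pd.DataFrame(rows)
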