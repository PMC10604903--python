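# Methods

## Model

`regmtlmm` fits the multi-trait linear mixed model (mtLMM) for a panel of
n individuals, q traits and p markers:

    Y = X B + G + E,
    G ~ N_{n×q}(0, C_g, K),      E ~ N_{n×q}(0, C_e, I_n),

where Y (n×q) holds the phenotypes, X (n×p) the marker scores, B (p×q)
the fixed marker effects, K the genomic relationship matrix, and
N_{n×q}(M, Ψ, Φ) is the matrix-variate normal with column covariance Ψ
(traits) and row covariance Φ (individuals).  Equivalently
vec(Y) ~ N_nq(vec(XB), C_g ⊗ K + C_e ⊗ I_n).  The random effect G absorbs
polygenic background variation structured by relatedness — the source of
spurious marker-trait associations in diversity panels — while C_g and
C_e capture genetic and residual covariance between traits.

A trait-specific intercept (column of ones) is always part of the fixed
design and is never penalized.

## Penalized estimation

With p ≫ n the joint fit is regularized:

    minimize over (B, C_g, C_e):   −LL(B, C_g, C_e) + R(B)

with either the entrywise L1 penalty R(B) = λ Σ_ij |B_ij| (marker
selection) or the combined L1 + convex-clustering penalty

    R(B) = λ Σ_ij |B_ij| + γ Σ_{(j,j')∈E} c_jj' ‖B_:j − B_:j'‖₂,

whose second term shrinks the effect profiles of trait pairs toward each
other.  The edge set defaults to the complete graph over traits with unit
weights; weights c_jj' can encode prior knowledge of trait relatedness.
The Euclidean norm is used for the clustering term, consistent with the
convex-clustering literature.

### Likelihood evaluation

All likelihood code works in the eigenbasis of K = U diag(s) U′.  Rotating
Ỹ = U′Y, X̃ = U′X turns the nq×nq covariance into n independent q×q blocks
V_i = s_i C_g + C_e.  A second congruence transform T that simultaneously
diagonalizes (C_g, C_e) — solve C_e = L_e L_e′, eigendecompose
L_e⁻¹ C_g L_e⁻ᵀ = Q diag(d) Q′, set T = Q′L_e⁻¹ — gives
T V_i T′ = diag(s_i d + 1), so the log-likelihood, its B-gradient and its
covariance gradients reduce to elementwise operations on an n×q weight
array W_ik = 1/(s_i d_k + 1).  One likelihood/gradient evaluation costs
O(npq + nq² + q³); the dense Kronecker matrix is never formed outside the
test oracles.

### Optimizer

The penalized criterion is minimized by block alternation:

* **B-step**: FISTA (accelerated proximal gradient) with adaptive restart
  and backtracking line search, starting from step 1/L̂ with
  L̂ = σ_max([ĩ X̃])² · max_i λ_max(V_i⁻¹).  The combined penalty's
  proximal operator has no closed form; it is solved by a consensus ADMM
  (ρ = 1) splitting the quadratic coupling, one exact soft-threshold
  block for the L1 term and one exact group-shrinkage block per
  clustering edge.  The per-iteration B-update solves a single q×q system
  built from the edge-graph Laplacian, and the ADMM state is warm-started
  across FISTA iterations.  ADMM stops at primal/dual residuals ≤ 1e-6
  (max 200 iterations, warning on non-convergence).
* **covariance-step**: L-BFGS on Cholesky parameterizations
  C_g = L_g L_g′ and C_e = L_e L_e′ + 1e-8·I, holding B fixed.  The
  intercept is profiled out exactly, so envelope differentiation applies.
  For the unpenalized case (λ = γ = 0, p < n) the whole effect matrix is
  profiled by exact GLS inside the covariance objective, which converges
  directly to the joint maximum likelihood.
* Each candidate block update is accepted only if it does not increase
  the penalized objective, so the recorded objective trace is
  non-increasing by construction.  Defaults: outer_max 50, outer_tol
  1e-6, fista_max 500, fista_tol 1e-7, backtracking factor 0.5.

`model="mtLM"` freezes C_g at 0, giving the regularized multi-trait
linear model comparators (no correction for relatedness).

Maximum likelihood (not REML) is optimized throughout.  With jointly
estimated C_e and pq ≥ nq the penalized likelihood becomes degenerate for
small λ (dense B can interpolate and C_e → 0); λ must therefore stay in
the upper part of its path in the p ≫ n regime.  λ_max — the smallest λ
at which B = 0 at the initial covariances — is computed from the gradient
at zero and anchors the default log-spaced grid (10 points down to
0.01·λ_max).

### Hyperparameter selection

For genomic selection the package follows a holdout protocol: on each
training set, candidate (λ, γ) pairs are scored by mean per-trait Pearson
accuracy on a single 20% inner holdout, the best pair is refitted on the
full training set, and ties prefer stronger regularization.  For the
detection benchmark (below) a fixed data-driven rule is used instead,
because holdout prediction accuracy selects weaker penalties than
support recovery warrants (prediction-optimal and selection-optimal
regularization are famously different targets):

    λ = max(0.35·λ_max, λ_noise),     γ = 0.1·λ_max (clustering variants),

where λ_noise is a permutation-calibrated noise floor: residuals from
the intercept-only model are standardized in the doubly-rotated
coordinates (where they are exchangeable under the null), permuted
within each transformed trait, and the gradient ∞-norm is recomputed;
the mean over two permutations estimates the largest gradient entry
produced by noise alone.  The floor matters in the p ≫ n regime: on data
with no signal, λ_max itself is a noise maximum, and any λ materially
below it lets spurious selections shrink the fitted C_e, which weakens
the effective penalty further and cascades into dense interpolation.
With the floor, null data yield an (almost) empty model.

The floor has a measurable cost when the signal is weak: if most QTN
gradients sit below the noise maximum — as happens at the synthetic
generator's default signal scale — the floored λ screens them out along
with the noise, and the calibrated single-marker scans, which exploit
multiplicity-adaptive BH thresholds instead of a single global penalty,
can attain higher F1.  In high-signal regimes (strong QTNs relative to
residual noise) the F1-optimal λ lies above the floor and the rule is
inactive.

## Association scans and detection

Two single-marker engines mirror standard GWAS practice: the univariate
LMM per trait (stLMM-sm) and the joint multi-trait LMM (mtLMM-sm).  Both
estimate variance components once under the marker-free null model and
reuse them for every marker; each marker is then tested by GLS with a
Wald chi-square (1 df per trait, or q df jointly), followed by
Benjamini–Hochberg FDR control across the scan's markers at 5%.  In the
rotated-and-transformed coordinates each marker's GLS collapses to q
independent weighted simple regressions, so a scan is O(npq).  The
univariate null fit profiles the variance ratio on a 1-D bounded search;
the q=1 joint scan uses the same profile fit, so the two engines agree
exactly there.

Regularized detectors declare a (marker, trait) pair detected when
|B̂_ij| > 1e-8 on the standardized-genotype scale.  The mtLMM-sm verdict
is per marker and is replicated across traits for scoring; per-marker
summaries (stability counts) use the maximum frequency over traits.

## Genomic prediction

A GEBV for a test individual combines the fixed part with the best linear
predictor of its genetic effect given the training residuals:

    Ŷ_test = X_test B̂ + (C_g ⊗ K_ts)(C_g ⊗ K_tt + C_e ⊗ I)⁻¹ vec(R_train),

computed in the eigenbasis of K_tt.  For mtLM fits (C_g = 0) the
prediction is the fixed part alone.  Cross-validation uses repeated
seeded 80/20 train/test splits with all traits masked in the test set
(CV1); accuracy is the per-trait Pearson correlation.  The univariate
RR-BLUP baseline solves û = X′(XX′ + (σ̂_e²/σ̂_u²)I)⁻¹(y − μ̂) per trait
with the variance ratio from a univariate ML fit on the marker-derived
relationship XX′/p.

## Synthetic data generator

The generator exists so the whole pipeline is testable without external
downloads.  It emulates a crop diversity panel:

* **Genotypes**: Balding–Nichols model — ancestral frequencies uniform on
  [0.05, 0.5], subpopulation frequencies Beta-distributed with parameter
  F_ST (default 0.2, 3 subpopulations), genotypes Binomial(2, freq),
  monomorphic columns resampled.  This produces the population structure
  the kinship random effect must correct for.
* **Kinship**: VanRaden's estimator K = WW′/(2Σp_j(1−p_j)), W = X − 2p,
  computed from the raw dosages; negative eigenvalues from numerical
  noise are clamped to zero.
* **Effect architectures** (four scenarios): (1) random — each trait gets
  its own 100 QTNs with iid N(0,1) effects; (2) clustered — traits are
  partitioned into groups (two groups of three plus one of q−6; the empty
  third group is dropped at q=6) sharing one QTN support per group, with
  effects μ_i + ε_ij, μ_i ~ U[−1,1] shared within the group per QTN and
  ε_ij ~ N(0, 0.25) trait-specific; (3) mixed — the sum of a random draw
  (20 QTNs/trait) and a clustered draw (80 QTNs/group); (4) null — B = 0.
  Sharing μ within a group is the default because trait-wise clustering
  is only meaningful when group members have similar, not merely
  co-located, effects; a per-entry μ_ij variant sits behind
  `shared_mu=False`.
* **Phenotypes**: Y = XB + G + E drawn exactly from the model, with
  default covariances C_g (unit variances, within-group correlation 0.5)
  and C_e (diagonal) jointly rescaled so that the total random variance
  matches the total variance of XB — fixed-QTN heritability ≈ 0.5.

What the generator does **not** emulate: linkage disequilibrium along
real chromosomes (markers are independent given subpopulation), minor
allele frequency spectra of GBS data, missingness patterns, or
trait-specific measurement error.  Passing tests therefore demonstrate
correctness of the machinery and the qualitative method ordering under
structured confounding, not absolute detection rates on real panels.

## Detection scoring

True/false positives are counted over (marker, trait) pairs: precision
TP/(TP+FP) (1 when nothing is detected), recall TP/(TP+FN), F1 their
harmonic mean (0 when TP=0 with errors present), and the false-positive
rate FP divided by the number of truly-null pairs.

## Problem sizes used by the test suite and acceptance script

Exactness checks run on n ≤ 12, q ≤ 4, p ≤ 6 against dense Kronecker
oracles.  Calibration uses 50 null replicates at n=120, p=60, q=3.
Variance-component recovery uses n=400, q=2 over 20 seeds (acceptance
tests) and n=300 over 10 seeds (acceptance script).  The detection
benchmark runs at desk scale — n=200, p=500, q=6, 20 QTNs per group, 20
replicates in the test suite and 10 in the acceptance script — which
preserves the qualitative ordering of methods while keeping a full run in
the minutes range on one core.

## Numerical choices and edge cases

* Kinship eigenvalues are clamped at zero; a warning fires if the most
  negative eigenvalue is below −1e-6.  Eigenvectors follow a
  deterministic sign convention (largest-magnitude entry positive).
* C_e carries a 1e-8 ridge; a failed Cholesky adds one extra jitter with
  a warning.
* Missing phenotypes: complete-case (individuals dropped, count logged).
  Missing genotypes: per-marker mean imputation, rounded to a valid
  dosage.  Monomorphic markers are an error where they would produce a
  zero denominator or zero variance.
* K = I makes (C_g, C_e) unidentifiable under the null; the null fit
  warns and forces C_g = 0.
* Constant markers in a scan yield missing statistics, excluded from BH.
* Seeds control only data draws and splits; the optimizer is
  deterministic.

## Known limitations

* No P-values for the regularized estimates — inference after selection
  is deliberately out of scope.
* No SCAD or other non-convex penalties; no REML; no GPU path.
* The clustering prox is iterative, so regularized paths at many (λ, γ)
  pairs are the dominant cost; the ADMM warm start mitigates but does not
  remove this.
* Single-marker scans reuse null-model covariances rather than refitting
  per marker; with very large single-QTN effects this is slightly
  conservative.
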