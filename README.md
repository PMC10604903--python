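# regmtlmm

Regularized multi-trait linear mixed models for GWAS and genomic
selection in structured populations (crop diversity panels and beyond).

## The problem

Diversity panels carry subpopulation structure and uneven familial
relatedness.  Single-trait, single-marker linear mixed models (LMMs)
correct for both through a kinship random effect, but they test one
marker at a time and one trait at a time — discarding the covariance
between traits and the joint contribution of many loci.  Multi-trait
linear models with sparsity penalties handle many markers and traits at
once but ignore relatedness, so their top hits are often artifacts of
population structure.

`regmtlmm` fits the model that does both:

    Y = X B + G + E,   G ~ N_{n×q}(0, C_g, K),   E ~ N_{n×q}(0, C_e, I_n)

— Y the n×q phenotype matrix, X the n×p marker matrix, B the p×q fixed
effect matrix, K the genomic (VanRaden) relationship matrix, and C_g, C_e
the q×q genetic and residual trait covariances — by penalized maximum
likelihood:

    minimize  −LL(B, C_g, C_e) + λ Σ|B_ij| + γ Σ_{(j,j')} c_jj' ‖B_:j − B_:j'‖₂.

The L1 term selects markers; the optional convex-clustering term shrinks
the effect profiles of related traits toward each other.  Estimation uses
FISTA in the kinship eigenbasis (where C_g ⊗ K + C_e ⊗ I block-
diagonalizes) alternating with an L-BFGS covariance step, so p ≫ n
genome-wide fits are routine.  See `docs/methods.md` for the full
account.

The package also ships the surrounding machinery: kinship computation
from 0/1/2 dosages (TSV, PLINK `.raw`, or VCF), single-marker LMM scans
(single- and multi-trait) with Benjamini–Hochberg FDR control, GEBV
prediction with the 80/20 cross-validation protocol, an RR-BLUP baseline,
and a fully seeded simulation benchmark (four QTN architectures on
Balding–Nichols structured genotypes) for detection accuracy.

## Worked example

```python
import numpy as np
from regmtlmm import (ScenarioSpec, FitOptions, PenaltySpec, lambda_max,
                      eigendecompose_kinship, rotate,
                      make_synthetic_dataset, fit_regularized_mtlmm,
                      evaluate_detection, detected_support, scan_multi_trait)
from regmtlmm.estimation import _init_cov

# a small diversity-panel-like dataset: 3 subpopulations, clustered QTNs
spec = ScenarioSpec(scenario=2, q=6, p=500, qtn_per_trait=20, seed=1)
data, truth, cov = make_synthetic_dataset(spec, n=200,
                                          rng=np.random.default_rng(1))

# penalized mixed-model fit (L1 + trait clustering) at half of lambda_max
rot = rotate(eigendecompose_kinship(data.kinship), data.traits, data.genotypes)
lam = 0.5 * lambda_max(rot, _init_cov(data.traits.values))
fit = fit_regularized_mtlmm(data, PenaltySpec(lam=lam, gamma=0.1 * lam),
                            FitOptions(outer_max=10, fista_max=300))
m = evaluate_detection(detected_support(fit.B_hat), truth.support)
print(f"mtLMM-clust: {int(fit.support.sum())} nonzero effects, "
      f"precision {m.precision:.2f}, recall {m.recall:.2f}, F1 {m.f1:.2f}")

# classical joint single-marker scan on the same data
scan = scan_multi_trait(data, fdr=0.05)
print(f"mtLMM-sm: {int(scan.rejected.sum())} of {data.p} markers "
      f"significant at FDR 5%")
```

Output:

```
mtLMM-clust: 213 nonzero effects, precision 0.21, recall 0.37, F1 0.26
mtLMM-sm: 8 of 500 markers significant at FDR 5%
```

At this signal scale (QTN heritability ≈ 0.5 spread over 40 causal
markers per trait group) the joint fit recovers 37% of the planted
(marker, trait) effects at a precision five times the 4.4% base rate of
true pairs, while the calibrated single-marker scan flags a handful of
marker-level hits.  A command line mirrors the library:
`regmtlmm kinship|fit|gwas|cv|simulate --help`.

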