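"""Scenario generators, matrix-variate sampling and detection scoring."""

import numpy as np
import pytest
import scipy.stats

from regmtlmm import (CovariancePair, ScenarioSpec, compute_vanraden_kinship,
                      evaluate_detection, generate_effect_matrix,
                      generate_structured_genotypes, run_scenario_benchmark,
                      sample_matrix_normal, simulate_phenotypes,
                      standardize_genotypes)
from regmtlmm.simulation import default_groups, make_synthetic_dataset

from conftest import random_psd


class TestEffectMatrixScenarios:
    def test_scenario1_column_sparsity(self):
        spec = ScenarioSpec(scenario=1, q=6, p=1000, qtn_per_trait=100, seed=1)
        truth = generate_effect_matrix(spec)
        nnz = (truth.B_true.values != 0).sum(axis=0)
        np.testing.assert_array_equal(nnz, 100)

    def test_scenario2_groups_share_support(self):
        spec = ScenarioSpec(scenario=2, q=20, p=800, qtn_per_trait=100, seed=2)
        truth = generate_effect_matrix(spec)
        groups = spec.groups
        assert [len(g) for g in groups] == [3, 3, 14]
        S = truth.support.values
        for g in groups:
            base = S[:, g[0]]
            for j in g[1:]:
                np.testing.assert_array_equal(S[:, j], base)

    def test_scenario2_six_traits_drops_empty_group(self):
        assert [len(g) for g in default_groups(6)] == [3, 3]

    def test_scenario3_support_bounded_by_qtn_totals(self):
        spec = ScenarioSpec(scenario=3, q=6, p=600, qtn_per_trait=100,
                            mixed_split=(20, 80), seed=3)
        truth = generate_effect_matrix(spec)
        nnz = (truth.B_true.values != 0).sum(axis=0)
        assert (nnz <= 100).all()
        assert (nnz >= 80).all()  # overlap can only reduce the count

    def test_scenario4_no_effects(self):
        spec = ScenarioSpec(scenario=4, q=6, p=100, seed=4)
        truth = generate_effect_matrix(spec)
        assert not truth.B_true.values.any()

    def test_identical_seed_bit_identical_draws(self):
        spec = ScenarioSpec(scenario=2, q=6, p=200, qtn_per_trait=10, seed=11)
        t1 = generate_effect_matrix(spec)
        t2 = generate_effect_matrix(spec)
        np.testing.assert_array_equal(t1.B_true.values, t2.B_true.values)
        t3 = generate_effect_matrix(ScenarioSpec(scenario=2, q=6, p=200,
                                                 qtn_per_trait=10, seed=12))
        assert not np.array_equal(t1.B_true.values, t3.B_true.values)

    def test_too_many_qtns_rejected(self):
        with pytest.raises(ValueError, match="QTN"):
            ScenarioSpec(scenario=1, q=3, p=50, qtn_per_trait=100)


class TestMatrixNormal:
    def test_zero_column_covariance_gives_zero(self, rng):
        G = sample_matrix_normal(np.eye(5), np.zeros((2, 2)), rng)
        assert not G.any()

    def test_identity_covariances_are_iid_standard_normal(self):
        rng = np.random.default_rng(8)
        draws = np.concatenate([
            sample_matrix_normal(np.eye(10), np.eye(1), rng).ravel()
            for _ in range(1000)])
        stat, pval = scipy.stats.kstest(draws, "norm")
        assert pval > 0.01

    def test_vec_covariance_matches_kronecker(self):
        rng = np.random.default_rng(9)
        row = random_psd(3, rng, 0.2)
        col = random_psd(2, rng, 0.2)
        acc = np.zeros((6, 6))
        draws = 20000
        for _ in range(draws):
            v = sample_matrix_normal(row, col, rng).ravel(order="F")
            acc += np.outer(v, v)
        acc /= draws
        target = np.kron(col, row)
        assert np.abs(acc - target).max() < 0.05 * np.abs(target).max() * 3

    def test_non_psd_rejected(self, rng):
        with pytest.raises(ValueError, match="PSD"):
            sample_matrix_normal(np.array([[1.0, 2.0], [2.0, 1.0]]),
                                 np.eye(2), rng)


class TestSimulatePhenotypes:
    def test_noiseless_is_exact_linear_model(self, rng):
        geno = generate_structured_genotypes(20, 15, rng=rng)
        kin = compute_vanraden_kinship(geno)
        spec = ScenarioSpec(scenario=1, q=2, p=15, qtn_per_trait=3, seed=5)
        truth = generate_effect_matrix(spec, marker_ids=geno.marker_ids)
        cov = CovariancePair(np.zeros((2, 2)), 1e-8 * np.eye(2))
        Y = simulate_phenotypes(geno, kin, truth, cov, rng)
        np.testing.assert_allclose(Y.values,
                                   geno.values @ truth.B_true.values,
                                   atol=1e-3)

    def test_null_effect_row_covariance_is_cg_plus_ce(self):
        rng = np.random.default_rng(10)
        n, q = 5, 2
        geno = generate_structured_genotypes(n, 8, rng=rng)
        from regmtlmm.containers import KinshipMatrix
        kin = KinshipMatrix(np.eye(n), geno.individual_ids)
        spec = ScenarioSpec(scenario=4, q=q, p=8, seed=0)
        truth = generate_effect_matrix(spec, marker_ids=geno.marker_ids)
        Cg = random_psd(q, rng, 0.1)
        Ce = random_psd(q, rng, 0.3)
        cov = CovariancePair(Cg, Ce)
        acc = np.zeros((q, q))
        reps = 4000
        for _ in range(reps):
            Y = simulate_phenotypes(geno, kin, truth, cov, rng).values
            acc += Y.T @ Y / n
        acc /= reps
        np.testing.assert_allclose(acc, Cg + Ce, atol=0.15 * (Cg + Ce).max())

    def test_seeded_reproducibility(self):
        r1, r2 = np.random.default_rng(3), np.random.default_rng(3)
        geno = generate_structured_genotypes(12, 6, rng=np.random.default_rng(1))
        kin = compute_vanraden_kinship(geno)
        spec = ScenarioSpec(scenario=1, q=2, p=6, qtn_per_trait=2, seed=0)
        truth = generate_effect_matrix(spec, marker_ids=geno.marker_ids)
        cov = CovariancePair(np.eye(2), np.eye(2))
        Y1 = simulate_phenotypes(geno, kin, truth, cov, r1)
        Y2 = simulate_phenotypes(geno, kin, truth, cov, r2)
        np.testing.assert_array_equal(Y1.values, Y2.values)


class TestStructuredGenotypes:
    def test_no_structure_when_fst_zero(self):
        rng = np.random.default_rng(12)
        geno = generate_structured_genotypes(90, 300, n_subpops=3, fst=0.0,
                                             rng=rng)
        kin = compute_vanraden_kinship(geno).values
        blocks = [slice(0, 30), slice(30, 60), slice(60, 90)]
        within = np.mean([kin[b, b].mean() for b in blocks])
        total = kin.mean()
        assert abs(within - total) < 0.05

    def test_fst_recovered_by_hudson_estimator(self):
        rng = np.random.default_rng(13)
        n, p, fst = 200, 2000, 0.3
        geno = generate_structured_genotypes(n, p, n_subpops=2, fst=fst,
                                             rng=rng)
        X = geno.values
        half = n // 2
        p1 = X[:half].mean(axis=0) / 2
        p2 = X[half:].mean(axis=0) / 2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (half - 1) \
            - p2 * (1 - p2) / (half - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst_hat = np.nanmean(num) / np.nanmean(den)
        assert abs(fst_hat - fst) < 0.05

    def test_kinship_shows_subpopulation_blocks(self):
        rng = np.random.default_rng(14)
        geno = generate_structured_genotypes(100, 500, n_subpops=2, fst=0.2,
                                             rng=rng)
        K = compute_vanraden_kinship(geno).values
        within = (K[:50, :50].mean() + K[50:, 50:].mean()) / 2
        between = K[:50, 50:].mean()
        assert within > between

    def test_no_monomorphic_markers(self):
        rng = np.random.default_rng(15)
        geno = generate_structured_genotypes(30, 200, rng=rng)
        assert (geno.values.std(axis=0) > 0).all()

    def test_degenerate_maf_range_rejected(self, rng):
        with pytest.raises(ValueError, match="maf_range"):
            generate_structured_genotypes(10, 5, maf_range=(0.0, 0.7), rng=rng)


class TestEvaluateDetection:
    def test_formula_hand_example(self):
        est = np.zeros((100, 10), bool)
        tru = np.zeros((100, 10), bool)
        tru.ravel()[:100] = True            # 100 true pairs
        est.ravel()[:80] = True             # 80 TP
        est.ravel()[100:120] = True         # 20 FP
        m = evaluate_detection(est, tru)
        assert m.precision == pytest.approx(0.8)
        assert m.recall == pytest.approx(0.8)
        assert m.f1 == pytest.approx(0.8)

    def test_perfect_detection(self, rng):
        tru = rng.uniform(size=(30, 4)) < 0.2
        tru[0, 0] = True
        m = evaluate_detection(tru, tru)
        assert m.f1 == 1.0 and m.fpr == 0.0

    def test_null_truth_fpr_counting(self):
        est = np.zeros((500, 2), bool)
        est.ravel()[:3] = True
        m = evaluate_detection(est, np.zeros((500, 2), bool))
        assert m.fpr == pytest.approx(3 / 1000)
        assert m.f1 == 0.0

    def test_matches_bruteforce_confusion_matrix(self, rng):
        for _ in range(50):
            est = rng.uniform(size=(12, 3)) < 0.3
            tru = rng.uniform(size=(12, 3)) < 0.3
            m = evaluate_detection(est, tru)
            tp = sum(bool(e and t) for e, t in zip(est.ravel(), tru.ravel()))
            fp = sum(bool(e and not t) for e, t in zip(est.ravel(), tru.ravel()))
            fn = sum(bool(t and not e) for e, t in zip(est.ravel(), tru.ravel()))
            assert (m.tp, m.fp, m.fn) == (tp, fp, fn)
            if tp + fp:
                assert m.precision == pytest.approx(tp / (tp + fp))
            if tp:
                assert m.f1 == pytest.approx(
                    2 * m.precision * m.recall / (m.precision + m.recall))


class TestBenchmarkPlumbing:
    def test_replicate_table_shape_and_seeding(self, rng):
        geno = generate_structured_genotypes(40, 30, rng=np.random.default_rng(2))
        kin = compute_vanraden_kinship(geno)
        geno_std = standardize_genotypes(geno)
        spec = ScenarioSpec(scenario=1, q=2, p=30, qtn_per_trait=3, seed=0)
        df1 = run_scenario_benchmark(geno_std, kin, None, [spec],
                                     ["stLMM-sm"], n_replicates=2, seed=5)
        df2 = run_scenario_benchmark(geno_std, kin, None, [spec],
                                     ["stLMM-sm"], n_replicates=2, seed=5)
        assert len(df1) == 2
        assert (df1["f1"] == df2["f1"]).all()

    def test_unknown_method_rejected(self, rng):
        geno = generate_structured_genotypes(20, 10, rng=rng)
        kin = compute_vanraden_kinship(geno)
        spec = ScenarioSpec(scenario=4, q=2, p=10, seed=0)
        with pytest.raises(ValueError, match="unknown"):
            run_scenario_benchmark(geno, kin, None, [spec], ["nope"],
                                   n_replicates=1)

    def test_make_synthetic_dataset_is_aligned_and_reproducible(self):
        spec = ScenarioSpec(scenario=2, q=6, p=25, qtn_per_trait=3, seed=21)
        d1, t1, c1 = make_synthetic_dataset(spec, n=30,
                                            rng=np.random.default_rng(21))
        d2, t2, c2 = make_synthetic_dataset(spec, n=30,
                                            rng=np.random.default_rng(21))
        np.testing.assert_array_equal(d1.traits.values, d2.traits.values)
        assert d1.n == 30 and d1.p == 25 and d1.q == 6
        np.testing.assert_array_equal(t1.support.values, t2.support.values)
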