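import itertools

import numpy as np
import pytest
from scipy import stats

from fcbench.data_model import FoldPartition
from fcbench.individual_tests import (
    FoldDelta,
    compute_fold_deltas,
    corrected_resampled_t,
    differential_identifiability,
    fold_bootstrap_comparison,
    fold_constrained_permutation_test,
    intra_inter,
    naive_identifiability_test,
    percent_improvement,
)
from fcbench.similarity import SimilarityMatrix


def sim_from(values, measure="pearson"):
    values = np.asarray(values, dtype=float)
    direction = "higher_is_more_similar" if measure == "pearson" else "lower_is_more_similar"
    return SimilarityMatrix(
        values=values,
        measure=measure,
        direction=direction,
        subject_ids=[f"s{i}" for i in range(values.shape[0])],
    )


class TestIntraInter:
    def test_identity_matrix(self):
        r_intra, r_inter = intra_inter(sim_from(np.eye(3)))
        np.testing.assert_array_equal(r_intra, [1, 1, 1])
        np.testing.assert_array_equal(r_inter, [0, 0, 0])

    def test_constant_matrix(self):
        c = 0.37
        r_intra, r_inter = intra_inter(sim_from(np.full((4, 4), c)))
        np.testing.assert_allclose(r_intra, c)
        np.testing.assert_allclose(r_inter, c)

    def test_within_fold_matches_double_loop(self, rng):
        values = np.clip(rng.uniform(-1, 1, (10, 10)), -1, 1)
        folds = FoldPartition(n_folds=2, assignment=np.array([1] * 5 + [2] * 5))
        r_intra, r_inter = intra_inter(sim_from(values), folds, scope="within_fold")
        for i in range(10):
            mates = [j for j in range(10) if folds.assignment[j] == folds.assignment[i] and j != i]
            assert r_intra[i] == values[i, i]
            assert r_inter[i] == pytest.approx(np.mean([values[i, j] for j in mates]))

    def test_global_averages_n_minus_1_values(self, rng):
        values = rng.uniform(-1, 1, (6, 6))
        _, r_inter = intra_inter(sim_from(values))
        i = 2
        assert r_inter[i] == pytest.approx(
            np.mean([values[i, j] for j in range(6) if j != i])
        )


class TestNaiveTest:
    def test_zero_differences_give_p_half(self):
        res = naive_identifiability_test(np.full(5, 0.4), np.full(5, 0.4))
        assert res.t_statistic == 0.0
        assert res.p_value == 0.5
        assert res.df == 4

    def test_df_is_n_minus_1(self):
        res = naive_identifiability_test(np.linspace(0, 1, 1000), np.zeros(1000))
        assert res.df == 999

    def test_hand_computed_t_and_p(self):
        d = np.array([0.1, 0.2, 0.3, 0.2])
        res = naive_identifiability_test(d, np.zeros(4))
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        assert res.t_statistic == pytest.approx(t_expected, abs=1e-12)
        assert res.p_value == pytest.approx(float(stats.t.sf(t_expected, 3)), abs=1e-12)
        assert res.cohen_d == pytest.approx(d.mean() / d.std(ddof=1), abs=1e-12)

    def test_distance_direction_flips_sign(self):
        r_intra, r_inter = np.array([1.0, 1.1, 0.9]), np.array([2.0, 2.1, 1.9])
        res = naive_identifiability_test(r_intra, r_inter, direction="lower_is_more_similar")
        # intra distances below inter distances: evidence FOR identifiability
        assert res.t_statistic > 0
        assert res.p_value < 0.05

    def test_degenerate_zero_variance_flagged(self):
        res = naive_identifiability_test(np.full(4, 0.6), np.full(4, 0.4))
        assert res.degenerate
        assert res.p_value == 0.0


class TestFoldConstrainedPermutation:
    def test_constant_fold_blocks_give_p_one(self):
        # similarity constant within every fold block: permutation invariant
        values = np.block(
            [[np.full((3, 3), 0.8), np.full((3, 3), 0.2)],
             [np.full((3, 3), 0.1), np.full((3, 3), 0.9)]]
        )
        folds = FoldPartition(n_folds=2, assignment=np.array([1] * 3 + [2] * 3))
        p, _ = fold_constrained_permutation_test(sim_from(values), folds, n_perm=200, seed=0)
        assert p == 1.0

    def test_same_seed_identical_p(self, rng):
        values = rng.uniform(0, 1, (8, 8))
        folds = FoldPartition(n_folds=2, assignment=np.array([1] * 4 + [2] * 4))
        sim = sim_from(values)
        p1, ci1 = fold_constrained_permutation_test(sim, folds, n_perm=300, seed=42)
        p2, ci2 = fold_constrained_permutation_test(sim, folds, n_perm=300, seed=42)
        assert p1 == p2 and ci1 == ci2

    def test_matches_exhaustive_enumeration(self, rng):
        # two folds of 3: only (3!)^2 = 36 distinct within-fold column permutations
        values = rng.uniform(0, 1, (6, 6))
        folds = FoldPartition(n_folds=2, assignment=np.array([1, 1, 1, 2, 2, 2]))
        sim = sim_from(values)

        def t_of(vals):
            diag = np.diagonal(vals)
            r_inter = (vals.sum(axis=1) - diag) / 5
            d = diag - r_inter
            return d.mean() / (d.std(ddof=1) / np.sqrt(6))

        t_obs = t_of(values)
        count = total = 0
        for pa in itertools.permutations([0, 1, 2]):
            for pb in itertools.permutations([3, 4, 5]):
                perm = np.array(pa + pb)
                count += t_of(values[:, perm]) >= t_obs
                total += 1
        exact_p = count / total
        mc_p, _ = fold_constrained_permutation_test(sim, folds, n_perm=10_000, seed=5)
        assert mc_p == pytest.approx(exact_p, abs=0.02)

    def test_ci_covers_p(self, rng):
        values = rng.uniform(0, 1, (8, 8))
        folds = FoldPartition(n_folds=2, assignment=np.array([1] * 4 + [2] * 4))
        p, (lo, hi) = fold_constrained_permutation_test(sim_from(values), folds, n_perm=500, seed=1)
        assert lo <= p <= hi
        assert 0.0 <= lo and hi <= 1.0


def _deltas(arrays):
    return [FoldDelta(fold=k + 1, delta=np.asarray(a, float)) for k, a in enumerate(arrays)]


class TestCorrectedResampledT:
    def test_identical_models_give_zero(self):
        d = _deltas([[0.1, 0.2], [0.3, 0.1]])
        t, p, df = corrected_resampled_t(d, d, n_test=2, n_train=2)
        assert t == 0.0 and p == 0.5 and df == 1

    def test_df_is_k_minus_1(self, rng):
        dm = _deltas([rng.normal(0.1, 0.05, 10) for _ in range(10)])
        db = _deltas([rng.normal(0.0, 0.05, 10) for _ in range(10)])
        _, _, df = corrected_resampled_t(dm, db, n_test=10, n_train=90)
        assert df == 9

    def test_hand_formula_k3(self):
        # s = (0.1, 0.2, 0.3) with f=mean, n_test/n_train = 10/90
        dm = _deltas([[0.1], [0.2], [0.3]])
        db = _deltas([[0.0], [0.0], [0.0]])
        # single-element folds: median == mean == the element itself
        t, p, df = corrected_resampled_t(dm, db, n_test=10, n_train=90, f="mean")
        expected = 0.2 / np.sqrt((1 / 3 + 10 / 90) * 0.01)
        assert t == pytest.approx(expected, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(float(stats.t.sf(expected, 2)), abs=1e-12)

    def test_antisymmetric_in_model_and_benchmark(self, rng):
        dm = _deltas([rng.normal(0.1, 0.1, 8) for _ in range(5)])
        db = _deltas([rng.normal(0.0, 0.1, 8) for _ in range(5)])
        t_fwd, _, _ = corrected_resampled_t(dm, db, n_test=8, n_train=32)
        t_rev, _, _ = corrected_resampled_t(db, dm, n_test=8, n_train=32)
        assert t_fwd == pytest.approx(-t_rev, abs=1e-12)

    def test_median_is_default_f(self):
        dm = _deltas([[0.0, 0.0, 10.0], [0.1, 0.1, 0.1]])  # skewed fold
        db = _deltas([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        t_med, _, _ = corrected_resampled_t(dm, db, n_test=3, n_train=3)
        t_mean, _, _ = corrected_resampled_t(dm, db, n_test=3, n_train=3, f="mean")
        assert t_med != pytest.approx(t_mean)


class TestFoldBootstrap:
    def test_constant_positive_differences(self):
        dm = _deltas([[0.5] * 5, [0.5] * 5])
        db = _deltas([[0.0] * 5, [0.0] * 5])
        bounds, n_sig = fold_bootstrap_comparison(dm, db, n_boot=1000, seed=0)
        assert n_sig == 2
        for lower, sig in bounds:
            assert lower == pytest.approx(0.5) and sig

    def test_same_seed_identical(self, rng):
        dm = _deltas([rng.normal(0.1, 0.2, 12) for _ in range(3)])
        db = _deltas([rng.normal(0.0, 0.2, 12) for _ in range(3)])
        r1 = fold_bootstrap_comparison(dm, db, n_boot=1000, seed=9)
        r2 = fold_bootstrap_comparison(dm, db, n_boot=1000, seed=9)
        assert r1 == r2

    def test_symmetric_null_rarely_significant(self, rng):
        # differences symmetric around 0: one-sided 95% bound should exceed 0
        # in roughly 5% of draws
        flags = []
        for s in range(200):
            diff = rng.normal(0.0, 1.0, 20)
            dm = _deltas([diff])
            db = _deltas([np.zeros(20)])
            _, n_sig = fold_bootstrap_comparison(dm, db, n_boot=1000, seed=s)
            flags.append(n_sig)
        rate = np.mean(flags)
        assert rate < 0.12  # ~0.05 nominal, generous Monte-Carlo margin


class TestPercentImprovement:
    def test_equal_means_zero(self):
        assert percent_improvement(0.5, 0.5) == 0.0

    def test_arithmetic(self):
        assert percent_improvement(0.5, 0.25) == pytest.approx(50.0)
        # printed-precision means of a large-cohort comparison
        assert percent_improvement(0.547, 0.477) == pytest.approx(12.797, abs=1e-3)

    def test_zero_model_rejected(self):
        with pytest.raises(ValueError):
            percent_improvement(0.0, 0.3)


class TestFoldDeltas:
    def test_uses_fold_submatrix_only(self, rng):
        values = rng.uniform(0, 1, (6, 6))
        folds = FoldPartition(n_folds=2, assignment=np.array([1, 1, 1, 2, 2, 2]))
        deltas = compute_fold_deltas(sim_from(values), folds)
        block = values[:3, :3]
        expected = np.diagonal(block) - (block.sum(axis=1) - np.diagonal(block)) / 2
        np.testing.assert_allclose(deltas[0].delta, expected, atol=1e-12)
        # changing a cross-fold entry must not alter fold-1 deltas
        values2 = values.copy()
        values2[0, 4] = 0.999
        deltas2 = compute_fold_deltas(sim_from(values2), folds)
        np.testing.assert_array_equal(deltas[0].delta, deltas2[0].delta)

    def test_distance_direction_sign_oriented(self, rng):
        values = np.abs(rng.uniform(1, 2, (4, 4)))
        folds = FoldPartition(n_folds=1, assignment=np.array([1, 1, 1, 1]))
        d_pearson = compute_fold_deltas(sim_from(values), folds)[0].delta
        d_lerm = compute_fold_deltas(sim_from(values, measure="lerm"), folds)[0].delta
        np.testing.assert_allclose(d_pearson, -d_lerm, atol=1e-12)


def test_differential_identifiability_convenience():
    values = np.array([[1.0, 0.2, 0.2], [0.2, 1.0, 0.2], [0.2, 0.2, 1.0]])
    assert differential_identifiability(sim_from(values)) == pytest.approx(0.8)
    # distance measure: smaller diagonal means more identifiable
    dist = np.full((3, 3), 2.0) - values
    assert differential_identifiability(sim_from(dist, measure="lerm")) == pytest.approx(0.8)
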