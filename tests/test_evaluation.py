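"""RMSE, paired nonparametric tests (vs enumeration oracles), CV protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import wilcoxon as scipy_wilcoxon

from tml import (
    ConfigurationError,
    DimensionError,
    EvaluationConfig,
    LearnerSpec,
    TaskCollection,
    cross_validate_task,
    rmse,
    run_benchmark,
    sign_test,
    train_baseline_registry,
    wilcoxon_signed_rank,
)
from tml.evaluation import fold_digest, _task_folds

from conftest import make_task
from oracles import exact_sign_test_p, exact_wilcoxon_p


class TestRmse:
    def test_identity_is_zero(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_offset(self):
        obs = np.arange(5.0)
        assert rmse(obs + 1.0, obs) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert rmse([1.0, 2.0], [3.0, 2.0]) == pytest.approx(np.sqrt(2.0))

    def test_empty_rejected(self):
        with pytest.raises(DimensionError):
            rmse([], [])


class TestSignTest:
    def test_all_positive_ten(self):
        result = sign_test(np.ones(10))
        assert result.p_value == pytest.approx(2 * 0.5**10)
        assert (result.n_pos, result.n_neg, result.n_ties) == (10, 0, 0)

    def test_nine_one(self):
        result = sign_test(np.array([1.0] * 9 + [-1.0]))
        assert result.p_value == pytest.approx(0.021484375)

    def test_symmetric_capped_at_one(self):
        result = sign_test(np.array([1.0] * 5 + [-1.0] * 5))
        assert result.p_value == 1.0

    def test_all_zero(self):
        result = sign_test(np.zeros(4))
        assert result.p_value == 1.0
        assert result.n_pos == result.n_neg == 0
        assert result.n_ties == 4

    def test_zeros_discarded(self):
        with_zeros = sign_test(np.array([1.0, 1.0, 0.0, -1.0, 0.0]))
        without = sign_test(np.array([1.0, 1.0, -1.0]))
        assert with_zeros.p_value == without.p_value
        assert with_zeros.n_ties == 2

    @given(st.integers(1, 20), st.integers(0, 2**20))
    @settings(max_examples=100)
    def test_matches_binomial_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        diffs = rng.choice([-1.0, 1.0], size=n)
        result = sign_test(diffs)
        assert result.p_value == pytest.approx(
            exact_sign_test_p(result.n_pos, result.n_neg), abs=1e-12
        )


class TestWilcoxon:
    def test_n5_all_positive(self):
        result = wilcoxon_signed_rank(np.arange(1.0, 6.0))
        assert result.statistic == 15.0
        assert result.p_value == pytest.approx(2 / 32)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(0)
        diffs = rng.standard_normal(12)
        assert wilcoxon_signed_rank(diffs).p_value == pytest.approx(
            wilcoxon_signed_rank(-diffs).p_value
        )

    def test_all_zero_degenerate(self):
        assert wilcoxon_signed_rank(np.zeros(5)).p_value == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_full_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        # half-integer values force ties in |d|
        diffs = rng.choice([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0], size=n)
        assert wilcoxon_signed_rank(diffs).p_value == pytest.approx(
            exact_wilcoxon_p(diffs), abs=1e-12
        )

    def test_large_n_matches_reference_approximation(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            diffs = rng.standard_normal(30) + 0.3
            ours = wilcoxon_signed_rank(diffs).p_value
            ref = scipy_wilcoxon(diffs, correction=True, method="approx").pvalue
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_exact_and_approx_agree_near_boundary(self):
        # sanity: the two regimes should roughly agree for moderate n
        rng = np.random.default_rng(7)
        diffs = rng.standard_normal(25) + 0.2
        exact = wilcoxon_signed_rank(diffs).p_value
        ref = scipy_wilcoxon(diffs, correction=True, method="approx").pvalue
        assert exact == pytest.approx(ref, abs=0.01)


class TestCrossValidateTask:
    def _setup(self, n_tasks=3, n=30, seed=0):
        tasks = [make_task(f"t{i}", n=n, seed=seed + i) for i in range(n_tasks)]
        coll = TaskCollection(tasks)
        spec = LearnerSpec("knn", {"k": 3}, seed=1)
        registry = train_baseline_registry(coll, spec)
        return coll, spec, registry

    def test_same_seed_identical_predictions(self):
        coll, spec, registry = self._setup()
        config = EvaluationConfig(n_folds=3, seed=5, variants=("baseline", "transformed"))
        a = cross_validate_task(coll["t0"], registry, spec, config)
        b = cross_validate_task(coll["t0"], registry, spec, config)
        for variant in a.oof_predictions:
            np.testing.assert_array_equal(
                a.oof_predictions[variant], b.oof_predictions[variant]
            )
        assert a.fold_digest == b.fold_digest

    def test_duplicate_rows_with_1nn_score_zero(self):
        # exact duplicates with equal y split across folds -> 1-NN recalls them
        rng = np.random.default_rng(0)
        X_half = rng.standard_normal((10, 3))
        X = np.vstack([X_half, X_half])
        y = np.concatenate([np.arange(10.0), np.arange(10.0)])
        frame = pd.DataFrame(X, columns=["a", "b", "c"], index=[f"e{i}" for i in range(20)])
        from tml import Task

        task = Task("dup", frame, pd.Series(y, index=frame.index))
        other = make_task("other", n=20, p=3, seed=1)
        other.X.columns = ["a", "b", "c"]
        coll = TaskCollection([task, other])
        spec = LearnerSpec("knn", {"k": 1}, seed=1)
        registry = train_baseline_registry(coll, spec)
        config = EvaluationConfig(n_folds=2, seed=3, variants=("baseline",))
        result = cross_validate_task(coll["dup"], registry, spec, config)
        folds = _task_folds(coll["dup"], config)
        checked = 0
        for train_idx, test_idx in folds:
            train_set = set(train_idx)
            for i in test_idx:
                twin = (i + 10) % 20
                if twin in train_set:  # duplicate available to memorize
                    assert result.oof_predictions["baseline"][i] == pytest.approx(y[i])
                    checked += 1
        assert checked > 0

    def test_stacked_variants_present_and_finite(self):
        coll, spec, registry = self._setup()
        config = EvaluationConfig(
            n_folds=3, seed=2,
            variants=("baseline", "transformed", "stacked_convex", "stacked_ridge"),
        )
        result = cross_validate_task(coll["t1"], registry, spec, config)
        assert set(result.rmse_per_variant) == set(config.variants)
        assert all(v >= 0 for v in result.rmse_per_variant.values())
        assert result.stack_weights["stacked_convex"]

    def test_fold_digests_shared_across_variants(self):
        coll, spec, registry = self._setup()
        folds = _task_folds(coll["t0"], EvaluationConfig(n_folds=3, seed=9))
        assert fold_digest(folds) == fold_digest(
            _task_folds(coll["t0"], EvaluationConfig(n_folds=3, seed=9))
        )


class TestRunBenchmark:
    def test_identical_tasks_equal_rmse(self):
        base = make_task("a", n=24, seed=3)
        twin = type(base)(
            "b",
            base.X.set_axis([f"b_e{i}" for i in range(24)]),
            base.y.set_axis([f"b_e{i}" for i in range(24)]),
        )
        coll = TaskCollection([base, twin])
        spec = LearnerSpec("knn", {"k": 3}, seed=1)
        config = EvaluationConfig(n_folds=3, seed=1, variants=("baseline",))
        result = run_benchmark(coll, spec, config)
        a, b = result.per_task["baseline"]
        assert a == pytest.approx(b)
        assert result.summary["baseline"] == pytest.approx(a)

    def test_summary_invariant_to_task_order(self):
        tasks = [make_task(f"t{i}", n=24, seed=i) for i in range(4)]
        spec = LearnerSpec("knn", {"k": 3}, seed=1)
        config = EvaluationConfig(n_folds=3, seed=1, variants=("baseline", "transformed"))
        fwd = run_benchmark(TaskCollection(tasks), spec, config)
        rev = run_benchmark(TaskCollection(list(reversed(tasks))), spec, config)
        pd.testing.assert_frame_equal(fwd.per_task, rev.per_task)

    def test_improvement_formula(self):
        tasks = [make_task(f"t{i}", n=24, seed=i) for i in range(4)]
        spec = LearnerSpec("knn", {"k": 3}, seed=1)
        config = EvaluationConfig(n_folds=3, seed=1, variants=("baseline", "transformed"))
        result = run_benchmark(TaskCollection(tasks), spec, config)
        expected = 100.0 * (
            1.0 - result.summary["transformed"] / result.summary["baseline"]
        )
        assert result.improvements["transformed"] == pytest.approx(expected)

    def test_tests_report_both_p_values(self):
        tasks = [make_task(f"t{i}", n=24, seed=i) for i in range(6)]
        spec = LearnerSpec("knn", {"k": 3}, seed=1)
        config = EvaluationConfig(n_folds=3, seed=1, variants=("baseline", "transformed"))
        result = run_benchmark(TaskCollection(tasks), spec, config)
        comparison = result.tests[("baseline", "transformed")]
        assert 0 < comparison.sign_p <= 1
        assert 0 < comparison.wilcoxon_p <= 1

    def test_invalid_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            EvaluationConfig(variants=("baseline", "quantum"))
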