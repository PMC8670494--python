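"""Benchmark protocol: per-task cross-validated RMSE and paired tests.

For each task and each representation variant — baseline (intrinsic
features), transformed (extrinsic TML features), combined (both), and the
two stacked variants — a seeded k-fold cross-validation produces one
out-of-fold prediction vector and hence one RMSE per (task, variant).
Variants are compared across tasks with two paired nonparametric tests on
the per-task RMSE differences: an exact sign test (medians) and a Wilcoxon
signed-rank test (means/ranks).

The stacked variants combine the baseline and TML out-of-fold prediction
streams: for each fold, stack weights are fit on the *other* folds'
out-of-fold predictions (never on resubstitution predictions) and applied to
the held-out fold.

The Wilcoxon test is implemented here with an exact, tie-aware null
distribution (dynamic programming over rank sums) for n <= 25 and a
tie-corrected normal approximation with continuity correction above.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest, rankdata
from sklearn.model_selection import KFold

from ._exceptions import ConfigurationError, DimensionError, TMLError
from .learners import LearnerSpec, fit
from .stacking import PredictionPanel, fit_convex, fit_ridge, stack_predict
from .tasks import ModelRegistry, Task, TaskCollection
from .transform import combined_representation, transform

VARIANTS = ("baseline", "transformed", "combined", "stacked_convex", "stacked_ridge")

EXACT_WILCOXON_LIMIT = 25


def rmse(pred, obs) -> float:
    """Root-mean-squared error between two aligned vectors."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.size == 0 or obs.size == 0:
        raise DimensionError("rmse of empty vectors is undefined")
    if pred.shape != obs.shape:
        raise DimensionError(f"length mismatch: {pred.shape} vs {obs.shape}")
    if not (np.isfinite(pred).all() and np.isfinite(obs).all()):
        raise ConfigurationError("rmse inputs must be finite")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


@dataclass
class PairedTestResult:
    p_value: float
    statistic: float
    n_pos: int
    n_neg: int
    n_ties: int

    @property
    def n_used(self) -> int:
        return self.n_pos + self.n_neg


def sign_test(diffs) -> PairedTestResult:
    """Two-sided exact sign test on paired differences.

    Zero differences are discarded (classical convention; counts are
    reported so the choice is auditable).  All-zero input returns p = 1.
    """
    diffs = np.asarray(diffs, dtype=float).ravel()
    if diffs.size == 0:
        raise ConfigurationError("sign test needs at least one difference")
    n_pos = int((diffs > 0).sum())
    n_neg = int((diffs < 0).sum())
    n_ties = int((diffs == 0).sum())
    n = n_pos + n_neg
    if n == 0:
        return PairedTestResult(1.0, 0.0, 0, 0, n_ties)
    p = float(binomtest(n_pos, n, 0.5, alternative="two-sided").pvalue)
    return PairedTestResult(min(p, 1.0), float(n_pos), n_pos, n_neg, n_ties)


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic, ties allowed.

    Under the null each |difference| carries its (possibly tied, averaged)
    rank with an independent fair sign, so W+ is a sum of independent
    scaled Bernoullis.  Doubling the ranks makes them integers (average
    ranks are half-integers at worst), and the null pmf of 2*W+ follows by
    dynamic programming.
    """
    scaled = np.round(ranks * 2).astype(int)
    total = int(scaled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(round(w_plus * 2))
    p_le = float(pmf[: w2 + 1].sum())
    p_ge = float(pmf[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(diffs) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are discarded; tied absolute differences receive average ranks.
    The null distribution is exact (full enumeration via dynamic
    programming) for n <= 25 after zero removal, and a normal approximation
    with tie-corrected variance and continuity correction beyond.
    """
    diffs = np.asarray(diffs, dtype=float).ravel()
    if diffs.size == 0:
        raise ConfigurationError("wilcoxon test needs at least one difference")
    nonzero = diffs[diffs != 0]
    n_ties = int(diffs.size - nonzero.size)
    n = nonzero.size
    if n == 0:
        return PairedTestResult(1.0, 0.0, 0, 0, n_ties)
    ranks = rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    n_pos = int((nonzero > 0).sum())
    n_neg = n - n_pos
    if n <= EXACT_WILCOXON_LIMIT:
        p = _wilcoxon_exact_p(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        # tie correction: subtract sum(t^3 - t)/48 over groups of tied |d|
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(((counts**3 - counts)).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            p = 1.0
        else:
            from scipy.stats import norm

            d = w_plus - mean
            z = (d - 0.5 * np.sign(d)) / np.sqrt(var)
            p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return PairedTestResult(p, w_plus, n_pos, n_neg, n_ties)


@dataclass
class VariantComparison:
    """Sign and Wilcoxon tests of one variant against another, same RMSE pairs."""

    sign: PairedTestResult
    wilcoxon: PairedTestResult

    @property
    def sign_p(self) -> float:
        return self.sign.p_value

    @property
    def wilcoxon_p(self) -> float:
        return self.wilcoxon.p_value


@dataclass
class EvaluationConfig:
    """Protocol settings for the benchmark."""

    n_folds: int = 5
    seed: int = 0
    variants: tuple[str, ...] = VARIANTS
    strict_no_leak: bool = False
    max_failure_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ConfigurationError(f"unknown variants: {sorted(unknown)}")
        if not self.variants:
            raise ConfigurationError("variants must be nonempty")


def _stable_seed(*parts) -> int:
    payload = "|".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "big") % (2**31)


def _task_folds(task: Task, config: EvaluationConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    # seeded by (config.seed, task size) so identical tasks get identical
    # partitions and equal RMSEs
    n_splits = min(config.n_folds, task.n_examples)
    splitter = KFold(
        n_splits=n_splits,
        shuffle=True,
        random_state=_stable_seed(config.seed, task.n_examples),
    )
    return list(splitter.split(np.arange(task.n_examples)))


def fold_digest(folds: list[tuple[np.ndarray, np.ndarray]]) -> str:
    payload = ";".join(",".join(map(str, test)) for _, test in folds).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _strict_registry(
    collection: TaskCollection,
    learner_spec: LearnerSpec,
    exclude_example_ids: set[str],
    skip_task: str,
) -> ModelRegistry:
    """Retrain source models without the held-out example ids (strict mode)."""
    registry = ModelRegistry()
    for task in collection:
        if task.task_id == skip_task:
            continue
        keep = [i for i, eid in enumerate(task.example_ids) if eid not in exclude_example_ids]
        if len(keep) < 2:
            raise ConfigurationError(
                f"strict mode leaves too few rows for source task {task.task_id!r}"
            )
        model = fit(
            learner_spec.with_seed(_stable_seed(learner_spec.seed, task.task_id)),
            task.X.iloc[keep],
            task.y.iloc[keep],
        )
        registry.add(task.task_id, learner_spec.digest, model)
    return registry


def _oof_predictions(
    task: Task,
    design: pd.DataFrame,
    learner_spec: LearnerSpec,
    folds,
    seed_salt: str,
) -> np.ndarray:
    """Out-of-fold predictions of one learner on one fixed design matrix."""
    y = task.y.to_numpy()
    out = np.empty(task.n_examples)
    for fold_idx, (train_idx, test_idx) in enumerate(folds):
        model = fit(
            learner_spec.with_seed(
                _stable_seed(learner_spec.seed, task.task_id, seed_salt, fold_idx)
            ),
            design.iloc[train_idx],
            y[train_idx],
        )
        out[test_idx] = model.predict(design.iloc[test_idx])
    return out


@dataclass
class TaskEvaluation:
    task_id: str
    oof_predictions: dict[str, np.ndarray]
    rmse_per_variant: dict[str, float]
    fold_digest: str
    stack_weights: dict = field(default_factory=dict)


def cross_validate_task(
    task: Task,
    registry: ModelRegistry,
    learner_spec: LearnerSpec,
    config: EvaluationConfig,
    collection: TaskCollection | None = None,
) -> TaskEvaluation:
    """Evaluate every requested variant on one task over a shared fold split.

    All variants share one seeded fold partition, so per-task RMSE pairs are
    honestly paired.  Stacked variants need both ``baseline`` and
    ``transformed`` streams and compute them if not requested explicitly.
    """
    folds = _task_folds(task, config)
    for train_idx, _ in folds:
        if len(train_idx) < 2:
            raise ConfigurationError(
                f"task {task.task_id!r}: a fold has fewer than 2 training rows"
            )
    y = task.y.to_numpy()
    want = set(config.variants)
    need_streams = want & {"baseline", "transformed", "combined"}
    if want & {"stacked_convex", "stacked_ridge"}:
        need_streams |= {"baseline", "transformed"}

    oof: dict[str, np.ndarray] = {}
    if "baseline" in need_streams:
        oof["baseline"] = _oof_predictions(task, task.X, learner_spec, folds, "baseline")

    if need_streams & {"transformed", "combined"}:
        if config.strict_no_leak:
            # per-fold: retrain every source model without the test examples
            tml_oof = np.empty(task.n_examples)
            comb_oof = np.empty(task.n_examples)
            for fold_idx, (train_idx, test_idx) in enumerate(folds):
                test_ids = {task.example_ids[i] for i in test_idx}
                fold_registry = _strict_registry(
                    collection, learner_spec, test_ids, task.task_id
                )
                rep = transform(
                    fold_registry, learner_spec.digest, task.X, exclude_task=task.task_id
                )
                frame = rep.to_frame(index=task.X.index)
                for tag, design, store in (
                    ("transformed", frame, tml_oof),
                    ("combined", combined_representation(task.X, rep), comb_oof),
                ):
                    if tag in need_streams:
                        model = fit(
                            learner_spec.with_seed(
                                _stable_seed(learner_spec.seed, task.task_id, tag, fold_idx)
                            ),
                            design.iloc[train_idx],
                            y[train_idx],
                        )
                        store[test_idx] = model.predict(design.iloc[test_idx])
            if "transformed" in need_streams:
                oof["transformed"] = tml_oof
            if "combined" in need_streams:
                oof["combined"] = comb_oof
        else:
            rep = transform(
                registry, learner_spec.digest, task.X, exclude_task=task.task_id
            )
            if "transformed" in need_streams:
                oof["transformed"] = _oof_predictions(
                    task, rep.to_frame(index=task.X.index), learner_spec, folds, "transformed"
                )
            if "combined" in need_streams:
                oof["combined"] = _oof_predictions(
                    task, combined_representation(task.X, rep), learner_spec, folds, "combined"
                )

    stack_weights: dict = {}
    for variant, fitter in (
        ("stacked_convex", "convex"),
        ("stacked_ridge", "ridge"),
    ):
        if variant not in want:
            continue
        panel_matrix = np.column_stack([oof["baseline"], oof["transformed"]])
        labels = [f"baseline:{learner_spec.family}", f"tml:{learner_spec.family}"]
        pred = np.empty(task.n_examples)
        fold_weights = []
        for fold_idx, (train_idx, test_idx) in enumerate(folds):
            panel = PredictionPanel(panel_matrix[train_idx], labels, y[train_idx])
            if fitter == "convex":
                weights = fit_convex(panel)
            else:
                weights = fit_ridge(
                    panel, seed=_stable_seed(config.seed, task.task_id, variant, fold_idx)
                )
            pred[test_idx] = stack_predict(weights, panel_matrix[test_idx], labels)
            fold_weights.append(weights.to_dict())
        oof[variant] = pred
        stack_weights[variant] = fold_weights

    scores = {v: rmse(oof[v], y) for v in want}
    return TaskEvaluation(
        task_id=task.task_id,
        oof_predictions={v: oof[v] for v in want},
        rmse_per_variant=scores,
        fold_digest=fold_digest(folds),
        stack_weights=stack_weights,
    )


@dataclass
class BenchmarkResult:
    """Per-task and aggregate RMSEs plus paired significance tests."""

    per_task: pd.DataFrame  # index task_id, columns variants
    summary: pd.Series  # variant -> mean RMSE over tasks
    medians: pd.Series
    tests: dict[tuple[str, str], "VariantComparison"]
    improvements: dict[str, float]  # variant -> % improvement over baseline
    n_evaluated: int
    skipped: dict[str, str]
    fold_digests: dict[str, str]
    config_digest: str

    def significant_improvement(self, variant: str, alpha: float = 0.05) -> bool:
        """Did ``variant`` beat baseline on a majority of tasks, significantly?"""
        result = self.tests[("baseline", variant)]
        better = (self.per_task[variant] < self.per_task["baseline"]).sum()
        worse = (self.per_task[variant] > self.per_task["baseline"]).sum()
        return bool(result.sign_p < alpha and better > worse)


def train_baseline_registry(
    collection: TaskCollection, learner_spec: LearnerSpec
) -> ModelRegistry:
    """Fit one baseline model per task on its full data (the source models)."""
    registry = ModelRegistry()
    for task in collection:
        model = fit(
            learner_spec.with_seed(_stable_seed(learner_spec.seed, task.task_id)),
            task.X,
            task.y,
        )
        registry.add(
            task.task_id,
            learner_spec.digest,
            model,
            n_train=task.n_examples,
            seed=learner_spec.seed,
        )
    return registry


def run_benchmark(
    collection: TaskCollection,
    learner_spec: LearnerSpec,
    config: EvaluationConfig,
    registry: ModelRegistry | None = None,
) -> BenchmarkResult:
    """Run the full per-task CV benchmark for one learner family.

    Returns mean and median RMSE per variant, paired sign and Wilcoxon tests
    of every non-baseline variant against baseline, and the percentage
    improvement ``100 * (1 - mean_variant / mean_baseline)``.

    A task whose evaluation fails is skipped with a recorded reason; if more
    than ``config.max_failure_fraction`` of tasks fail, the benchmark aborts.
    """
    if registry is None:
        registry = train_baseline_registry(collection, learner_spec)
    rows: dict[str, dict[str, float]] = {}
    digests: dict[str, str] = {}
    skipped: dict[str, str] = {}
    for task in collection:
        try:
            evaluation = cross_validate_task(
                task, registry, learner_spec, config, collection=collection
            )
        except TMLError as exc:
            skipped[task.task_id] = str(exc)
            continue
        rows[task.task_id] = evaluation.rmse_per_variant
        digests[task.task_id] = evaluation.fold_digest
    if len(skipped) > config.max_failure_fraction * len(collection):
        raise ConfigurationError(
            f"benchmark aborted: {len(skipped)}/{len(collection)} tasks failed: "
            f"{dict(list(skipped.items())[:3])}"
        )
    if not rows:
        raise ConfigurationError("no task evaluated successfully")
    per_task = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    per_task = per_task[[v for v in config.variants]]
    if per_task.isna().any().any():
        raise ConfigurationError("incomplete per-task RMSE table")
    summary = per_task.mean(axis=0)
    medians = per_task.median(axis=0)
    tests = {}
    improvements = {}
    if "baseline" in per_task.columns:
        base = per_task["baseline"]
        for variant in per_task.columns:
            if variant == "baseline":
                continue
            diffs = (base - per_task[variant]).to_numpy()
            tests[("baseline", variant)] = _paired(diffs)
            improvements[variant] = float(
                100.0 * (1.0 - summary[variant] / summary["baseline"])
            )
    config_digest = hashlib.sha256(
        f"{config}|{learner_spec.family}|{learner_spec.params}".encode()
    ).hexdigest()[:16]
    return BenchmarkResult(
        per_task=per_task,
        summary=summary,
        medians=medians,
        tests={k: v for k, v in tests.items()},
        improvements=improvements,
        n_evaluated=len(per_task),
        skipped=skipped,
        fold_digests=digests,
        config_digest=config_digest,
    )


def _paired(diffs: np.ndarray) -> VariantComparison:
    return VariantComparison(sign=sign_test(diffs), wilcoxon=wilcoxon_signed_rank(diffs))
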