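"""Synthetic multi-task benchmark generator with controllable relatedness.

The premise being tested is that extrinsic features help exactly when tasks
are related.  The generator therefore plants relatedness explicitly through
two channels, mirroring how real task families (e.g. activity prediction
against homologous protein targets over overlapping compound libraries) are
related:

* **shared latent structure** — every task's true function acts on the same
  k-dimensional latent projection ``z = x'B`` of the p intrinsic features;
* **correlated coefficients** — task i's latent coefficient vector is
  ``w_i = sqrt(rho) * w_bar + sqrt(1 - rho) * u_i`` with ``w_bar``, ``u_i``
  i.i.d. standard normal, so ``Corr(w_i, w_j) = rho`` for tasks sharing a
  group; optional group structure gives each group its own independent
  ``w_bar`` (between-group relatedness 0).

Targets are ``y_i = f(z' w_i) + noise``; features are sparse binary
fingerprint-like bits (per-bit frequency ~ Beta(0.3, 1)) or Gaussians; a
configurable fraction of each task's examples is drawn from a shared pool so
example sets overlap across tasks, as compound libraries do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError
from .tasks import Task, TaskCollection

#: Default benchmark settings: many related small tasks (the regime the
#: method targets), fingerprint-like features, moderate noise.
DEFAULT_BENCHMARK = dict(
    n_tasks=60,
    n_examples_per_task=100,
    p_features=128,
    latent_dim=10,
    relatedness=0.9,
    noise_sd=0.5,
    feature_kind="binary_fingerprint",
    nonlinearity="squash",
    overlap_fraction=0.3,
    seed=20211129,
)

_REFERENCE_SAMPLE = 4000  # rows used to calibrate signal scale per task


@dataclass
class GeneratorConfig:
    """All knobs of the generator; validated before any sampling."""

    n_tasks: int = 60
    n_examples_per_task: int = 100
    p_features: int = 128
    latent_dim: int = 10
    relatedness: float = 0.9
    group_sizes: list[int] | None = None
    noise_sd: float = 0.5
    noise_kind: str = "relative"  # relative (x sd of signal) | absolute
    feature_kind: str = "binary_fingerprint"
    nonlinearity: str = "squash"
    overlap_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tasks < 1 or self.n_examples_per_task < 2:
            raise ConfigurationError("need n_tasks >= 1 and >= 2 examples per task")
        if self.p_features < 1 or not 1 <= self.latent_dim <= self.p_features:
            raise ConfigurationError("need 1 <= latent_dim <= p_features")
        if not 0.0 <= self.relatedness <= 1.0:
            raise ConfigurationError("relatedness must lie in [0, 1]")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ConfigurationError("overlap_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.noise_kind not in ("relative", "absolute"):
            raise ConfigurationError(f"unknown noise_kind {self.noise_kind!r}")
        if self.feature_kind not in ("binary_fingerprint", "gaussian"):
            raise ConfigurationError(f"unknown feature_kind {self.feature_kind!r}")
        if self.nonlinearity not in ("none", "squash", "interactions"):
            raise ConfigurationError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.group_sizes is not None:
            if sum(self.group_sizes) != self.n_tasks:
                raise ConfigurationError("group_sizes must sum to n_tasks")
            if any(g < 1 for g in self.group_sizes):
                raise ConfigurationError("group sizes must be positive")


@dataclass
class GroundTruth:
    """What the generator actually planted, for oracle checks."""

    loading_matrix: np.ndarray  # B, p x k
    coefficients: np.ndarray  # W, n_tasks x k
    shared_components: np.ndarray  # one w_bar per group, groups x k
    group_of_task: np.ndarray  # task index -> group index
    signal_scale: np.ndarray  # per-task calibration constant for the squash
    signal_sd: np.ndarray  # per-task sd of the noiseless signal
    noise_sd: np.ndarray  # per-task absolute noise sd
    expected_r2: np.ndarray  # per-task Var(signal) / (Var(signal) + sigma^2)
    task_ids: list[str] = field(default_factory=list)


def _streams(config: GeneratorConfig) -> dict[str, np.random.Generator]:
    """Independent, reproducible RNG streams per generator concern.

    The feature-distribution stream is shared between ``generate`` and
    ``make_probe_set`` so probes come from exactly the training feature law.
    """
    root = np.random.SeedSequence(config.seed)
    names = ["feature_law", "truth", "pool", "tasks", "noise", "probe"]
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _feature_frequencies(config: GeneratorConfig) -> np.ndarray | None:
    if config.feature_kind != "binary_fingerprint":
        return None
    rng = _streams(config)["feature_law"]
    return rng.beta(0.3, 1.0, size=config.p_features)


def _draw_features(
    config: GeneratorConfig, rng: np.random.Generator, n: int, freqs: np.ndarray | None
) -> np.ndarray:
    if config.feature_kind == "binary_fingerprint":
        return (rng.random((n, config.p_features)) < freqs).astype(float)
    return rng.standard_normal((n, config.p_features))


def _signal(
    index: np.ndarray, scale: float, nonlinearity: str, z: np.ndarray, w: np.ndarray
) -> np.ndarray:
    if nonlinearity == "none":
        return index
    if nonlinearity == "squash":
        return np.tanh(index / scale)
    # interactions: add a product of the two leading latent coordinates
    return index + 0.5 * z[:, 0] * z[:, 1]


def generate(config: GeneratorConfig) -> tuple[TaskCollection, GroundTruth]:
    """Draw a task collection and the ground truth that produced it.

    Fully reproducible from ``config.seed``; identical configs give
    byte-identical collections.
    """
    streams = _streams(config)
    freqs = _feature_frequencies(config)
    p, k, n = config.p_features, config.latent_dim, config.n_tasks

    truth_rng = streams["truth"]
    B = truth_rng.standard_normal((p, k)) / np.sqrt(p)
    group_sizes = config.group_sizes or [n]
    n_groups = len(group_sizes)
    shared = truth_rng.standard_normal((n_groups, k))
    group_of_task = np.repeat(np.arange(n_groups), group_sizes)
    rho = config.relatedness
    U = truth_rng.standard_normal((n, k))
    W = np.sqrt(rho) * shared[group_of_task] + np.sqrt(1.0 - rho) * U

    # reference sample fixes each task's signal scale and sd so the true
    # function is a deterministic object, not a property of the drawn data
    ref = _draw_features(config, streams["truth"], _REFERENCE_SAMPLE, freqs)
    ref_z = ref @ B

    pool_size = config.n_examples_per_task
    pool_rng = streams["pool"]
    pool_X = _draw_features(config, pool_rng, pool_size, freqs)
    pool_ids = [f"shared_{i:05d}" for i in range(pool_size)]

    task_rng = streams["tasks"]
    noise_rng = streams["noise"]
    task_ids = [f"task_{i:03d}" for i in range(n)]

    scale = np.empty(n)
    signal_sd = np.empty(n)
    sigma = np.empty(n)
    expected_r2 = np.empty(n)
    tasks: list[Task] = []
    feature_names = [f"x_{j:04d}" for j in range(p)]
    n_shared = int(round(config.overlap_fraction * config.n_examples_per_task))

    for i, task_id in enumerate(task_ids):
        ref_index = ref_z @ W[i]
        scale[i] = max(float(ref_index.std()), 1e-12)
        ref_signal = _signal(ref_index, scale[i], config.nonlinearity, ref_z, W[i])
        signal_sd[i] = max(float(ref_signal.std()), 1e-12)
        sigma[i] = (
            config.noise_sd * signal_sd[i]
            if config.noise_kind == "relative"
            else config.noise_sd
        )
        expected_r2[i] = signal_sd[i] ** 2 / (signal_sd[i] ** 2 + sigma[i] ** 2)

        shared_idx = np.sort(
            task_rng.choice(pool_size, size=n_shared, replace=False)
        ) if n_shared else np.empty(0, dtype=int)
        n_own = config.n_examples_per_task - n_shared
        own_X = _draw_features(config, task_rng, n_own, freqs)
        X = np.vstack([pool_X[shared_idx], own_X]) if n_shared else own_X
        ids = [pool_ids[j] for j in shared_idx] + [
            f"{task_id}_ex{j:04d}" for j in range(n_own)
        ]
        z = X @ B
        index = z @ W[i]
        y = _signal(index, scale[i], config.nonlinearity, z, W[i])
        if sigma[i] > 0:
            y = y + noise_rng.normal(0.0, sigma[i], size=len(y))
        tasks.append(
            Task(
                task_id=task_id,
                X=pd.DataFrame(X, index=ids, columns=feature_names),
                y=pd.Series(y, index=ids),
                metadata={"group": int(group_of_task[i])},
            )
        )

    truth = GroundTruth(
        loading_matrix=B,
        coefficients=W,
        shared_components=shared,
        group_of_task=group_of_task,
        signal_scale=scale,
        signal_sd=signal_sd,
        noise_sd=sigma,
        expected_r2=expected_r2,
        task_ids=task_ids,
    )
    return TaskCollection(tasks, collection_id=f"synthetic_seed{config.seed}"), truth


def make_probe_set(config: GeneratorConfig, n_probe: int) -> pd.DataFrame:
    """Fresh examples from the training feature distribution.

    Probe ids are disjoint from every training example id; the feature law
    (per-bit frequencies) is identical to the one ``generate`` used because
    both derive it from the same seed lineage.
    """
    if n_probe < 0:
        raise ConfigurationError("n_probe must be >= 0")
    freqs = _feature_frequencies(config)
    rng = _streams(config)["probe"]
    X = _draw_features(config, rng, n_probe, freqs)
    return pd.DataFrame(
        X,
        index=[f"probe_{i:05d}" for i in range(n_probe)],
        columns=[f"x_{j:04d}" for j in range(config.p_features)],
    )


def default_benchmark_config(**overrides) -> GeneratorConfig:
    """The package's standard related-task benchmark (experiment A)."""
    return GeneratorConfig(**{**DEFAULT_BENCHMARK, **overrides})
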