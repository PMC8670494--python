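"""The transformational-ML representation.

The central operation of the package: re-represent examples not by their
intrinsic attributes (fingerprint bits, descriptors) but *extrinsically*, by
what the models trained on the other tasks predict about them.  Given a
registry holding one fitted baseline model per task, ``transform`` applies
every source model to a feature matrix and stacks the prediction vectors as
columns — one column per source task, sorted by task id.

For an in-collection task the task's own model is excluded from its
representation (a model should not be given its own target as a feature);
for a genuinely new task all n source models contribute.

Also here: the *combined* (augmented) representation — intrinsic and
extrinsic columns concatenated — second-order transforms (the predictions of
first-order TML models used as the representation for a second round), and
data-driven TML feature selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, DependencyError, DimensionError
from .learners import FittedModel, fit
from .tasks import ModelRegistry, TaskCollection


@dataclass
class TransformedRepresentation:
    """Examples x source-task prediction matrix (the extrinsic feature space).

    ``matrix`` has one column per contributing source model, in sorted
    task-id order; ``excluded_task_id`` records a leave-own-model-out
    exclusion; ``order_tag`` distinguishes first- from second-order
    transforms.
    """

    matrix: np.ndarray
    column_task_ids: list[str]
    excluded_task_id: str | None = None
    order_tag: str = "first"
    selection: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.column_task_ids):
            raise DimensionError(
                f"matrix shape {self.matrix.shape} vs "
                f"{len(self.column_task_ids)} column task ids"
            )
        if self.excluded_task_id in self.column_task_ids:
            raise ConfigurationError(
                f"excluded task {self.excluded_task_id!r} appears in columns"
            )
        if list(self.column_task_ids) != sorted(self.column_task_ids):
            raise ConfigurationError("column task ids must be sorted")

    @property
    def n_columns(self) -> int:
        return len(self.column_task_ids)

    @property
    def column_names(self) -> list[str]:
        return [f"tml:{t}" for t in self.column_task_ids]

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.column_names, index=index)

    def drop_column(self, task_id: str) -> "TransformedRepresentation":
        if task_id not in self.column_task_ids:
            raise ConfigurationError(f"no column for task {task_id!r}")
        keep = [i for i, t in enumerate(self.column_task_ids) if t != task_id]
        return TransformedRepresentation(
            self.matrix[:, keep],
            [self.column_task_ids[i] for i in keep],
            excluded_task_id=task_id,
            order_tag=self.order_tag,
        )


def transform(
    registry: ModelRegistry,
    learner_digest: str,
    X: pd.DataFrame,
    exclude_task: str | None = None,
    representation_tag: str = "baseline",
    order_tag: str = "first",
) -> TransformedRepresentation:
    """Build the extrinsic representation of ``X`` from registered models.

    Column j holds the predictions of the model trained on source task
    ``column_task_ids[j]``; columns are sorted by task id so the output is
    invariant to registry insertion order.  ``exclude_task`` removes that
    task's own model (leave-own-model-out); excluding down to zero columns is
    an error.
    """
    models = registry.models_for(learner_digest, representation_tag)
    if len(models) < 2:
        raise DependencyError(
            f"need at least 2 registered {representation_tag!r} models for this "
            f"learner, found {len(models)}"
        )
    task_ids = [t for t in models if t != exclude_task]
    if not task_ids:
        raise ConfigurationError("exclusion left no source models")
    columns = [models[t].predict(X) for t in task_ids]
    return TransformedRepresentation(
        np.column_stack(columns) if len(X) else np.empty((0, len(task_ids))),
        task_ids,
        excluded_task_id=exclude_task,
        order_tag=order_tag,
    )


def combined_representation(
    X_baseline: pd.DataFrame, X_tml: TransformedRepresentation
) -> pd.DataFrame:
    """Concatenate intrinsic and extrinsic columns (baseline first).

    Column names are namespaced ``base:<feature>`` / ``tml:<task_id>`` so the
    two blocks can never collide.
    """
    if X_tml.n_columns == 0:
        raise ConfigurationError("combined representation needs TML columns")
    if len(X_baseline) != X_tml.matrix.shape[0]:
        raise DimensionError(
            f"{len(X_baseline)} baseline rows vs {X_tml.matrix.shape[0]} TML rows"
        )
    base = X_baseline.copy()
    base.columns = [f"base:{c}" for c in X_baseline.columns]
    tml_frame = X_tml.to_frame(index=X_baseline.index)
    return pd.concat([base, tml_frame], axis=1)


def train_tml_models(
    registry: ModelRegistry,
    learner_digest: str,
    collection: TaskCollection,
    phi_spec,
    seed_offset: int = 1_000_000,
) -> None:
    """Fit and register one first-order TML model per task in the collection.

    Each task's TML model is trained on the task's extrinsic representation
    (leave-own-model-out) against its own target, using learner ``phi_spec``.
    Registered under tag ``tml``.
    """
    for i, task in enumerate(collection):
        rep = transform(registry, learner_digest, task.X, exclude_task=task.task_id)
        model = fit(
            phi_spec.with_seed(phi_spec.seed + seed_offset + i),
            rep.to_frame(index=task.X.index),
            task.y,
        )
        registry.add(task.task_id, phi_spec.digest, model, representation_tag="tml")


def second_order_transform(
    registry: ModelRegistry,
    learner_digest: str,
    collection: TaskCollection,
    phi_digest: str | None = None,
) -> dict[str, TransformedRepresentation]:
    """Second-order TML: represent each task by the other tasks' *TML* models.

    Each first-order TML model consumes an extrinsic representation, so to
    apply the TML model of task j to task i's examples we first rebuild, from
    the baseline registry, the first-order representation task j's model
    expects (all baseline models except j's own), then predict.  The
    exclusion rule is identical to first order: task i's own TML model never
    contributes a column to task i's second-order representation.
    """
    phi_digest = phi_digest or learner_digest
    tml_models = registry.models_for(phi_digest, "tml")
    missing = [t.task_id for t in collection if t.task_id not in tml_models]
    if missing:
        raise DependencyError(
            f"missing first-order TML models for tasks: {missing}"
        )
    out: dict[str, TransformedRepresentation] = {}
    for task in collection:
        source_ids = sorted(t for t in tml_models if t != task.task_id)
        if not source_ids:
            raise ConfigurationError("exclusion left no source TML models")
        columns = []
        for j in source_ids:
            first_order = transform(
                registry, learner_digest, task.X, exclude_task=j
            )
            columns.append(
                tml_models[j].predict(first_order.to_frame(index=task.X.index))
            )
        out[task.task_id] = TransformedRepresentation(
            np.column_stack(columns),
            source_ids,
            excluded_task_id=task.task_id,
            order_tag="second",
        )
    return out


def select_tml_features(
    X_tml: TransformedRepresentation,
    y: np.ndarray | pd.Series,
    m_keep: int,
    method: str = "correlation",
    seed: int = 0,
) -> TransformedRepresentation:
    """Keep the ``m_keep`` extrinsic columns most predictive of ``y``.

    ``correlation`` scores columns by absolute Pearson correlation with the
    target; ``importance`` by the importance scores of a random forest fit on
    the full representation.  Ties break by column order.  A constant target
    makes correlation undefined, so the call falls back to importance and
    records a warning in ``selection``.
    """
    y = np.asarray(y, dtype=float).ravel()
    m = X_tml.n_columns
    if not 1 <= m_keep <= m:
        raise ConfigurationError(f"m_keep={m_keep} out of range [1, {m}]")
    if method not in ("correlation", "importance"):
        raise ConfigurationError(f"unknown selection method {method!r}")
    warning = None
    if method == "correlation" and np.all(y == y[0]):
        warning = "constant target: correlation undefined, fell back to importance"
        method = "importance"
    if method == "correlation":
        scores = np.empty(m)
        for j in range(m):
            col = X_tml.matrix[:, j]
            sd = col.std()
            scores[j] = (
                0.0 if sd == 0 else abs(np.corrcoef(col, y)[0, 1])
            )
        scores = np.nan_to_num(scores)
    else:
        from .learners import LearnerSpec

        forest = fit(
            LearnerSpec("forest", {"n_estimators": 100}, seed=seed),
            X_tml.to_frame(),
            y,
        )
        scores = forest.importance_scores.to_numpy()
    # stable sort on negated scores keeps original column order among ties
    order = np.argsort(-scores, kind="stable")
    keep = np.sort(order[:m_keep])
    selected = TransformedRepresentation(
        X_tml.matrix[:, keep],
        [X_tml.column_task_ids[i] for i in keep],
        excluded_task_id=X_tml.excluded_task_id,
        order_tag=X_tml.order_tag,
    )
    selected.selection = {
        "method": method,
        "m_keep": m_keep,
        "scores": {X_tml.column_task_ids[i]: float(scores[i]) for i in range(m)},
    }
    if warning:
        selected.selection["warning"] = warning
    return selected
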