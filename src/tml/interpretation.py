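"""Explainability: attribute-model importance and prediction-profile clustering.

Two complementary views of what a collection of task models has learned:

* **Importance ranking** — for a TML model (whose features are other tasks'
  predictions), rank the source tasks by how much their prediction column
  contributes.  Forest/boosting models expose native importances; for the
  other families permutation importance (mean RMSE increase when a column is
  shuffled) is the uniform fallback.
* **Prediction profiles** — apply every task model to a probe set of
  examples.  An *example profile* is one example's vector of predictions
  across all task models; a *problem profile* is one task model's vector of
  predictions across the probe examples (exactly the transpose).  Profiles
  are clustered hierarchically: examples cluster by predicted functional
  behaviour rather than intrinsic similarity, and tasks cluster by how they
  respond to the same probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from ._exceptions import ConfigurationError, DependencyError, DimensionError
from .learners import FittedModel
from .tasks import ModelRegistry

DISTANCES = ("euclidean", "correlation")
LINKAGES = ("average", "complete", "ward")


@dataclass
class ImportanceRanking:
    """Ranked source tasks for one TML model (descending weight)."""

    rows: pd.DataFrame  # columns: rank, source_task_id, weight (+ metadata)
    method: str  # native | permutation
    normalization: str  # raw | percent

    def top(self, k: int) -> pd.DataFrame:
        return self.rows.head(k)


def _permutation_importance(
    model: FittedModel, X: pd.DataFrame, y: np.ndarray, n_repeats: int, seed: int
) -> pd.Series:
    """Mean RMSE increase when one column is shuffled, per column, seeded."""
    rng = np.random.default_rng(seed % (2**31))
    values = X[model.feature_schema].to_numpy(dtype=float)
    base_rmse = float(np.sqrt(np.mean((model.predict(X[model.feature_schema]) - y) ** 2)))
    out = {}
    for j, column in enumerate(model.feature_schema):
        increases = []
        for _ in range(n_repeats):
            shuffled = values.copy()
            shuffled[:, j] = rng.permutation(shuffled[:, j])
            pred = model.predict(
                pd.DataFrame(shuffled, columns=model.feature_schema)
            )
            increases.append(float(np.sqrt(np.mean((pred - y) ** 2))) - base_rmse)
        out[column] = float(np.mean(increases))
    return pd.Series(out)


def attribute_importance(
    tml_model: FittedModel,
    X_tml: pd.DataFrame,
    y,
    method: str = "native",
    top_k: int | None = None,
    normalization: str = "percent",
    n_repeats: int = 10,
    seed: int = 0,
    metadata: dict[str, dict] | None = None,
) -> ImportanceRanking:
    """Rank the source-task prediction columns by importance to a TML model.

    ``native`` uses the learner's own importances where available and falls
    back to permutation (with a record in ``method``) where not.
    ``permutation`` computes the mean increase in RMSE over ``n_repeats``
    seeded shuffles of each column.  Ties order by task id; ``percent``
    rescales weights to sum to 100.
    """
    if method not in ("native", "permutation"):
        raise ConfigurationError(f"unknown importance method {method!r}")
    if normalization not in ("raw", "percent"):
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    y = np.asarray(y, dtype=float).ravel()
    used = method
    scores = None
    if method == "native":
        native = tml_model.importance_scores
        if native is None:
            used = "permutation"
        else:
            scores = native.reindex(tml_model.feature_schema)
    if scores is None:
        scores = _permutation_importance(tml_model, X_tml, y, n_repeats, seed)
    weights = scores.clip(lower=0.0)
    if normalization == "percent":
        total = weights.sum()
        if total > 0:
            weights = 100.0 * weights / total
    task_ids = [c.removeprefix("tml:") for c in weights.index]
    table = pd.DataFrame(
        {"source_task_id": task_ids, "weight": weights.to_numpy()}
    )
    table = table.sort_values(
        ["weight", "source_task_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    if metadata:
        for key in sorted({k for m in metadata.values() for k in m}):
            table[key] = [metadata.get(t, {}).get(key) for t in table["source_task_id"]]
    if top_k is not None:
        if top_k < 1:
            raise ConfigurationError("top_k must be >= 1")
        table = table.head(top_k).reset_index(drop=True)
    return ImportanceRanking(rows=table, method=used, normalization=normalization)


@dataclass
class ProfileMatrix:
    """Prediction profiles: examples x tasks, or tasks x examples."""

    matrix: pd.DataFrame
    axis: str  # example_profiles | problem_profiles

    def __post_init__(self) -> None:
        if self.axis not in ("example_profiles", "problem_profiles"):
            raise ConfigurationError(f"unknown profile axis {self.axis!r}")
        if not np.isfinite(self.matrix.to_numpy()).all():
            raise ConfigurationError("profiles contain non-finite entries")

    @property
    def row_ids(self) -> list[str]:
        return [str(i) for i in self.matrix.index]


def example_profiles(
    registry: ModelRegistry,
    learner_digest: str,
    X: pd.DataFrame,
    representation_tag: str = "baseline",
) -> ProfileMatrix:
    """Rows = examples, column j = task j's model applied to every example."""
    models = registry.models_for(learner_digest, representation_tag)
    if len(models) < 2:
        raise DependencyError("profiles need models for at least 2 tasks")
    columns = {task_id: model.predict(X) for task_id, model in models.items()}
    frame = pd.DataFrame(columns, index=X.index)
    return ProfileMatrix(frame, axis="example_profiles")


def problem_profiles(
    registry: ModelRegistry,
    learner_digest: str,
    probe_examples: pd.DataFrame,
    representation_tag: str = "baseline",
) -> ProfileMatrix:
    """Rows = tasks, columns = probe examples; the transpose of example profiles."""
    profiles = example_profiles(registry, learner_digest, probe_examples, representation_tag)
    return ProfileMatrix(profiles.matrix.T, axis="problem_profiles")


@dataclass
class ClusterTree:
    """An agglomerative merge history over named leaves."""

    linkage_matrix: np.ndarray  # scipy linkage format
    leaf_ids: list[str]
    linkage: str
    distance: str

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.linkage_matrix.shape != (n - 1, 4):
            raise DimensionError("linkage matrix must have n-1 merges for n leaves")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Serialize to Newick; branch lengths are merge-height increments."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def render(node, parent_height) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def hierarchical_cluster(
    profiles: ProfileMatrix | pd.DataFrame,
    distance: str = "correlation",
    linkage: str = "average",
) -> ClusterTree:
    """Agglomeratively cluster profile rows.

    Correlation distance (1 - Pearson between rows) with average linkage is
    the default: prediction profiles carry their signal in shape, not scale.
    Constant rows make correlation distance undefined and are rejected by
    name.  Ward linkage requires euclidean distance.
    """
    frame = profiles.matrix if isinstance(profiles, ProfileMatrix) else profiles
    if distance not in DISTANCES:
        raise ConfigurationError(f"unknown distance {distance!r}")
    if linkage not in LINKAGES:
        raise ConfigurationError(f"unknown linkage {linkage!r}")
    if linkage == "ward" and distance != "euclidean":
        raise ConfigurationError("ward linkage requires euclidean distance")
    if len(frame) < 2:
        raise ConfigurationError("clustering needs at least 2 rows")
    values = frame.to_numpy(dtype=float)
    if distance == "correlation":
        constant = frame.index[values.std(axis=1) == 0].tolist()
        if constant:
            raise ConfigurationError(
                f"correlation distance undefined for constant rows: {constant[:5]}"
            )
    condensed = pdist(values, metric=distance)
    # numerical floor: correlation distance can go epsilon-negative
    condensed = np.clip(condensed, 0.0, None)
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(
        linkage_matrix=Z,
        leaf_ids=[str(i) for i in frame.index],
        linkage=linkage,
        distance=distance,
    )


def cut_clusters(
    tree: ClusterTree, k: int | None = None, height: float | None = None
) -> dict[str, int]:
    """Cut the tree into flat clusters by count ``k`` or by ``height``.

    Exactly one of ``k``/``height`` must be given.  Labels are deterministic:
    cluster 1 contains the smallest leaf index, cluster 2 the smallest leaf
    not yet labelled, and so on.
    """
    if (k is None) == (height is None):
        raise ConfigurationError("give exactly one of k or height")
    n = len(tree.leaf_ids)
    if k is not None:
        if not 1 <= k <= n:
            raise ConfigurationError(f"k={k} out of range [1, {n}]")
        raw = hierarchy.fcluster(tree.linkage_matrix, t=k, criterion="maxclust")
    else:
        if height < 0:
            raise ConfigurationError("height must be >= 0")
        raw = hierarchy.fcluster(tree.linkage_matrix, t=height, criterion="distance")
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for leaf_idx in range(n):
        group = int(raw[leaf_idx])
        if group not in relabel:
            relabel[group] = len(relabel) + 1
        labels[tree.leaf_ids[leaf_idx]] = relabel[group]
    return labels
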