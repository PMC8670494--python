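import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tml import (
    LearnerSpec,
    Task,
    TaskCollection,
    train_baseline_registry,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_task(task_id, n=30, p=4, seed=0, fn=None, metadata=None):
    """A small deterministic task: Gaussian features, smooth target + noise."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if fn is None:
        fn = lambda X: np.sin(X[:, 0]) + 0.5 * X[:, 1]
    y = fn(X) + 0.05 * rng.standard_normal(n)
    frame = pd.DataFrame(
        X, columns=[f"f{j}" for j in range(p)], index=[f"{task_id}_e{i}" for i in range(n)]
    )
    return Task(task_id, frame, pd.Series(y, index=frame.index), metadata=metadata or {})


@pytest.fixture(scope="session")
def small_collection():
    """Three related tasks over a shared 4-feature schema."""
    tasks = [
        make_task("donkey", seed=1),
        make_task("kitten", seed=2),
        make_task("rabbit", seed=3),
    ]
    return TaskCollection(tasks, collection_id="toy")


@pytest.fixture(scope="session")
def knn_spec():
    return LearnerSpec("knn", {"k": 3}, seed=7)


@pytest.fixture(scope="session")
def small_registry(small_collection, knn_spec):
    return train_baseline_registry(small_collection, knn_spec)
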