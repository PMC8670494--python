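"""Stack the baseline and transformed prediction streams for one task.

Computes out-of-fold predictions for both streams, fits the convex (NNLS)
and ridge combiners, and shows the weights and resulting training RMSEs.
"""

import numpy as np

from tml import (
    EvaluationConfig, GeneratorConfig, LearnerSpec, PredictionPanel,
    fit_convex, fit_ridge, generate, stack_predict, train_baseline_registry,
)
from tml.evaluation import cross_validate_task, rmse

config = GeneratorConfig(n_tasks=10, n_examples_per_task=80, p_features=64,
                         latent_dim=6, relatedness=0.9, seed=13)
collection, _ = generate(config)
spec = LearnerSpec("knn", {"k": 5}, seed=2)
registry = train_baseline_registry(collection, spec)

task = collection["task_003"]
evaluation = cross_validate_task(
    task, registry, spec,
    EvaluationConfig(n_folds=5, seed=2, variants=("baseline", "transformed")),
)
y = task.y.to_numpy()
panel = PredictionPanel(
    np.column_stack([evaluation.oof_predictions["baseline"],
                     evaluation.oof_predictions["transformed"]]),
    ["baseline", "tml"], y,
)

convex = fit_convex(panel)
ridge = fit_ridge(panel, seed=2)
print(f"component RMSE: baseline={rmse(panel.matrix[:, 0], y):.4f}, "
      f"tml={rmse(panel.matrix[:, 1], y):.4f}")
print(f"convex weights: {dict(zip(convex.column_labels, convex.weights.round(3).tolist()))}, "
      f"stack RMSE={rmse(stack_predict(convex, panel.matrix), y):.4f}")
print(f"ridge  weights: {dict(zip(ridge.column_labels, ridge.weights.round(3).tolist()))}, "
      f"lambda={ridge.ridge_lambda}, "
      f"stack RMSE={rmse(stack_predict(ridge, panel.matrix), y):.4f}")
# The convex stack's training RMSE can never exceed the better component's;
# the weights show how much each stream contributes.
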