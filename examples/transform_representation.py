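"""Build the extrinsic (transformed) representation for one task.

Trains one baseline model per task, then re-represents task_000's examples
by the predictions of the *other* tasks' models — the core transformation.
"""

from tml import (
    GeneratorConfig, LearnerSpec, generate, train_baseline_registry, transform,
    combined_representation,
)

config = GeneratorConfig(n_tasks=6, n_examples_per_task=60, p_features=48,
                         latent_dim=5, relatedness=0.9, seed=11)
collection, _ = generate(config)
spec = LearnerSpec("knn", {"k": 5}, seed=1)
registry = train_baseline_registry(collection, spec)

task = collection["task_000"]
rep = transform(registry, spec.digest, task.X, exclude_task="task_000")
print(f"intrinsic representation: {task.X.shape[0]} x {task.X.shape[1]} fingerprint bits")
print(f"extrinsic representation: {rep.matrix.shape[0]} x {rep.n_columns} "
      f"source-model predictions, columns = {rep.column_task_ids}")
print("first example, extrinsic features:",
      [round(float(v), 3) for v in rep.matrix[0]])

combined = combined_representation(task.X, rep)
print(f"combined representation: {combined.shape[1]} columns "
      f"({task.X.shape[1]} intrinsic + {rep.n_columns} extrinsic)")
# Each extrinsic feature is another task's predicted target for this
# example; the task's own model is excluded so its target never leaks.
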