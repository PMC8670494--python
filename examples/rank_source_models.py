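"""Rank the source-task models most important to one task's TML model.

Fits a forest TML model on task_000's extrinsic representation and prints
which other tasks' prediction columns carry the most weight — the
interpretability view: related tasks should rank high.
"""

from tml import (
    GeneratorConfig, LearnerSpec, attribute_importance, fit, generate,
    train_baseline_registry, transform,
)

# two groups of tasks: only the first 5 share task_000's true function
config = GeneratorConfig(n_tasks=10, n_examples_per_task=100, p_features=64,
                         latent_dim=6, relatedness=1.0, group_sizes=[5, 5],
                         noise_sd=0.3, seed=17)
collection, truth = generate(config)
spec = LearnerSpec("knn", {"k": 5}, seed=3)
registry = train_baseline_registry(collection, spec)

task = collection["task_000"]
rep = transform(registry, spec.digest, task.X, exclude_task="task_000")
frame = rep.to_frame(index=task.X.index)
tml_model = fit(LearnerSpec("forest", {"n_estimators": 100}, seed=3), frame, task.y)

metadata = {t.task_id: {"group": t.metadata["group"]} for t in collection}
ranking = attribute_importance(tml_model, frame, task.y, method="native",
                               top_k=5, metadata=metadata)
print("top 5 source models for predicting task_000 (weights in % of total):")
print(ranking.rows.to_string(index=False))
# task_000 is in group 0; its group-mates should dominate the ranking
# because their models encode the same underlying function.
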