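# Methods

## The model

The package operates on a collection of $n$ regression tasks
$T_1, \dots, T_n$ sharing one schema of $p$ attributes. Baseline learning
fits one model per task on its intrinsic features, $A_i \approx y_i$. The
transformational step re-represents any example $x$ by the vector of other
models' predictions $(A_1(x), \dots, A_n(x))$ and fits a second-stage
learner $\Phi$ on that representation. Three further constructions build on
it:

- **combined representation** — intrinsic and extrinsic columns
  concatenated (namespaced `base:*` / `tml:<task_id>`), for the case where
  extrinsic features help by augmenting rather than replacing;
- **stacking** — the baseline and TML *predicted outputs* for a task are
  combined linearly, by nonnegative least squares ("convex") or ridge
  regression;
- **second-order transform** — the predictions of the first-order TML
  models used as a representation for a second round.

The premise is that models trained on related tasks encode shared structure
("regularity") that raw features do not expose; the extrinsic
representation makes that knowledge available to any learner.

### Own-model exclusion

For an in-collection task, its own model is excluded from its
representation by default — a model's predictions of its own training
targets are a thinly laundered copy of the labels. For a genuinely new task
all $n$ source models contribute. `transform(..., exclude_task=None)`
overrides (the CLI flag `--include-self`).

Source models are trained once on their tasks' full data; they are **not**
retrained per evaluation fold. When example sets overlap across tasks this
leaves a residual leakage channel: a source task may have been trained on
an example that is in the evaluated task's test fold. The benchmark offers
`strict_no_leak=True`, which retrains every source model per fold without
the held-out example ids; the default keeps the cheaper convention and the
documentation of this risk.

## Learner families

Five nonlinear families sit behind one adapter contract (`LearnerSpec` /
`FittedModel`): random forest, gradient boosting (xgboost), RBF-SVM, k-NN,
and a single-hidden-layer neural network. All fits are single-threaded and
seeded; fit/predict is deterministic per platform (the neural network's
determinism is platform-level only, as is usual for SGD-trained models).
Fitted models carry their feature schema and realign prediction inputs by
column name, refusing mismatches.

Defaults (all overridable per `LearnerSpec`): forest 200 trees,
`max_features="sqrt"`; boosting 200 rounds, depth 3, learning rate 0.1;
SVM C=1, RBF `gamma="scale"`; k-NN k=5, uniform weights; NN one hidden
layer of 64, 500 iterations. `tune()` grid-searches by seeded
cross-validated RMSE with ties resolved in grid order; the shipped grids
(`DEFAULT_GRIDS`) are package choices. SVM and NN standardize features
internally; k-NN uses raw Euclidean distance by default, because its two
input representations — binary fingerprint bits and TML prediction columns
on the target's own scale — are already commensurate, and raw distance
keeps the model equivalent to the plain nearest-neighbour rule (a
`standardize` hyperparameter turns scaling on). TML feature columns are
never externally standardized: they share the target's scale by
construction.

## Evaluation protocol

Per task, a seeded k-fold partition (default 5 folds; seeded by the
evaluation seed and the task size, so identical tasks receive identical
partitions) yields one out-of-fold prediction vector per variant, and RMSE
is computed once on the full vector. All variants of a task share the same
partition, so per-task RMSE pairs are honestly paired.

Stacked variants: the baseline and TML out-of-fold streams are computed
over the shared partition; for each fold, stack weights are fit on the
*other* folds' out-of-fold predictions and applied to the held-out fold —
never on resubstitution predictions.

Aggregation reports the mean RMSE per variant (and the median, since the
sign test addresses medians), the percentage improvement
$100\,(1 - \mathrm{mean}_v / \mathrm{mean}_{\text{baseline}})$, and two
paired tests of each variant against baseline over per-task RMSE
differences:

- **sign test** — exact two-sided binomial on the sign counts; zero
  differences discarded (counts reported so the convention is auditable);
- **Wilcoxon signed-rank** — zeros discarded, average ranks for tied
  absolute differences; the null distribution of the rank sum is computed
  *exactly* for $n \le 25$ (dynamic programming over the doubled — hence
  integer — ranks, valid with ties), and by a normal approximation with
  tie-corrected variance and continuity correction above. The exact path
  was chosen because textbook exact tables do not cover ties, which are
  common in per-task RMSE differences rounded by shared folds.

Tasks that fail to evaluate are skipped with a recorded reason; if more
than 20% fail, the benchmark aborts rather than reporting a silently
censored summary.

## Stacking details

Convex weights solve $\min_w \lVert y - Pw \rVert^2$ s.t. $w \ge 0$ by the
active-set NNLS algorithm; there is no intercept and no sum-to-one
constraint (the streams already live on the target scale; an optional
simplex mode renormalizes for sensitivity analysis). Because unit vectors
are feasible, the convex stack's training RMSE is never worse than any
single stream's — asserted exactly in tests. A rank-deficient panel is
flagged `non_unique`. Ridge solves the centered normal equations in closed
form, recovers the intercept from the means, and picks $\lambda$ from
$\{0.01, 0.1, 1, 10, 100\}$ by 5-fold CV (ties to the smallest $\lambda$;
$\lambda = 0$ is dropped automatically when the Gram matrix's condition
number exceeds $10^{10}$).

## Interpretation

A TML model's feature columns *are* source-task models, so feature
importance doubles as a ranking of which other tasks inform a prediction
problem. Forest/boosting expose native importances; for the other families
the uniform fallback is permutation importance: the mean RMSE increase over
seeded shuffles of each column (10 repeats by default). Weights are
reported as percent of total by default (raw mode available); ties order by
task id.

Prediction profiles: *example profiles* (rows = examples, columns = task
models) cluster examples by predicted behaviour; *problem profiles* are
exactly the transpose, computed on a user-supplied probe set (the synthetic
benchmark draws a fresh probe matrix from the training feature law).
Default clustering is correlation distance ($1 - $ Pearson) with average
linkage: profiles carry their signal in shape, not scale. Constant rows are
rejected by name under correlation distance; Ward linkage requires
Euclidean distance. Trees serialize to Newick with branch lengths equal to
merge-height increments; flat cuts (by count or height) label clusters
deterministically by smallest leaf index.

## The synthetic generator

The generator plants the two relatedness channels real task families have:
shared structure in the *function* and shared *examples*.

- Features: $p$ binary fingerprint-like bits, each with frequency drawn
  once from Beta(0.3, 1) (sparse, heterogeneous, like real substructure
  keys), or standard Gaussians.
- Truth: a shared loading matrix $B \in \mathbb{R}^{p \times k}$ maps
  features to a $k$-dimensional latent space; task $i$'s coefficient vector
  is $w_i = \sqrt{\rho}\,\bar w + \sqrt{1-\rho}\,u_i$ with
  $\bar w, u_i \sim \mathcal N(0, I_k)$, so $\mathrm{Corr}(w_i, w_j) = \rho$;
  optional task groups each get an independent $\bar w$ (between-group
  relatedness 0).
- Targets: $y = f(z^\top w_i) + \varepsilon$ with $z = x^\top B$,
  $\varepsilon \sim \mathcal N(0, \sigma^2)$. The default nonlinearity is a
  tanh squash of the standardized linear index — with a purely linear
  truth, kernel and forest baselines already saturate and the extrinsic
  representation has little room to help; `none` and `interactions` are
  available. The squash scale and the noise level (default
  $\sigma = 0.5 \times \mathrm{sd}(\text{signal})$, i.e. expected
  $R^2 = 0.8$) are calibrated per task on a large reference sample drawn
  inside the generator, so the true function is a fixed object rather than
  a property of the drawn data.
- Overlap: a fraction (default 0.3) of each task's examples comes from a
  shared pool, as overlapping compound libraries do.
- Reproducibility: all streams (feature law, truth, pool, tasks, noise,
  probes) derive from one seed; identical configs give byte-identical
  collections, and probe sets share the training feature law while staying
  disjoint in ids.

What the generator does *not* emulate: chemistry. Bits are independent
given their frequencies — no substructure correlation, no activity cliffs,
no assay heterogeneity. Passing benchmarks here show the machinery exploits
planted relatedness correctly; they do not predict effect sizes on real
corpora.

## Benchmark configurations

- **Experiment A (related tasks)**: the default generator config — 60
  tasks × 100 examples, $p = 128$, $k = 10$, $\rho = 0.9$, squash
  nonlinearity, overlap 0.3 — evaluated with the forest (100 trees for this
  benchmark) and k-NN families, 5-fold CV, variants baseline / transformed
  / stacked-convex / stacked-ridge. Small per-task sample sizes are
  deliberate: many related *small* tasks is the regime the method targets.
- **Experiment B (unrelated-task control)**: the same protocol at
  $\rho = 0$, 20 replicate seeds, k-NN family (the forest adds nothing to
  the control's logic and the control is replicated 20-fold). A replicate
  counts as a spurious win only if the transformed variant is significantly
  different from baseline *and* better on a majority of tasks — at
  $\rho = 0$ the extrinsic features are uninformative, so being
  significantly *worse* is expected behaviour, not manufactured signal.
- **Clustering recovery**: 12 tasks in two planted groups (within-group
  $\rho = 1$, between-group 0), k-NN models, 150 probe examples,
  correlation/average-linkage clustering of problem profiles cut at
  $k = 2$, scored by adjusted Rand index against the planted partition.
  With $k = 8$ latent dimensions the two groups' shared components are
  occasionally similar by chance, so perfect recovery in every seed is not
  expected; the study reports the recovery rate over 20 seeds.

## Numerical choices and degenerate inputs

- Tie-breaking is deterministic everywhere: tuning ties by grid order,
  ridge $\lambda$ ties to the smallest value, importance ties by task id,
  selection ties by column order, clustering tie behaviour fixed by the
  linkage implementation.
- Constant targets fit legally but are flagged (`zero_variance_target`);
  constant-target correlation-based feature selection falls back to
  importance with a recorded warning; constant profile rows are rejected
  under correlation distance.
- Transformed columns from constant source models pass through unchanged —
  no silent column dropping.
- Registry round-trips are bit-exact for deterministic learners; a
  serialization version mismatch raises instead of risking silent
  misprediction.
- All seeds are reduced modulo $2^{31}$ before reaching underlying
  libraries; derived seeds come from SHA-256 of (seed, context) so stages
  are decoupled.

## Known limitations

- The neural-network family is deterministic only per platform; benchmark
  defaults therefore use forest and k-NN.
- `strict_no_leak` retrains source models per fold and is quadratic in the
  collection size; it is an audit tool, not a default.
- Second-order transforms rebuild first-order representations on the fly,
  costing $O(n^2)$ model predictions per collection.
- The exact Wilcoxon path is limited to $n \le 25$ non-zero differences;
  beyond that the tie-corrected normal approximation is used.
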