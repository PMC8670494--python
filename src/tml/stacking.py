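"""Stacking of prediction streams: convex (NNLS) and ridge combination.

The simplest form of stacking: learn a linear combiner over columns of
out-of-fold predictions (typically the baseline stream and the TML stream
for one task, but any number of streams is accepted — e.g. ensembling TML
models of several learner families).

Two combiners:

* **convex** — nonnegative least squares, ``min ||y - Pw||^2 s.t. w >= 0``,
  no intercept and no sum-to-one constraint (an optional simplex mode
  renormalizes for sensitivity analysis).  Because every unit vector is
  feasible, the training RMSE of the convex stack can never exceed that of
  any single component stream.
* **ridge** — closed-form ``w = (P'P + lambda I)^{-1} P'y`` on column-centered
  data, intercept recovered from the means, ``lambda`` picked by
  cross-validated RMSE over a grid (ties -> smallest lambda).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.model_selection import KFold

from ._exceptions import ConfigurationError, DimensionError, SchemaError

DEFAULT_LAMBDA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)

# lambda=0 is dropped from a ridge grid when P'P is this ill-conditioned
_CONDITION_LIMIT = 1e10


@dataclass
class PredictionPanel:
    """Aligned out-of-fold prediction columns plus the observed target."""

    matrix: np.ndarray
    column_labels: list[str]
    target: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.target = np.asarray(self.target, dtype=float).ravel()
        if self.matrix.ndim != 2:
            raise DimensionError("panel matrix must be 2-D")
        if self.matrix.shape[1] != len(self.column_labels):
            raise DimensionError(
                f"{self.matrix.shape[1]} columns vs {len(self.column_labels)} labels"
            )
        if self.matrix.shape[0] != len(self.target):
            raise DimensionError("panel rows must align with target length")
        if not np.isfinite(self.matrix).all() or not np.isfinite(self.target).all():
            raise ConfigurationError("panel contains non-finite entries")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.matrix, columns=self.column_labels)
        frame["target"] = self.target
        return frame


@dataclass
class StackWeights:
    """Fitted combiner: per-column weights, intercept, and provenance."""

    weights: np.ndarray
    intercept: float
    method: str
    column_labels: list[str]
    ridge_lambda: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if len(self.weights) != len(self.column_labels):
            raise DimensionError("one weight per panel column required")
        if not np.isfinite(self.weights).all() or not np.isfinite(self.intercept):
            raise ConfigurationError("non-finite stack weights")
        if self.method == "convex" and (self.weights < 0).any():
            raise ConfigurationError("convex weights must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "weights": dict(zip(self.column_labels, map(float, self.weights))),
            "intercept": float(self.intercept),
            "ridge_lambda": self.ridge_lambda,
            "diagnostics": self.diagnostics,
        }


def fit_convex(panel: PredictionPanel, simplex: bool = False) -> StackWeights:
    """Nonnegative least-squares combination of the panel columns.

    Solved by the active-set NNLS algorithm (deterministic pivoting).  A
    rank-deficient panel has multiple optima; the solver's solution is
    returned and ``diagnostics['non_unique']`` is set.  With ``simplex=True``
    the weights are renormalized to sum to one (sensitivity-analysis mode).
    """
    if panel.n_columns < 2:
        raise ConfigurationError("stacking needs at least 2 prediction columns")
    P, y = panel.matrix, panel.target
    w, residual = nnls(P, y)
    rank = np.linalg.matrix_rank(P)
    diagnostics = {
        "residual_norm": float(residual),
        "non_unique": bool(rank < panel.n_columns),
    }
    if simplex:
        total = w.sum()
        if total <= 0:
            raise ConfigurationError("simplex mode undefined: all weights zero")
        w = w / total
        diagnostics["simplex"] = True
    return StackWeights(w, 0.0, "convex", list(panel.column_labels), diagnostics=diagnostics)


def _ridge_solve(P: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Closed-form ridge on centered columns; intercept from the means."""
    col_means = P.mean(axis=0)
    y_mean = y.mean()
    Pc = P - col_means
    yc = y - y_mean
    gram = Pc.T @ Pc + lam * np.eye(P.shape[1])
    w = np.linalg.solve(gram, Pc.T @ yc)
    return w, float(y_mean - col_means @ w)


def fit_ridge(
    panel: PredictionPanel,
    lambda_grid: tuple[float, ...] | list[float] = DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> StackWeights:
    """Ridge combination with lambda chosen by cross-validated RMSE.

    Ties in CV-RMSE go to the smallest lambda.  lambda=0 is excluded
    automatically (and recorded) when the centered Gram matrix is too
    ill-conditioned for a meaningful unpenalized solve.
    """
    if panel.n_columns < 2:
        raise ConfigurationError("stacking needs at least 2 prediction columns")
    grid = sorted(float(l) for l in lambda_grid)
    if not grid:
        raise ConfigurationError("lambda_grid is empty")
    if any(l < 0 for l in grid):
        raise ConfigurationError("lambda values must be nonnegative")
    P, y = panel.matrix, panel.target
    diagnostics: dict = {}
    if 0.0 in grid:
        Pc = P - P.mean(axis=0)
        cond = np.linalg.cond(Pc.T @ Pc)
        if not np.isfinite(cond) or cond > _CONDITION_LIMIT:
            grid = [l for l in grid if l > 0]
            diagnostics["lambda_zero_excluded"] = float(cond)
            if not grid:
                raise ConfigurationError(
                    "lambda grid reduced to empty after excluding singular lambda=0"
                )
    if len(grid) == 1:
        best_lam = grid[0]
    else:
        splitter = KFold(
            n_splits=min(n_folds, len(y)), shuffle=True, random_state=seed % (2**31)
        )
        folds = list(splitter.split(P))
        best_lam, best_score = None, np.inf
        for lam in grid:  # ascending: ties keep the smallest lambda
            sq_errors = []
            for train_idx, test_idx in folds:
                w, b = _ridge_solve(P[train_idx], y[train_idx], lam)
                pred = P[test_idx] @ w + b
                sq_errors.append(np.mean((pred - y[test_idx]) ** 2))
            score = float(np.sqrt(np.mean(sq_errors)))
            if score < best_score:
                best_lam, best_score = lam, score
        diagnostics["cv_rmse"] = best_score
    w, b = _ridge_solve(P, y, best_lam)
    return StackWeights(
        w, b, "ridge", list(panel.column_labels), ridge_lambda=best_lam,
        diagnostics=diagnostics,
    )


def stack_predict(
    weights: StackWeights,
    new_panel: np.ndarray | pd.DataFrame,
    column_labels: list[str] | None = None,
) -> np.ndarray:
    """Apply fitted stack weights to a new panel: ``P w + intercept``."""
    if isinstance(new_panel, pd.DataFrame):
        labels = list(new_panel.columns)
        matrix = new_panel.to_numpy(dtype=float)
    else:
        matrix = np.asarray(new_panel, dtype=float)
        labels = column_labels
    if labels is not None and list(labels) != list(weights.column_labels):
        raise SchemaError(
            f"panel columns {labels} do not match stack weights "
            f"{weights.column_labels}"
        )
    if matrix.ndim != 2 or matrix.shape[1] != len(weights.weights):
        raise DimensionError(
            f"panel shape {matrix.shape} vs {len(weights.weights)} weights"
        )
    return matrix @ weights.weights + weights.intercept
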