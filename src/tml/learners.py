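"""Uniform adapters over the five nonlinear learner families.

The downstream machinery (transform, stacking, benchmark) is learner-agnostic:
it sees only :class:`LearnerSpec` (family + hyperparameters + seed) and
:class:`FittedModel` (predicts on schema-checked feature frames).  The five
families mirror the main nonlinear regression method families — random
forests, gradient boosting, RBF support-vector machines, k-nearest
neighbours, and feed-forward neural networks — backed by scikit-learn and
xgboost.

Determinism: every family is fit single-threaded with an explicit seed, so
fit/predict is reproducible on a given platform.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from ._exceptions import ConfigurationError, SchemaError

FAMILIES = ("forest", "boosting", "svm", "knn", "nn")

# Allowed hyperparameter keys per family (unknown keys are rejected).
_ALLOWED_KEYS = {
    "forest": {"n_estimators", "max_features", "min_samples_leaf", "max_depth"},
    "boosting": {"n_estimators", "max_depth", "learning_rate", "subsample"},
    "svm": {"C", "gamma", "epsilon"},
    "knn": {"k", "weights", "standardize"},
    "nn": {"hidden", "max_iter", "alpha", "learning_rate_init"},
}

# Default hyperparameters: sensible for small tabular tasks (tens to a few
# hundred examples), overridable per spec.
_DEFAULTS = {
    "forest": {"n_estimators": 200, "max_features": "sqrt", "min_samples_leaf": 1},
    "boosting": {"n_estimators": 200, "max_depth": 3, "learning_rate": 0.1},
    "svm": {"C": 1.0, "gamma": "scale", "epsilon": 0.1},
    "knn": {"k": 5, "weights": "uniform", "standardize": False},
    "nn": {"hidden": 64, "max_iter": 500, "alpha": 1e-4},
}

# Default tuning grids.  The families were historically tuned per task; the
# exact grids are a package choice and fully overridable.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "forest": {"n_estimators": [500], "max_features": ["sqrt", 0.33]},
    "boosting": {"max_depth": [3, 6], "n_estimators": [200]},
    "svm": {"C": [0.1, 1.0, 10.0], "gamma": ["scale"]},
    "knn": {"k": [1, 3, 5, 11, 25]},
    "nn": {"hidden": [64, 256]},
}


@dataclass(frozen=True)
class LearnerSpec:
    """A learner family plus hyperparameters, tuning grid and seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    tuning_grid: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown learner family {self.family!r}; choose from {FAMILIES}"
            )
        unknown = set(self.hyperparameters) - _ALLOWED_KEYS[self.family]
        if unknown:
            raise ConfigurationError(
                f"unknown hyperparameters for {self.family}: {sorted(unknown)}"
            )

    @property
    def params(self) -> dict:
        """Hyperparameters with family defaults filled in."""
        return {**_DEFAULTS[self.family], **self.hyperparameters}

    @property
    def digest(self) -> str:
        """Stable hash of family + sorted hyperparameters (not the seed).

        Models fit from specs with equal digests are interchangeable columns
        in the transformed representation.
        """
        payload = json.dumps(
            {"family": self.family, "params": self.params}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def with_seed(self, seed: int) -> "LearnerSpec":
        return replace(self, seed=int(seed))


def _build_estimator(spec: LearnerSpec, n_rows: int):
    p = spec.params
    seed = int(spec.seed) % (2**31)
    if spec.family == "forest":
        return RandomForestRegressor(
            n_estimators=int(p["n_estimators"]),
            max_features=p["max_features"],
            min_samples_leaf=int(p["min_samples_leaf"]),
            max_depth=p.get("max_depth"),
            random_state=seed,
            n_jobs=1,
        )
    if spec.family == "boosting":
        from xgboost import XGBRegressor

        return XGBRegressor(
            n_estimators=int(p["n_estimators"]),
            max_depth=int(p["max_depth"]),
            learning_rate=float(p["learning_rate"]),
            subsample=float(p.get("subsample", 1.0)),
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )
    if spec.family == "svm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svr", SVR(C=float(p["C"]), gamma=p["gamma"], epsilon=float(p["epsilon"]))),
            ]
        )
    if spec.family == "knn":
        k = int(p["k"])
        if k > n_rows:
            raise ConfigurationError(
                f"knn with k={k} needs at least {k} training rows, got {n_rows}"
            )
        est = KNeighborsRegressor(n_neighbors=k, weights=p["weights"], n_jobs=1)
        if p["standardize"]:
            return Pipeline([("scale", StandardScaler()), ("knn", est)])
        return est
    if spec.family == "nn":
        hidden = p["hidden"]
        layers = tuple(hidden) if isinstance(hidden, (list, tuple)) else (int(hidden),)
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPRegressor(
                        hidden_layer_sizes=layers,
                        max_iter=int(p["max_iter"]),
                        alpha=float(p["alpha"]),
                        learning_rate_init=float(p.get("learning_rate_init", 1e-3)),
                        random_state=seed,
                        early_stopping=False,
                    ),
                ),
            ]
        )
    raise ConfigurationError(f"unknown family {spec.family!r}")  # pragma: no cover


class FittedModel:
    """A fitted learner bound to the feature schema it was trained on.

    ``predict`` realigns columns by name and refuses matrices whose columns
    do not match the training schema, so a model can never silently consume
    features in the wrong order.
    """

    def __init__(self, spec: LearnerSpec, estimator, feature_schema: list[str], fit_metadata: dict):
        self.spec = spec
        self.estimator = estimator
        self.feature_schema = list(feature_schema)
        self.fit_metadata = fit_metadata

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_schema if c not in X.columns]
            extra = [c for c in X.columns if c not in self.feature_schema]
            if missing or extra:
                raise SchemaError(
                    f"feature mismatch: missing {missing[:5]}, extra {extra[:5]}"
                )
            values = X[self.feature_schema].to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim != 2 or values.shape[1] != len(self.feature_schema):
                raise SchemaError(
                    f"expected {len(self.feature_schema)} feature columns, "
                    f"got shape {values.shape}"
                )
        if values.shape[0] == 0:
            return np.empty(0, dtype=float)
        out = np.asarray(self.estimator.predict(values), dtype=float).ravel()
        if not np.isfinite(out).all():
            out = np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)
        return out

    @property
    def importance_scores(self) -> pd.Series | None:
        """Native per-feature importances (forest/boosting), else ``None``."""
        est = self.estimator
        if hasattr(est, "feature_importances_"):
            scores = np.asarray(est.feature_importances_, dtype=float)
            return pd.Series(np.clip(scores, 0.0, None), index=self.feature_schema)
        return None


def fit(spec: LearnerSpec, X: pd.DataFrame, y: np.ndarray | pd.Series) -> FittedModel:
    """Fit one model; deterministic given ``(spec.seed, X, y)``.

    A constant target is legal — the model fits but ``fit_metadata`` flags
    ``zero_variance_target`` so downstream consumers can tell.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [str(c) for c in X.columns]
    y = np.asarray(y, dtype=float).ravel()
    if len(X) != len(y):
        raise ConfigurationError(f"{len(X)} rows vs {len(y)} targets")
    if len(X) < 2:
        raise ConfigurationError("need at least 2 training rows")
    estimator = _build_estimator(spec, n_rows=len(X))
    estimator.fit(X.to_numpy(dtype=float), y)
    meta = {
        "n_train": len(X),
        "seed": spec.seed,
        "hyperparameters": spec.params,
        "zero_variance_target": bool(np.all(y == y[0])),
    }
    return FittedModel(spec, estimator, list(X.columns), meta)


def predict(model: FittedModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`FittedModel.predict`."""
    return model.predict(X)


def _grid_points(grid: dict[str, list]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def tune(
    spec: LearnerSpec,
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_folds: int = 5,
    metric: str = "rmse",
) -> LearnerSpec:
    """Grid search by cross-validated RMSE; returns the winning spec.

    Ties are broken by grid order (first listed wins); a grid point that
    fails to fit scores +inf and never aborts the search; fold assignment is
    seeded from ``spec.seed``.
    """
    if metric != "rmse":
        raise ConfigurationError(f"unsupported tuning metric {metric!r}")
    grid = spec.tuning_grid if spec.tuning_grid is not None else DEFAULT_GRIDS[spec.family]
    if not grid:
        raise ConfigurationError("tuning_grid is empty")
    if n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    y = np.asarray(y, dtype=float).ravel()
    folds = list(
        KFold(n_splits=min(n_folds, len(X)), shuffle=True, random_state=spec.seed % (2**31)).split(X)
    )
    best_score, best_params = np.inf, None
    for params in _grid_points(grid):
        candidate = LearnerSpec(spec.family, {**spec.hyperparameters, **params}, seed=spec.seed)
        errors = []
        try:
            for train_idx, test_idx in folds:
                model = fit(candidate, X.iloc[train_idx], y[train_idx])
                pred = model.predict(X.iloc[test_idx])
                errors.append(float(np.sqrt(np.mean((pred - y[test_idx]) ** 2))))
            score = float(np.mean(errors))
        except Exception:
            score = np.inf
        if score < best_score:  # strict: ties keep the earlier grid point
            best_score, best_params = score, params
    if best_params is None:
        raise ConfigurationError("every grid point failed to fit")
    return LearnerSpec(
        spec.family, {**spec.hyperparameters, **best_params}, tuning_grid=grid, seed=spec.seed
    )
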