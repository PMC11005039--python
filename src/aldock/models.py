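"""Uniform train/predict layer over the benchmarked regressor families.

Families map 1:1 to scikit-learn estimators at their documented defaults;
the exact resolved hyperparameters of every fit are recorded so runs are
reproducible even if library defaults drift between versions.  Features
are raw binary fingerprints for every family (no centering/scaling).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import sklearn

__all__ = ["ModelSpec", "FittedModel", "fit", "predict", "MODEL_FAMILIES"]

#: family name -> (module path, class name, accepts random_state)
MODEL_FAMILIES: dict[str, tuple[str, str, bool]] = {
    "linear": ("sklearn.linear_model", "LinearRegression", False),
    "ridge": ("sklearn.linear_model", "Ridge", False),
    "ridge_cv": ("sklearn.linear_model", "RidgeCV", False),
    "lasso": ("sklearn.linear_model", "Lasso", False),
    "lasso_cv": ("sklearn.linear_model", "LassoCV", True),
    "linear_svr": ("sklearn.svm", "LinearSVR", True),
    "knn": ("sklearn.neighbors", "KNeighborsRegressor", False),
    "decision_tree": ("sklearn.tree", "DecisionTreeRegressor", True),
    "random_forest": ("sklearn.ensemble", "RandomForestRegressor", True),
}


@dataclass(frozen=True)
class ModelSpec:
    """Base-regressor family, optional hyperparameter overrides, and seed.

    An empty hyperparameter map means the estimator's library defaults;
    ``seed`` feeds ``random_state`` for stochastic families and is ignored
    by deterministic ones.
    """

    family: str = "linear"
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; known: {sorted(MODEL_FAMILIES)}"
            )

    def to_dict(self) -> dict:
        return {"family": self.family, "hyperparameters": dict(self.hyperparameters),
                "seed": self.seed}


@dataclass
class FittedModel:
    """A trained base regressor plus bookkeeping for rank ensembling.

    ``cached_predictions``, when set, holds this model's predictions over
    the FULL library, computed once at model creation and reused for rank
    ensembling at every later iteration.
    """

    spec: ModelSpec
    estimator: Any
    n_train: int
    n_features: int
    fit_seconds: float
    resolved_params: dict[str, Any]
    sklearn_version: str = sklearn.__version__
    cached_predictions: np.ndarray | None = None


def _make_estimator(spec: ModelSpec):
    import importlib

    module, cls_name, stochastic = MODEL_FAMILIES[spec.family]
    cls = getattr(importlib.import_module(module), cls_name)
    kwargs = dict(spec.hyperparameters)
    if stochastic and spec.seed is not None and "random_state" not in kwargs:
        kwargs["random_state"] = spec.seed
    return cls(**kwargs)


def fit(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> FittedModel:
    """Train a base regressor on fingerprints X and docking scores y."""
    X = np.asarray(X)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D, got shape {X.shape}")
    if X.shape[0] != len(y):
        raise ValueError(f"X has {X.shape[0]} rows but y has {len(y)} entries")
    if len(y) < 2:
        raise ValueError("need at least 2 training ligands")
    if not np.all(np.isfinite(y)):
        raise ValueError("training scores must be finite")
    estimator = _make_estimator(spec)
    t0 = time.perf_counter()
    estimator.fit(X, y)  # family-specific failures surface as-is
    elapsed = time.perf_counter() - t0
    return FittedModel(
        spec=spec,
        estimator=estimator,
        n_train=X.shape[0],
        n_features=X.shape[1],
        fit_seconds=elapsed,
        resolved_params={k: repr(v) for k, v in estimator.get_params().items()},
    )


def predict(model: FittedModel, X: np.ndarray, chunk: int = 1 << 17) -> np.ndarray:
    """Predict docking scores; chunked so million-row libraries never force
    a full float64 copy of the fingerprint matrix at once."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width mismatch: model trained on {model.n_features} bits, "
            f"input has shape {X.shape}"
        )
    if X.shape[0] <= chunk:
        return np.asarray(model.estimator.predict(X), dtype=np.float64)
    parts = [
        np.asarray(model.estimator.predict(X[i : i + chunk]), dtype=np.float64)
        for i in range(0, X.shape[0], chunk)
    ]
    return np.concatenate(parts)
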