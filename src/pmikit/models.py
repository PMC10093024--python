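"""The six regression strategies behind one fit/predict contract.

Tree-family methods (a single regression tree, bagging, random forests,
extremely randomized trees) consume the raw 4-column feature matrix.  The
support-vector methods (RBF-kernel SVR and its AdaBoost ensemble) are
scale-sensitive, so both the features and the label are standardized with
training-set statistics that are stored in the trained model; epsilon for
the SVR family is therefore expressed in standardized label units.

Hyperparameter defaults were fixed once by a small design sweep (the C
regularization weight stays exposed, mirroring the C in {5,10,20,50,100}
sweep used when benchmarking).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
from sklearn.ensemble import (
    AdaBoostRegressor,
    BaggingRegressor,
    ExtraTreesRegressor,
    RandomForestRegressor,
)
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .datasets import CaseDataset

__all__ = [
    "METHODS",
    "SVR_METHODS",
    "RegressorSpec",
    "TrainedModel",
    "ModelFileError",
    "train",
    "predict",
    "save_model",
    "load_model",
]

#: Method identifiers, in the order they are reported.
METHODS = (
    "decision_tree",
    "bagging",
    "random_forest",
    "extra_trees",
    "svr_rbf",
    "adaboost_svr",
)

#: Methods that use the standardized feature/label space.
SVR_METHODS = frozenset({"svr_rbf", "adaboost_svr"})

_MODEL_FORMAT = "pmikit-model"
_MODEL_VERSION = 1

_DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "decision_tree": {},
    "bagging": {"n_estimators": 100},
    "random_forest": {"n_estimators": 100},
    "extra_trees": {"n_estimators": 100},
    # epsilon/gamma act on standardized features and label
    "svr_rbf": {"C": 100.0, "epsilon": 0.01, "gamma": 1.5, "tol": 1e-2},
    "adaboost_svr": {
        "C": 100.0,
        "epsilon": 0.01,
        "gamma": 1.5,
        "tol": 1e-2,
        "n_estimators": 5,
        "loss": "linear",
        "learning_rate": 1.0,
    },
}


@dataclass(frozen=True)
class RegressorSpec:
    """Method identifier plus hyperparameters and RNG seed."""

    method: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        merged = dict(_DEFAULT_HYPERPARAMETERS[self.method])
        unknown = set(self.hyperparameters) - set(merged)
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.method}: {sorted(unknown)}")
        merged.update(self.hyperparameters)
        if self.method in SVR_METHODS and merged["C"] <= 0:
            raise ValueError("C must be positive")
        object.__setattr__(self, "hyperparameters", merged)


def _build_estimator(spec: RegressorSpec):
    hp = spec.hyperparameters
    if spec.method == "decision_tree":
        return DecisionTreeRegressor(random_state=spec.seed)
    if spec.method == "bagging":
        return BaggingRegressor(n_estimators=hp["n_estimators"], random_state=spec.seed)
    if spec.method == "random_forest":
        return RandomForestRegressor(n_estimators=hp["n_estimators"], random_state=spec.seed)
    if spec.method == "extra_trees":
        return ExtraTreesRegressor(n_estimators=hp["n_estimators"], random_state=spec.seed)
    svr = SVR(
        kernel="rbf",
        C=hp["C"],
        epsilon=hp["epsilon"],
        gamma=hp["gamma"],
        tol=hp["tol"],
        cache_size=500,
    )
    if spec.method == "svr_rbf":
        return svr
    return AdaBoostRegressor(
        estimator=svr,
        n_estimators=hp["n_estimators"],
        learning_rate=hp["learning_rate"],
        loss=hp["loss"],
        random_state=spec.seed,
    )


@dataclass
class TrainedModel:
    """A fitted predictor plus the scaling state needed to apply it."""

    spec: RegressorSpec
    estimator: Any
    x_mean: np.ndarray | None
    x_scale: np.ndarray | None
    y_mean: float | None
    y_scale: float | None
    n_train: int
    trained_at: float

    @property
    def standardized(self) -> bool:
        return self.x_mean is not None


def train(spec: RegressorSpec, train_data: CaseDataset) -> TrainedModel:
    """Fit `spec` on the labelled dataset; deterministic given spec.seed."""
    if len(train_data) < 10:
        raise ValueError("need at least 10 training cases")
    X, y = train_data.X, train_data.y
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("training features and labels must be finite")

    estimator = _build_estimator(spec)
    x_mean = x_scale = y_mean = y_scale = None
    if spec.method in SVR_METHODS:
        x_mean = X.mean(axis=0)
        x_scale = X.std(axis=0)
        x_scale[x_scale == 0.0] = 1.0
        y_mean = float(y.mean())
        y_scale = float(y.std()) or 1.0
        estimator.fit((X - x_mean) / x_scale, (y - y_mean) / y_scale)
    else:
        estimator.fit(X, y)
    return TrainedModel(
        spec=spec,
        estimator=estimator,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        n_train=len(train_data),
        trained_at=time.time(),
    )


def predict(model: TrainedModel, cases: CaseDataset | np.ndarray) -> np.ndarray:
    """Predict one interval (hours) per case."""
    X = cases.X if isinstance(cases, CaseDataset) else np.asarray(cases, dtype=float)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError(f"expected an n x 4 feature matrix, got shape {X.shape}")
    if model.standardized:
        return model.estimator.predict((X - model.x_mean) / model.x_scale) * model.y_scale + model.y_mean
    return model.estimator.predict(X)


class ModelFileError(RuntimeError):
    """Model file is corrupt or has an unsupported format/version."""


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model in a versioned joblib container."""
    payload = {
        "format": _MODEL_FORMAT,
        "version": _MODEL_VERSION,
        "spec": {
            "method": model.spec.method,
            "hyperparameters": model.spec.hyperparameters,
            "seed": model.spec.seed,
        },
        "estimator": model.estimator,
        "x_mean": model.x_mean,
        "x_scale": model.x_scale,
        "y_mean": model.y_mean,
        "y_scale": model.y_scale,
        "n_train": model.n_train,
        "trained_at": model.trained_at,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    """Load a model saved by :func:`save_model`; predictions round-trip exactly."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # joblib raises a zoo of unpickling errors
        raise ModelFileError(f"{path}: not a readable model file ({exc})") from exc
    if not isinstance(payload, dict) or payload.get("format") != _MODEL_FORMAT:
        raise ModelFileError(f"{path}: not a {_MODEL_FORMAT} container")
    if payload.get("version") != _MODEL_VERSION:
        raise ModelFileError(
            f"{path}: unsupported model version {payload.get('version')!r}"
        )
    spec = RegressorSpec(
        method=payload["spec"]["method"],
        hyperparameters=payload["spec"]["hyperparameters"],
        seed=payload["spec"]["seed"],
    )
    return TrainedModel(
        spec=spec,
        estimator=payload["estimator"],
        x_mean=payload["x_mean"],
        x_scale=payload["x_scale"],
        y_mean=payload["y_mean"],
        y_scale=payload["y_scale"],
        n_train=payload["n_train"],
        trained_at=payload["trained_at"],
    )
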