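"""Regression inversion of the composite stress score from spectral features.

Four model kinds map the selected spectral indices to CSPC: a random forest
(100 trees), a backpropagation neural network (8 hidden layers of
12,12,24,24,48,48,6,6 ReLU units, Adam, 1500 iterations), an RBF support
vector regressor (gamma 0.1), and ridge regression (alpha 1.0).  Features
are standardized before the SVR/ridge/network fits; the forest consumes raw
features.  Predicted scores are converted to stress levels with the grading
scheme stored by the scoring stage, and validated with R^2 (both the
regression-standard form 1 - SSE/SST and the variance-ratio form
sum(yhat - ybar)^2 / sum(y - ybar)^2), RMSE, and exact level accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .cspc_scoring import GradingScheme, grade

__all__ = [
    "MODEL_KINDS",
    "SplitSpec",
    "ModelSpec",
    "ValidationReport",
    "split",
    "train_model",
    "r_squared",
    "rmse",
    "level_accuracy",
    "predict_levels",
    "run_inversion",
]

MODEL_KINDS = ("RF", "BPNN", "SVR", "RR")

BPNN_HIDDEN_LAYERS = (12, 12, 24, 24, 48, 48, 6, 6)


@dataclass(frozen=True)
class SplitSpec:
    n_train: int = 352
    n_valid: int = 80
    seed: int = 0


@dataclass
class ModelSpec:
    kind: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")


def split(n_total: int, spec: SplitSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded uniform random partition into disjoint train/valid index sets."""
    if spec.n_train + spec.n_valid != n_total:
        raise ValueError(
            f"split sizes {spec.n_train}+{spec.n_valid} != {n_total}")
    perm = np.random.default_rng(spec.seed).permutation(n_total)
    return np.sort(perm[:spec.n_train]), np.sort(perm[spec.n_train:])


def _build_estimator(spec: ModelSpec, seed: int):
    hp = spec.hyperparameters
    if spec.kind == "RF":
        return RandomForestRegressor(
            n_estimators=hp.get("n_estimators", 100), random_state=seed)
    if spec.kind == "BPNN":
        net = MLPRegressor(
            hidden_layer_sizes=hp.get("hidden_layer_sizes", BPNN_HIDDEN_LAYERS),
            activation="relu", solver="adam",
            learning_rate_init=hp.get("learning_rate_init", 1e-3),
            alpha=hp.get("alpha", 1e-4),
            max_iter=hp.get("max_iter", 1500), random_state=seed)
        return make_pipeline(StandardScaler(), net)
    if spec.kind == "SVR":
        svr = SVR(kernel="rbf", gamma=hp.get("gamma", 0.1),
                  C=hp.get("C", 1.0), epsilon=hp.get("epsilon", 0.1))
        return make_pipeline(StandardScaler(), svr)
    if spec.kind == "RR":
        return make_pipeline(StandardScaler(),
                             Ridge(alpha=hp.get("alpha", 1.0)))
    raise ValueError(spec.kind)


def train_model(spec: ModelSpec, features: np.ndarray, targets: np.ndarray,
                seed: int = 0):
    """Fit one predictor; training is seeded for reproducibility."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in features or targets")
    model = _build_estimator(spec, seed)
    model.fit(X, y)
    return model


def r_squared(y_true, y_pred, mode: str = "standard") -> float:
    """Coefficient of determination.

    mode="standard": 1 - sum(yhat - y)^2 / sum(y - ybar)^2.
    mode="printed":  sum(yhat - ybar)^2 / sum(y - ybar)^2 (variance-ratio
    form; equals the standard form only for an OLS fit with intercept).
    """
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need equal-length vectors with >= 2 entries")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise ValueError("zero variance in y_true")
    if mode == "printed":
        return float(np.sum((yhat - y.mean()) ** 2)) / sst
    if mode == "standard":
        return 1.0 - float(np.sum((yhat - y) ** 2)) / sst
    raise ValueError(f"unknown mode {mode!r}")


def rmse(y_true, y_pred) -> float:
    """Root mean squared error."""
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if y.shape != yhat.shape or y.size < 1:
        raise ValueError("need equal-length vectors")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def level_accuracy(true_levels, pred_levels) -> Tuple[float, Dict[int, int]]:
    """Fraction of exactly matching levels, plus confusion counts keyed by
    signed level difference (true - predicted)."""
    t = np.asarray(true_levels, dtype=int)
    p = np.asarray(pred_levels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("length mismatch")
    diffs, counts = np.unique(t - p, return_counts=True)
    return float(np.mean(t == p)), {int(d): int(c)
                                    for d, c in zip(diffs, counts)}


def predict_levels(model, features: np.ndarray,
                   scheme: GradingScheme) -> np.ndarray:
    """Predict CSPC and grade it with the stored scheme."""
    if scheme is None:
        raise ValueError("grading scheme required to convert scores to levels")
    return grade(model.predict(np.asarray(features, dtype=float)), scheme)


@dataclass
class ModelValidation:
    kind: str
    pred_cspc: np.ndarray
    r2_standard: float
    r2_printed: float
    rmse: float
    pred_levels: np.ndarray
    accuracy: float
    confusion: Dict[int, int]


@dataclass
class ValidationReport:
    split: SplitSpec
    models: Dict[str, ModelValidation]

    def best_by_r2(self) -> ModelValidation:
        return max(self.models.values(), key=lambda m: m.r2_standard)

    def best_by_accuracy(self) -> ModelValidation:
        return max(self.models.values(), key=lambda m: m.accuracy)

    def to_dict(self) -> dict:
        return {
            "split": {"n_train": self.split.n_train,
                      "n_valid": self.split.n_valid, "seed": self.split.seed},
            "models": {k: {
                "r2_standard": m.r2_standard,
                "r2_printed": m.r2_printed,
                "rmse": m.rmse,
                "level_accuracy": m.accuracy,
                "confusion": {str(d): c for d, c in m.confusion.items()},
            } for k, m in self.models.items()},
        }


def run_inversion(features: np.ndarray, cspc: np.ndarray,
                  scheme: GradingScheme,
                  split_spec: SplitSpec | None = None,
                  kinds: Sequence[str] = MODEL_KINDS,
                  seed: int = 0) -> ValidationReport:
    """Train every requested model on the train split and validate on the
    held-out split."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(cspc, dtype=float)
    n = X.shape[0]
    if split_spec is None:
        n_valid = max(1, round(n * 80 / 432))
        split_spec = SplitSpec(n_train=n - n_valid, n_valid=n_valid, seed=seed)
    tr, va = split(n, split_spec)
    true_levels = grade(y[va], scheme)
    results: Dict[str, ModelValidation] = {}
    for kind in kinds:
        model = train_model(ModelSpec(kind=kind), X[tr], y[tr], seed=seed)
        pred = model.predict(X[va])
        acc, conf = level_accuracy(true_levels, grade(pred, scheme))
        results[kind] = ModelValidation(
            kind=kind, pred_cspc=pred,
            r2_standard=r_squared(y[va], pred, "standard"),
            r2_printed=r_squared(y[va], pred, "printed"),
            rmse=rmse(y[va], pred),
            pred_levels=grade(pred, scheme),
            accuracy=acc, confusion=conf)
    return ValidationReport(split=split_spec, models=results)
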