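"""Registry of the ten benchmarked regressors with a uniform contract.

Every model is trained and applied through the same pipeline: optional
degree-2 polynomial expansion of the 24 raw readings (only the two sparse
linear models use it), feature-wise standardization fitted on the training
data, then the learner. ``predict`` accepts raw windows and applies the
fitted preprocessing itself, so callers never handle expansion or scaling.

The "paper" profile pins the published configuration: Lasso alpha by 5-fold
CV, 100 000-iteration caps for Lasso/SVR/MLP, 500 trees for the ensembles,
MLP hidden layers of 5 tanh units trained with ADAM, nu-SVR for the RBF
kernel, everything else at scikit-learn defaults. The "fast" profile keeps
the same model families but shrinks iteration caps and tree counts for
desk-scale grid runs. The dummy baseline (constant training-mean predictor)
is implemented natively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import NuSVR, LinearSVR
from sklearn.tree import DecisionTreeRegressor

from .windowing import expand_polynomial, standardize

MODEL_NAMES = (
    "dummy",
    "lasso",
    "linear_svr",
    "decision_tree",
    "knn",
    "rbf_svr",
    "mlp_1",
    "mlp_2",
    "random_forest",
    "gradient_boosting",
)

#: Models trained on the degree-2 polynomial expansion of the window.
POLYNOMIAL_MODELS = frozenset({"lasso", "linear_svr"})

PROFILES = ("paper", "fast")


@dataclass(frozen=True)
class ModelSpec:
    """Name + hyperparameters + seed for one registry entry."""

    name: str
    uses_polynomial_features: bool
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")
        if self.uses_polynomial_features != (self.name in POLYNOMIAL_MODELS):
            raise ValueError(
                "polynomial expansion is used exactly by "
                f"{sorted(POLYNOMIAL_MODELS)}"
            )

    def with_seed(self, seed: int) -> "ModelSpec":
        return ModelSpec(
            name=self.name,
            uses_polynomial_features=self.uses_polynomial_features,
            hyperparameters=dict(self.hyperparameters),
            seed=seed,
        )


def _profile_params(profile: str) -> dict[str, dict[str, Any]]:
    if profile == "paper":
        return {
            "dummy": {},
            "lasso": {"cv": 5, "max_iter": 100_000},
            "linear_svr": {"max_iter": 100_000},
            "decision_tree": {},
            "knn": {},
            "rbf_svr": {},
            "mlp_1": {
                "hidden_layer_sizes": (5,),
                "activation": "tanh",
                "solver": "adam",
                "max_iter": 100_000,
            },
            "mlp_2": {
                "hidden_layer_sizes": (5, 5),
                "activation": "tanh",
                "solver": "adam",
                "max_iter": 100_000,
            },
            "random_forest": {"n_estimators": 500},
            "gradient_boosting": {"n_estimators": 500},
        }
    if profile == "fast":
        # same families, reduced iteration caps / tree counts for grid runs
        return {
            "dummy": {},
            "lasso": {"cv": 5, "max_iter": 200, "alphas": 10},
            "linear_svr": {"max_iter": 2000},
            "decision_tree": {},
            "knn": {},
            "rbf_svr": {"max_iter": 2000},
            "mlp_1": {
                "hidden_layer_sizes": (5,),
                "activation": "tanh",
                "solver": "adam",
                "max_iter": 300,
                "learning_rate_init": 0.02,
            },
            "mlp_2": {
                "hidden_layer_sizes": (5, 5),
                "activation": "tanh",
                "solver": "adam",
                "max_iter": 300,
                "learning_rate_init": 0.02,
            },
            "random_forest": {"n_estimators": 25},
            "gradient_boosting": {"n_estimators": 50},
        }
    raise ValueError(f"unknown profile {profile!r}; choose from {PROFILES}")


def registry(seed: int = 0, profile: str = "paper") -> list[ModelSpec]:
    """The ten benchmarked model configurations, in canonical order."""
    params = _profile_params(profile)
    return [
        ModelSpec(
            name=name,
            uses_polynomial_features=name in POLYNOMIAL_MODELS,
            hyperparameters=params[name],
            seed=seed,
        )
        for name in MODEL_NAMES
    ]


def get_spec(name: str, seed: int = 0, profile: str = "paper") -> ModelSpec:
    for spec in registry(seed=seed, profile=profile):
        if spec.name == name:
            return spec
    raise ValueError(f"unknown model {name!r}")


def _build_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    name = spec.name
    if name == "lasso":
        return LassoCV(random_state=spec.seed, **hp)
    if name == "linear_svr":
        return LinearSVR(random_state=spec.seed, **hp)
    if name == "decision_tree":
        return DecisionTreeRegressor(random_state=spec.seed, **hp)
    if name == "knn":
        return KNeighborsRegressor(**hp)
    if name == "rbf_svr":
        return NuSVR(**hp)
    if name in ("mlp_1", "mlp_2"):
        return MLPRegressor(random_state=spec.seed, **hp)
    if name == "random_forest":
        return RandomForestRegressor(random_state=spec.seed, **hp)
    if name == "gradient_boosting":
        return GradientBoostingRegressor(random_state=spec.seed, **hp)
    raise ValueError(f"no estimator for {name!r}")


@dataclass
class TrainedModel:
    """A fitted model bundled with its fitted preprocessing.

    ``predict`` takes raw windows (same column count as training input),
    expands and standardizes them with the train-fitted parameters, and
    returns finite mg/dl predictions.
    """

    spec: ModelSpec
    n_features_in: int
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    estimator: Any = None
    constant: float | None = None  # dummy: the training-mean prediction

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in:
            raise ValueError(
                f"expected matrix with {self.n_features_in} columns, "
                f"got shape {X.shape}"
            )
        if self.constant is not None:
            return np.full(len(X), self.constant)
        Xt = expand_polynomial(X) if self.spec.uses_polynomial_features else X
        Xt = (Xt - self.means) / self.sds
        pred = np.asarray(self.estimator.predict(Xt), dtype=float)
        if not np.all(np.isfinite(pred)):
            raise RuntimeError(f"model {self.spec.name!r} produced non-finite predictions")
        return pred


def train(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> TrainedModel:
    """Fit one registry model on raw windows and mg/dl targets."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or len(X) != len(y) or len(y) < 1:
        raise ValueError("X must be 2-D with one target per row")
    if spec.name == "dummy":
        return TrainedModel(
            spec=spec, n_features_in=X.shape[1], constant=float(np.mean(y))
        )
    Xt = expand_polynomial(X) if spec.uses_polynomial_features else X
    Xs, means, sds = standardize(Xt, Xt)
    est = _build_estimator(spec)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(Xs, y)
    except Exception as exc:  # surface spec name with the cause
        raise RuntimeError(f"training {spec.name!r} failed: {exc}") from exc
    return TrainedModel(
        spec=spec,
        n_features_in=X.shape[1],
        means=means,
        sds=sds,
        estimator=est,
    )
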