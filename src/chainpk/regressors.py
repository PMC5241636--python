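"""Uniform fit/predict contract over the five base learners.

Every learner maps a plain feature matrix to a single target vector:

* ``LR``   -- ordinary least squares via a minimum-norm pseudo-inverse solve,
  so rank-deficient designs (the orthogonal design plus augmented, collinear
  chain features) are handled without ridge bias.
* ``PR``   -- polynomial regression: least squares on polynomial features of
  total degree <= ``degree`` (default 2, with interaction terms).
* ``SVR``  -- epsilon-insensitive support vector regression, linear kernel by
  default; features are z-scored on the training data internally.
* ``ANN``  -- a multilayer perceptron with one hidden layer by default,
  seeded weight initialisation, L-BFGS training; standardized inputs.
* ``PLSR`` -- partial least squares with min(p, 3) components by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import PolynomialFeatures
from sklearn.svm import SVR as _SKSVR

KINDS = ("LR", "PR", "SVR", "ANN", "PLSR")


class InsufficientDataError(ValueError):
    """Too few samples to fit the requested model."""


class DegenerateDesignError(ValueError):
    """The design matrix has no usable variation (e.g. constant X for PLSR)."""


@dataclass(frozen=True)
class RegressorSpec:
    """Declarative description of one base learner.

    ``standardize=None`` resolves to True for SVR and ANN (whose losses are
    scale-sensitive) and False for the linear-algebraic learners.
    """

    kind: str = "LR"
    degree: int = 2
    kernel: str = "linear"
    cost: float = 1.0
    epsilon: float = 0.1
    hidden_layers: int = 1
    hidden_units: int = 8
    n_components: int | None = None
    standardize: bool | None = None
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown regressor kind {self.kind!r}; expected one of {KINDS}")
        if self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        if self.hidden_layers < 1:
            raise ValueError("ANN needs at least one hidden layer")

    @property
    def resolved_standardize(self) -> bool:
        if self.standardize is None:
            return self.kind in ("SVR", "ANN")
        return self.standardize

    def to_dict(self) -> dict[str, Any]:
        d = {
            "kind": self.kind,
            "degree": self.degree,
            "kernel": self.kernel,
            "cost": self.cost,
            "epsilon": self.epsilon,
            "hidden_layers": self.hidden_layers,
            "hidden_units": self.hidden_units,
            "n_components": self.n_components,
            "standardize": self.standardize,
            "max_iter": self.max_iter,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RegressorSpec":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown regressor options: {sorted(extra)}")
        return cls(**d)


class _Standardizer:
    """Per-column z-scoring fitted on the training fold only."""

    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0.0] = 1.0  # constant columns pass through centred
        self.sd = sd

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


class _OLS:
    """Least squares with intercept via numpy's SVD-based minimum-norm solve."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        A = np.column_stack([np.ones(len(X)), X])
        self.beta, *_ = np.linalg.lstsq(A, y, rcond=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        A = np.column_stack([np.ones(len(X)), X])
        return A @ self.beta


@dataclass
class TrainedModel:
    """A fitted base learner; ``predict`` rejects mismatched feature counts."""

    spec: RegressorSpec
    n_features: int
    _impl: Any
    _scaler: _Standardizer | None = None
    _poly: PolynomialFeatures | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected a 2-D matrix with {self.n_features} feature columns, "
                f"got shape {X.shape}"
            )
        if self._poly is not None:
            X = self._poly.transform(X)
        if self._scaler is not None:
            X = self._scaler.transform(X)
        yhat = self._impl.predict(X)
        return np.asarray(yhat, dtype=float).reshape(-1)


def fit(spec: RegressorSpec, X: np.ndarray, y: np.ndarray, seed: int = 0) -> TrainedModel:
    """Fit one base learner. Deterministic given ``(spec, X, y, seed)``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D, got shape {X.shape}")
    if len(X) != len(y):
        raise ValueError(f"X has {len(X)} rows but y has {len(y)} values")
    if len(X) < 2:
        raise InsufficientDataError(f"need at least 2 samples, got {len(X)}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite (no NaN/inf)")

    n_features = X.shape[1]
    poly = None
    if spec.kind == "PR":
        poly = PolynomialFeatures(degree=spec.degree, include_bias=False)
        X = poly.fit_transform(X)

    scaler = None
    if spec.resolved_standardize:
        scaler = _Standardizer(X)
        X = scaler.transform(X)

    if spec.kind in ("LR", "PR"):
        impl = _OLS(X, y)
    elif spec.kind == "SVR":
        impl = _SKSVR(kernel=spec.kernel, C=spec.cost, epsilon=spec.epsilon)
        impl.fit(X, y)
    elif spec.kind == "ANN":
        impl = MLPRegressor(
            hidden_layer_sizes=(spec.hidden_units,) * spec.hidden_layers,
            solver="lbfgs",
            max_iter=spec.max_iter,
            random_state=int(seed) % (2**31),
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("always", category=ConvergenceWarning)
            impl.fit(X, y)
    elif spec.kind == "PLSR":
        if np.allclose(X.std(axis=0), 0.0):
            raise DegenerateDesignError("PLSR requires a non-constant design matrix")
        n_comp = spec.n_components if spec.n_components is not None else 3
        n_comp = max(1, min(n_comp, X.shape[1], len(X) - 1))
        impl = _PLSWrapper(n_comp)
        impl.fit(X, y)
    else:  # pragma: no cover - guarded by RegressorSpec
        raise ValueError(spec.kind)

    return TrainedModel(spec=spec, n_features=n_features, _impl=impl,
                        _scaler=scaler, _poly=poly)


class _PLSWrapper:
    """PLSRegression returning flat prediction vectors."""

    def __init__(self, n_components: int):
        self._pls = PLSRegression(n_components=n_components, scale=True)

    def fit(self, X: np.ndarray, y: np.ndarray) -> None:
        with warnings.catch_warnings():
            # zero-variance augmented columns are centred away by PLS itself
            warnings.filterwarnings("ignore", message=".*y residual is constant.*")
            self._pls.fit(X, y)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._pls.predict(X).reshape(-1)


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Module-level alias for :meth:`TrainedModel.predict`."""
    return model.predict(np.asarray(X, dtype=float))
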