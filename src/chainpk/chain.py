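"""Chained multi-target regression over a concentration time series.

The framework fits one single-output model per time point, in time order.
The first target is always modelled from the herb proportions alone.  From
the second target onward the feature set may be augmented with a previously
predicted target:

* ``ST``  -- no augmentation: independent per-time-point regression.
* ``MT``  -- augment with the chain's prediction of the immediately
  preceding time point (optionally the last ``n_augment`` points).
* ``RMT`` -- augment with one uniformly drawn *other* target (seeded).

Augmentation always uses the framework's own predictions, never measured
target values: at training time the in-sample predictions of the already
fitted part of the chain, at prediction time the chain's predictions on the
new samples.  Measured values are unknown for new samples by definition, so
using them would leak targets.  (For study purposes,
``use_true_targets=True`` switches the *training-time* augmentation to the
measured values.)

An RMT draw may point at a target later in the chain; its augmentation
value then comes from an auxiliary single-target model of that time point
fitted on the plain features, since the chain's own prediction of a later
target does not exist yet when the earlier one is being predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import regressors
from .datamodel import ConcentrationDataset, PredictionMatrix
from .regressors import InsufficientDataError, RegressorSpec, TrainedModel


class ChainMode(str, Enum):
    ST = "ST"
    MT = "MT"
    RMT = "RMT"


class NotFittedError(RuntimeError):
    """predict_chain was called on an incomplete chain model."""


@dataclass
class ChainModel:
    """An ordered sequence of fitted per-target models plus the augmentation plan.

    ``augment_index[j]`` lists the (0-based) target indices whose predictions are
    appended to the features when modelling target ``j``; it is empty for the
    first target and for every target under ST.
    """

    mode: ChainMode
    spec: RegressorSpec
    models: list[TrainedModel]
    augment_index: list[tuple[int, ...]]
    seed: int
    n_targets: int
    helpers: dict[int, TrainedModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.models) != self.n_targets or len(self.augment_index) != self.n_targets:
            raise NotFittedError("chain model is incomplete")


def draw_rmt_plan(n_targets: int, seed: int) -> list[tuple[int, ...]]:
    """Seeded RMT augmentation plan: for each target j >= 1 one uniform draw
    from the other targets; the first target is never augmented."""
    rng = np.random.default_rng(seed)
    plan: list[tuple[int, ...]] = [()]
    for j in range(1, n_targets):
        choices = [k for k in range(n_targets) if k != j]
        plan.append((int(rng.choice(choices)),))
    return plan


def _plan(mode: ChainMode, n_targets: int, seed: int, n_augment: int) -> list[tuple[int, ...]]:
    if mode == ChainMode.ST:
        return [() for _ in range(n_targets)]
    if mode == ChainMode.MT:
        return [tuple(range(max(0, j - n_augment), j)) for j in range(n_targets)]
    if mode == ChainMode.RMT:
        return draw_rmt_plan(n_targets, seed)
    raise ValueError(mode)


def fit_chain(
    spec: RegressorSpec,
    data: ConcentrationDataset,
    mode: ChainMode | str,
    seed: int = 0,
    n_augment: int = 1,
    use_true_targets: bool = False,
) -> ChainModel:
    """Fit the per-target chain on one compound's dataset.

    ``n_augment`` (MT only) appends the last ``n_augment`` predicted targets
    instead of just the previous one.
    """
    mode = ChainMode(mode)
    X, Y = data.X, data.Y
    m, n = Y.shape
    if m < 2:
        raise InsufficientDataError(f"need at least 2 samples to fit a chain, got {m}")
    if n_augment < 1:
        raise ValueError("n_augment must be >= 1")

    plan = _plan(mode, n, seed, n_augment)
    models: list[TrainedModel] = []
    helpers: dict[int, TrainedModel] = {}
    insample = np.empty((m, n))

    def _train_column(k: int, j: int) -> np.ndarray:
        if use_true_targets:
            return Y[:, k]
        if k < j:
            return insample[:, k]
        # forward reference (RMT): auxiliary single-target model on X alone
        if k not in helpers:
            helpers[k] = regressors.fit(spec, X, Y[:, k], seed=seed + 1000 + k)
        return helpers[k].predict(X)

    for j in range(n):
        cols = [_train_column(k, j) for k in plan[j]]
        Xaug = np.column_stack([X] + cols) if cols else X
        model = regressors.fit(spec, Xaug, Y[:, j], seed=seed + j)
        models.append(model)
        insample[:, j] = model.predict(Xaug)

    return ChainModel(mode=mode, spec=spec, models=models, augment_index=plan,
                      seed=seed, n_targets=n, helpers=helpers)


def predict_chain(model: ChainModel, Xnew: np.ndarray) -> PredictionMatrix:
    """Predict all targets for new samples, in time order.

    Each augmented feature is the chain's own prediction (or, for an RMT
    forward reference, the auxiliary single-target model's prediction) on
    ``Xnew`` -- never a measured value.
    """
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.ndim != 2:
        raise ValueError(f"Xnew must be 2-D, got shape {Xnew.shape}")
    k = Xnew.shape[0]
    preds = np.empty((k, model.n_targets))

    def _pred_column(t: int, j: int) -> np.ndarray:
        if t < j:
            return preds[:, t]
        if t not in model.helpers:
            raise NotFittedError(
                f"no auxiliary model for forward-referenced target {t}"
            )
        return model.helpers[t].predict(Xnew)

    for j in range(model.n_targets):
        cols = [_pred_column(t, j) for t in model.augment_index[j]]
        Xaug = np.column_stack([Xnew] + cols) if cols else Xnew
        preds[:, j] = model.models[j].predict(Xaug)

    return PredictionMatrix(preds)
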