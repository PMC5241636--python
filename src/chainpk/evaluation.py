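"""Leave-one-out evaluation, error measures, and improvement tables.

Per-target errors over an l x n matrix of pooled held-out predictions:

    RMSE_j = sqrt( (1/l) sum_i (yhat_ij - y_ij)^2 )
    MAE_j  = (1/l) sum_i |yhat_ij - y_ij|
    MAPE_j = (1/l) sum_i |yhat_ij - y_ij| / |y_ij|        (fractional scale)

The "whole" value of each measure is the mean of its n per-target values and
is reported with the standard deviation (sample SD, n-1 denominator) across
targets.  Improvement percentages compare two whole errors:

    imp = (err_ref - err_new) / err_ref * 100

so a positive value means the new configuration (typically MT) is better.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chain import ChainMode, fit_chain, predict_chain
from .datamodel import ConcentrationDataset
from .regressors import RegressorSpec


class UndefinedMAPEError(ValueError):
    """MAPE was requested but a true value is zero; no silent epsilon is applied."""


@dataclass
class ErrorReport:
    """Per-target and whole RMSE/MAE/MAPE with across-target dispersion.

    ``mape`` fields are ``None`` when MAPE was not computed (zero true values
    present and MAPE not forced)."""

    per_target_rmse: np.ndarray
    per_target_mae: np.ndarray
    per_target_mape: np.ndarray | None
    rmse: float
    mae: float
    mape: float | None
    rmse_sd: float
    mae_sd: float
    mape_sd: float | None
    l: int
    n: int

    def whole(self, measure: str) -> float:
        value = {"RMSE": self.rmse, "MAE": self.mae, "MAPE": self.mape}[measure]
        if value is None:
            raise UndefinedMAPEError("MAPE was not computed for this report")
        return value


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def error_measures(Y: np.ndarray, Yhat: np.ndarray, include_mape: bool | str = True) -> ErrorReport:
    """Compute the three error measures from true and predicted matrices.

    ``include_mape`` may be True (raise :class:`UndefinedMAPEError` on zero
    true values), False, or ``"auto"`` (compute MAPE only when every true
    value is nonzero).
    """
    Y = np.asarray(Y, dtype=float)
    Yhat = getattr(Yhat, "Yhat", Yhat)
    Yhat = np.asarray(Yhat, dtype=float)
    if Y.shape != Yhat.shape or Y.ndim != 2:
        raise ValueError(f"shape mismatch: true {Y.shape} vs predicted {Yhat.shape}")
    l, n = Y.shape
    diff = Yhat - Y
    rmse_j = np.sqrt(np.mean(diff**2, axis=0))
    mae_j = np.mean(np.abs(diff), axis=0)

    mape_j = None
    if include_mape == "auto":
        include_mape = bool(np.all(Y != 0))
    if include_mape:
        if np.any(Y == 0):
            raise UndefinedMAPEError(
                "MAPE is undefined: at least one true value is zero"
            )
        mape_j = np.mean(np.abs(diff) / np.abs(Y), axis=0)

    return ErrorReport(
        per_target_rmse=rmse_j,
        per_target_mae=mae_j,
        per_target_mape=mape_j,
        rmse=float(np.mean(rmse_j)),
        mae=float(np.mean(mae_j)),
        mape=None if mape_j is None else float(np.mean(mape_j)),
        rmse_sd=_sd(rmse_j),
        mae_sd=_sd(mae_j),
        mape_sd=None if mape_j is None else _sd(mape_j),
        l=l,
        n=n,
    )


def loocv(
    data: ConcentrationDataset,
    spec: RegressorSpec,
    mode: ChainMode | str,
    seed: int = 0,
    include_mape: bool | str = "auto",
    n_augment: int = 1,
    use_true_targets: bool = False,
) -> ErrorReport:
    """Leave-one-out cross-validation of one (dataset, learner, mode) cell.

    Each of the m folds refits the chain on the other m - 1 samples and
    predicts the held-out one; the m held-out rows are pooled and scored.
    Under RMT a fresh augmentation plan is drawn per fold from
    ``seed + fold_index``, so the randomness varies across folds but is
    reproducible.
    """
    m = data.n_samples
    if m < 3:
        raise ValueError(f"LOOCV needs at least 3 samples, got {m}")
    Yhat = np.empty_like(data.Y)
    for fold in range(m):
        keep = np.arange(m) != fold
        train = ConcentrationDataset(
            compound=data.compound,
            X=data.X[keep],
            Y=data.Y[keep],
            grid=data.grid,
            group_ids=tuple(g for g, k in zip(data.group_ids, keep) if k),
        )
        try:
            model = fit_chain(spec, train, mode, seed=seed + fold,
                              n_augment=n_augment, use_true_targets=use_true_targets)
            Yhat[fold] = predict_chain(model, data.X[fold:fold + 1]).Yhat[0]
        except Exception as exc:
            raise type(exc)(f"fold {fold}: {exc}") from exc
    return error_measures(data.Y, Yhat, include_mape=include_mape)


def improvement(err_ref: float, err_new: float) -> float:
    """Percentage error reduction of ``err_new`` relative to ``err_ref``.

    Positive means the new configuration improves on the reference."""
    if err_ref <= 0:
        raise ValueError(f"reference error must be positive, got {err_ref}")
    return (err_ref - err_new) / err_ref * 100.0


_MEASURES = ("RMSE", "MAE", "MAPE")
#: CSV rounding: two decimals for RMSE/MAE and improvements, three for MAPE.
_DECIMALS = {"RMSE": 2, "MAE": 2, "MAPE": 3}


def comparison_report(
    datasets: Mapping[str, ConcentrationDataset],
    specs: Sequence[RegressorSpec],
    modes: Sequence[ChainMode | str] = (ChainMode.ST, ChainMode.MT, ChainMode.RMT),
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LOOCV every (dataset, learner, mode) cell and tabulate errors and
    MT-vs-ST / MT-vs-RMT improvement percentages.

    Returns ``(errors, improvements)`` data frames; when ``out_dir`` is given
    they are also written as ``errors.csv`` and ``improvements.csv`` with the
    standard rounding.  MAPE rows appear only for datasets whose true values
    are all nonzero.
    """
    if not datasets or not specs:
        raise ValueError("need at least one dataset and one regressor spec")
    modes = [ChainMode(m) for m in modes]
    reports: dict[tuple[str, str, str], ErrorReport] = {}
    err_rows = []
    for name, data in datasets.items():
        for spec in specs:
            for mode in modes:
                rep = loocv(data, spec, mode, seed=seed)
                reports[(name, spec.kind, mode.value)] = rep
                for meas in _MEASURES:
                    if meas == "MAPE" and rep.mape is None:
                        continue
                    per = {
                        "RMSE": rep.per_target_rmse,
                        "MAE": rep.per_target_mae,
                        "MAPE": rep.per_target_mape,
                    }[meas]
                    sd = {"RMSE": rep.rmse_sd, "MAE": rep.mae_sd, "MAPE": rep.mape_sd}[meas]
                    row = {
                        "dataset": name,
                        "spec": spec.kind,
                        "mode": mode.value,
                        "measure": meas,
                        "whole": rep.whole(meas),
                        "sd": sd,
                    }
                    for col, v in zip(data.grid.column_names, per):
                        row[col] = v
                    err_rows.append(row)
    errors = pd.DataFrame(err_rows)

    imp_rows = []
    if ChainMode.MT in modes:
        for name in datasets:
            for spec in specs:
                mt = reports[(name, spec.kind, "MT")]
                for vs in ("ST", "RMT"):
                    if ChainMode(vs) not in modes:
                        continue
                    ref = reports[(name, spec.kind, vs)]
                    for meas in _MEASURES:
                        if meas == "MAPE" and (mt.mape is None or ref.mape is None):
                            continue
                        imp_rows.append({
                            "dataset": name,
                            "spec": spec.kind,
                            "measure": meas,
                            "vs": vs,
                            "percent": improvement(ref.whole(meas), mt.whole(meas)),
                        })
    improvements = pd.DataFrame(imp_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        err_out = errors.copy()
        value_cols = [c for c in err_out.columns if c not in ("dataset", "spec", "mode", "measure")]
        for meas, dec in _DECIMALS.items():
            mask = err_out["measure"] == meas
            err_out.loc[mask, value_cols] = err_out.loc[mask, value_cols].round(dec)
        err_out.to_csv(out_dir / "errors.csv", index=False)
        imp_out = improvements.copy()
        if len(imp_out):
            imp_out["percent"] = imp_out["percent"].round(2)
        imp_out.to_csv(out_dir / "improvements.csv", index=False)

    return errors, improvements
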