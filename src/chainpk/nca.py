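"""Non-compartmental analysis of a single concentration-time curve.

Computes the eight standard indices reported for each sample of the
compatibility study: Lambda_z (terminal first-order elimination constant),
Tlag (absorption delay), Tmax and Cmax (time and value of the peak),
AUClast (linear-trapezoid area to the last observation), AUCINF_obs
(extrapolated to infinity as AUClast + C_last / Lambda_z), and the apparent
volume and clearance Vz_F_obs = dose / (Lambda_z * AUCINF_obs) and
Cl_F_obs = dose / AUCINF_obs, which satisfy Vz_F_obs * Lambda_z = Cl_F_obs
exactly.

Lambda_z comes from a least-squares line on log concentration versus time
over selected terminal points: by default the last three positive
concentrations strictly after Tmax; optionally the suffix (length >= 3)
maximising adjusted R^2, the common pharmacokinetics convention.  When fewer
than three usable terminal points exist, Lambda_z and its dependants are
reported as NaN and flagged, never silently zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ConcentrationDataset, TimeGrid

NCA_COLUMNS = (
    "Lambda_z", "Tlag", "Tmax", "Cmax",
    "AUClast", "AUCINF_obs", "Vz_F_obs", "Cl_F_obs",
)


@dataclass(frozen=True)
class NCAResult:
    Lambda_z: float
    Tlag: float
    Tmax: float
    Cmax: float
    AUClast: float
    AUCINF_obs: float
    Vz_F_obs: float
    Cl_F_obs: float
    lambda_points: tuple[int, ...]
    r_squared: float

    @property
    def lambda_defined(self) -> bool:
        return not math.isnan(self.Lambda_z)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in NCA_COLUMNS}


def _terminal_fit(times: np.ndarray, conc: np.ndarray, idx: np.ndarray) -> tuple[float, float]:
    """Slope magnitude and R^2 of ln(conc) vs time over the given indices."""
    t = times[idx]
    logc = np.log(conc[idx])
    A = np.column_stack([np.ones(len(t)), t])
    beta, *_ = np.linalg.lstsq(A, logc, rcond=None)
    fitted = A @ beta
    ss_res = float(np.sum((logc - fitted) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return -float(beta[1]), r2


def _select_terminal(times, conc, tmax_idx, method: str) -> np.ndarray | None:
    candidates = np.flatnonzero((conc > 0) & (np.arange(len(conc)) > tmax_idx))
    if len(candidates) < 3:
        return None
    if method == "last3":
        return candidates[-3:]
    if method == "best_r2":
        best, best_adj = None, -np.inf
        for start in range(len(candidates) - 2):
            idx = candidates[start:]
            k = len(idx)
            _, r2 = _terminal_fit(times, conc, idx)
            adj = 1 - (1 - r2) * (k - 1) / (k - 2)
            if adj > best_adj:
                best, best_adj = idx, adj
        return best
    raise ValueError(f"unknown terminal selection method {method!r}")


def nca(
    times: TimeGrid | np.ndarray,
    conc: np.ndarray,
    dose: float,
    terminal: str = "last3",
) -> NCAResult:
    """Non-compartmental indices for one curve sampled at ``times``."""
    t = times.asarray() if isinstance(times, TimeGrid) else np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError(f"times {t.shape} and concentrations {c.shape} must match 1-D")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")

    # peak: earliest time on ties
    tmax_idx = int(np.argmax(c))
    cmax = float(c[tmax_idx])
    tmax = float(t[tmax_idx])

    # delay: last sampling time still at zero before the first positive value
    pos = np.flatnonzero(c > 0)
    if len(pos) == 0 or pos[0] == 0:
        tlag = 0.0
    else:
        tlag = float(t[pos[0] - 1])

    auc_last = float(np.trapezoid(c, t))

    idx = _select_terminal(t, c, tmax_idx, terminal)
    if idx is None:
        lam, r2 = float("nan"), float("nan")
        auc_inf = vz = cl = float("nan")
        points: tuple[int, ...] = ()
    else:
        lam, r2 = _terminal_fit(t, c, idx)
        points = tuple(int(i) for i in idx)
        c_last = float(c[-1])
        auc_inf = auc_last + c_last / lam if lam > 0 else float("nan")
        if math.isnan(auc_inf) or auc_inf <= 0:
            auc_inf = vz = cl = float("nan")
        else:
            vz = dose / (lam * auc_inf)
            cl = vz * lam  # so Vz_F_obs * Lambda_z == Cl_F_obs holds exactly

    return NCAResult(
        Lambda_z=lam, Tlag=tlag, Tmax=tmax, Cmax=cmax,
        AUClast=auc_last, AUCINF_obs=auc_inf, Vz_F_obs=vz, Cl_F_obs=cl,
        lambda_points=points, r_squared=r2,
    )


def batch_nca(
    dataset: ConcentrationDataset,
    doses: np.ndarray | float,
    terminal: str = "last3",
) -> pd.DataFrame:
    """One NCA row per sample of a dataset.

    ``doses`` may be a scalar (same administered amount for every sample) or a
    per-sample vector.  Samples with an undefined terminal phase keep their
    row, with NaN in Lambda_z and its dependants and ``lambda_defined`` False.
    """
    m = dataset.n_samples
    doses = np.broadcast_to(np.asarray(doses, dtype=float), (m,))
    rows = []
    for i in range(m):
        res = nca(dataset.grid, dataset.Y[i], doses[i], terminal=terminal)
        row = {"sample": i, "group": dataset.group_ids[i], **res.as_dict(),
               "lambda_defined": res.lambda_defined, "r_squared": res.r_squared}
        rows.append(row)
    return pd.DataFrame(rows)
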