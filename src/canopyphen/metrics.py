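"""Forecast-quality metrics and residual diagnostics.

MSE, RMSE, MAE and MAPE over paired true/predicted sequences, plus residual
and normal-QQ arrays for diagnostic plots.  MAE takes the absolute error (the
signed mean error is exposed separately as ``bias``); MAPE is reported in
percent and is undefined (NaN) whenever a true value is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class EvalMetrics:
    mse: float
    rmse: float
    mae: float
    mape: float  # percent; NaN when undefined
    bias: float  # signed mean error, mean(y_true - y_pred)
    n: int


def evaluate(y_true, y_pred) -> EvalMetrics:
    y_true = np.asarray(y_true, dtype=float).reshape(-1)
    y_pred = np.asarray(y_pred, dtype=float).reshape(-1)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size < 1:
        raise ValueError("need at least one pair")
    err = y_true - y_pred
    mse = float(np.mean(err**2))
    if np.any(y_true == 0):
        mape = float("nan")
    else:
        with np.errstate(over="ignore"):
            mape = float(100.0 * np.mean(np.abs(err / y_true)))
    return EvalMetrics(mse=mse, rmse=float(np.sqrt(mse)),
                       mae=float(np.mean(np.abs(err))), mape=mape,
                       bias=float(np.mean(err)), n=y_true.size)


def residuals(y_true, y_pred) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=float).reshape(-1)
    y_pred = np.asarray(y_pred, dtype=float).reshape(-1)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return y_true - y_pred


def qq_points(res) -> tuple[np.ndarray, np.ndarray]:
    """Normal QQ pairs: standard-normal quantiles at plotting positions
    (i - 0.5)/n against ordered standardized residuals."""
    res = np.asarray(res, dtype=float).reshape(-1)
    n = res.size
    if n < 3:
        raise ValueError("QQ diagnostics need at least 3 residuals")
    sd = res.std(ddof=1)
    std_res = (res - res.mean()) / sd if sd > 0 else res - res.mean()
    theoretical = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return theoretical, np.sort(std_res)
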