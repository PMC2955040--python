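"""Goodness-of-fit statistics and model ranking.

Four accuracy measures are computed per fitted model:

* ``AIC = n*ln(2*pi*SSE/n) + n + 2k`` — the Gaussian-likelihood Akaike
  information criterion with ``k`` counting mean-function parameters only
  (the error variance is profiled out and contributes the constant terms).
* ``RMS = SSE/(n-k)`` — residual mean square.
* ``R^2 = 1 - SSE/SST``.
* ``MARE = mean(|obs - pred| / obs)`` — mean absolute relative error, with
  the observed value in the denominator.

The best model is the one with the lowest AIC; exact AIC ties break toward
fewer parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .fitting import FitResult
from .models import GrowthSeries, ModelFamily, predict

__all__ = ["mare", "rms", "aic", "r_squared", "rank_models", "order_rows", "ComparisonReport"]


def mare(observed, predicted) -> float:
    """Mean absolute relative error, denominator = observed value."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise InputError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if np.any(obs == 0):
        raise InputError("MARE undefined: observed value equal to zero")
    return float(np.mean(np.abs(obs - pred) / np.abs(obs)))


def rms(sse: float, n: int, k: int) -> float:
    """Residual mean square SSE/(n-k)."""
    if n <= k:
        raise InputError(f"need n > k for the residual mean square, got n={n}, k={k}")
    if sse < 0:
        raise InputError("SSE must be non-negative")
    return sse / (n - k)


def aic(sse: float, n: int, k: int) -> float:
    """Gaussian AIC: n*ln(2*pi*SSE/n) + n + 2k. SSE=0 maps to -inf."""
    if n <= 0:
        raise InputError("n must be positive")
    if sse < 0:
        raise InputError("SSE must be non-negative")
    if sse == 0:
        return -np.inf
    return float(n * np.log(2.0 * np.pi * sse / n) + n + 2 * k)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SSE/SST."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise InputError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if len(obs) < 2 or np.ptp(obs) == 0:
        raise InputError("R^2 undefined for constant or <2-point observations")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


@dataclass(frozen=True)
class ComparisonReport:
    """Per-model accuracy table, sorted best (lowest AIC) first."""

    table: pd.DataFrame
    best_model: ModelFamily

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self) -> str:
        return self.table.to_json(orient="records", indent=2)


def _check_same_series(fit: FitResult, series: GrowthSeries) -> None:
    if fit.n_obs != len(series):
        raise InputError(
            f"{fit.family.name} fit has n={fit.n_obs} but the series has {len(series)}"
        )
    recomputed = series.weights - np.asarray(predict(fit.params, series.times))
    if not np.allclose(recomputed, fit.residuals, atol=1e-6):
        raise InputError(
            f"{fit.family.name} fit residuals do not match this series; "
            "was it fitted to different data?"
        )


def order_rows(rows: Sequence[dict]) -> list[dict]:
    """Ranking rule: ascending AIC; exact ties break toward fewer parameters."""
    return sorted(rows, key=lambda r: (r["aic"], r["k"]))


def rank_models(fits: Sequence[FitResult], series: GrowthSeries) -> ComparisonReport:
    """Rank fitted models on one series by AIC (ties: fewer parameters)."""
    if len(fits) < 2:
        raise InputError("need at least two fits to rank")
    rows = []
    for f in fits:
        _check_same_series(f, series)
        pred = series.weights - f.residuals
        rows.append(
            {
                "family": f.family.name,
                "k": f.n_params,
                "sse": f.sse,
                "aic": aic(f.sse, f.n_obs, f.n_params),
                "rms": rms(f.sse, f.n_obs, f.n_params),
                "r2": r_squared(series.weights, pred),
                "mare": mare(series.weights, pred),
            }
        )
    table = pd.DataFrame(order_rows(rows))
    best = ModelFamily[table.iloc[0]["family"]]
    return ComparisonReport(table=table, best_model=best)
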