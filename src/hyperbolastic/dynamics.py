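"""Growth dynamics: locating the maximum growth rate and profiling P', P''.

The time of maximum growth rate (the inflection point of the growth curve)
and the rate attained there are the headline kinetic summaries: a treatment
that delays the inflection keeps the tumor in its slow-growth phase longer.
The maximum is found by a coarse grid scan (0.1-day step) followed by
bounded scalar refinement, which is robust to the flat ridge the
hyperbolastic type-III curve can show near its peak. On a plateau the
earliest time is reported; a maximum sitting on the search-window edge is
flagged ``at_boundary`` rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .exceptions import InputError
from .fitting import FitResult
from .models import AnchoredParams, ModelFamily, acceleration, rate

__all__ = ["RateMax", "DynamicsSummary", "max_growth_rate", "profiles", "compare_arms"]

_GRID_STEP = 0.1


class RateMax(NamedTuple):
    t_max: float
    v_max: float
    at_boundary: bool


@dataclass(frozen=True)
class DynamicsSummary:
    """Velocity/acceleration profiles plus the rate maximum for one curve."""

    family: ModelFamily
    t_max: float
    v_max: float
    at_boundary: bool
    times: np.ndarray
    rates: np.ndarray
    accelerations: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "rate": self.rates, "acceleration": self.accelerations}
        )

    def to_dict(self) -> dict:
        return {
            "family": self.family.value,
            "t_max": self.t_max,
            "v_max": self.v_max,
            "at_boundary": self.at_boundary,
        }


def max_growth_rate(
    params: AnchoredParams,
    search_window: tuple[float, float],
    step: float = _GRID_STEP,
) -> RateMax:
    """Maximize dP/dt over ``search_window`` = (lo, hi) in days.

    Grid scan at ``step`` days, then bounded refinement of the bracketing
    interval to ~1e-8 days. A monotone rate (argmax on the window edge, or a
    completely flat profile) sets ``at_boundary`` instead of raising.
    """
    lo, hi = float(search_window[0]), float(search_window[1])
    if not hi > lo:
        raise InputError(f"empty search window ({lo}, {hi})")
    gamma = params.values.get("gamma")
    if gamma is not None and gamma < 1.0 and lo <= 0.0:
        lo = min(step, hi / 2.0)  # rate singular at t=0 for gamma < 1
    grid = np.arange(lo, hi + step / 2.0, step)
    grid[-1] = min(grid[-1], hi)
    vals = np.asarray(rate(params, grid), dtype=float)
    if np.ptp(vals) == 0.0:
        return RateMax(t_max=lo, v_max=float(vals[0]), at_boundary=True)
    i = int(np.argmax(vals))  # first index on a plateau -> earliest time
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    if a == b:
        return RateMax(t_max=float(grid[i]), v_max=float(vals[i]), at_boundary=True)
    res = minimize_scalar(
        lambda t: -float(rate(params, t)),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-8},
    )
    t_star, v_star = float(res.x), float(-res.fun)
    if v_star < vals[i]:
        t_star, v_star = float(grid[i]), float(vals[i])
    boundary = i == 0 or i == len(grid) - 1
    return RateMax(t_max=t_star, v_max=v_star, at_boundary=boundary)


def profiles(
    params: AnchoredParams,
    t_grid,
    search_window: tuple[float, float] | None = None,
) -> DynamicsSummary:
    """Rate and acceleration on ``t_grid`` plus the rate maximum.

    The search window defaults to the grid's own span.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if search_window is None:
        search_window = (float(t_grid[0]), float(t_grid[-1]))
    peak = max_growth_rate(params, search_window)
    return DynamicsSummary(
        family=params.family,
        t_max=peak.t_max,
        v_max=peak.v_max,
        at_boundary=peak.at_boundary,
        times=t_grid,
        rates=np.asarray(rate(params, t_grid), dtype=float),
        accelerations=np.asarray(acceleration(params, t_grid), dtype=float),
    )


def default_window(fit: FitResult, max_time: float) -> tuple[float, float]:
    """Search window [t0, 1.5 * last observation]: published peak times can
    sit near the end of the observation range (Gompertz overshoots it)."""
    return (fit.t0, 1.5 * float(max_time))


def compare_arms(
    fits: Sequence[FitResult],
    labels: Sequence[str] | None = None,
    search_window: tuple[float, float] = (9.0, 123.0),
) -> pd.DataFrame:
    """Within-family comparison of treatment arms by growth kinetics.

    Returns one row per arm: carrying capacity, rate maximum (t_max, v_max),
    the ratio of v_max to the first (reference) arm, and the delay of t_max
    relative to it (negative when an arm peaks before the reference).
    """
    if len(fits) < 2:
        raise InputError("need at least two arms to compare")
    fams = {f.family for f in fits}
    if len(fams) > 1:
        raise InputError(
            f"arm comparison is within-family; got {sorted(f.name for f in fams)}"
        )
    if labels is None:
        labels = [f.label or f"arm{i}" for i, f in enumerate(fits)]
    if len(labels) != len(fits):
        raise InputError("labels and fits differ in length")
    rows = []
    for lab, f in zip(labels, fits):
        peak = max_growth_rate(f.params, search_window)
        rows.append(
            {
                "arm": lab,
                "M": f.estimates.get("M", np.nan),
                "t_max": peak.t_max,
                "v_max": peak.v_max,
                "at_boundary": peak.at_boundary,
            }
        )
    df = pd.DataFrame(rows)
    ref = df.iloc[0]
    df["vmax_ratio"] = df["v_max"] / ref["v_max"]
    df["tmax_delay"] = df["t_max"] - ref["t_max"]
    return df
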