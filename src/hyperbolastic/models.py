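"""Sigmoidal growth laws: hyperbolastic H1/H2/H3, Gompertz and Weibull.

Each family is defined by an ordinary differential equation for the
population (tumor) weight ``P(t)`` together with a closed-form solution.
The integration constant ``alpha`` is never a free parameter: it is
re-derived from the initial condition ``P(t0) = P0`` (anchoring), so every
curve passes exactly through the first observation.

Closed forms (t in days, P in grams, asinh the inverse hyperbolic sine):

=========  ==================================================  =============================
family     P(t)                                                free parameters
=========  ==================================================  =============================
H1         M / (1 + a·exp(−δt − θ·asinh t))                    M, δ, θ
H2         M / (1 + a·asinh(exp(−δ t^γ)))                      M, δ, γ   (γ > 0)
H3         M − a·exp(−δ t^γ − asinh(θt))                       M, δ, γ, θ  (γ > 0)
Gompertz   a·exp(b·exp(ct))                                    b, c      (b, c < 0)
Weibull    M − a·exp(−β t^γ)                                   M, β, γ   (γ > 0)
=========  ==================================================  =============================

``M`` is the carrying capacity (the Gompertz asymptote is ``a`` itself).
First and second time derivatives (growth velocity and acceleration) are
analytic; the ODE right-hand sides are kept as an independent evaluation
path so that the two can be cross-checked.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import DomainError, IntegrationError, InvalidParameterError

__all__ = [
    "ModelFamily",
    "GrowthSeries",
    "AnchoredParams",
    "anchor_alpha",
    "predict",
    "rate",
    "rate_from_ode",
    "acceleration",
    "integrate_rate_equation",
]


class ModelFamily(str, enum.Enum):
    """The five supported growth laws."""

    H1 = "h1"
    H2 = "h2"
    H3 = "h3"
    GOMPERTZ = "gompertz"
    WEIBULL = "weibull"

    @property
    def param_names(self) -> tuple[str, ...]:
        return _PARAM_NAMES[self]

    @property
    def n_params(self) -> int:
        """Number of free mean-function parameters (alpha excluded)."""
        return len(_PARAM_NAMES[self])

    @property
    def has_capacity(self) -> bool:
        return self is not ModelFamily.GOMPERTZ


_PARAM_NAMES: dict[ModelFamily, tuple[str, ...]] = {
    ModelFamily.H1: ("M", "delta", "theta"),
    ModelFamily.H2: ("M", "delta", "gamma"),
    ModelFamily.H3: ("M", "delta", "gamma", "theta"),
    ModelFamily.GOMPERTZ: ("b", "c"),
    ModelFamily.WEIBULL: ("M", "beta", "gamma"),
}


@dataclass(frozen=True)
class GrowthSeries:
    """An ordered tumor-growth time series: times in days, weights in grams."""

    times: np.ndarray
    weights: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "weights", w)
        if t.ndim != 1 or w.ndim != 1 or len(t) != len(w):
            raise InvalidParameterError("times and weights must be 1-D and equally long")
        if len(t) < 2:
            raise InvalidParameterError("a growth series needs at least 2 observations")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(w)):
            raise InvalidParameterError("times and weights must be finite")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if t[0] < 0:
            raise InvalidParameterError("times must be non-negative")
        if np.any(w <= 0):
            raise InvalidParameterError("weights must be positive")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def t0(self) -> float:
        return float(self.times[0])

    @property
    def P0(self) -> float:
        return float(self.weights[0])


@dataclass(frozen=True)
class AnchoredParams:
    """A fully specified curve: family, free parameters, and the anchor point.

    ``alpha`` is derived, never stored as an input: it is recomputed from the
    free parameters and ``(t0, P0)`` so ``predict(params, t0) == P0`` exactly.
    """

    family: ModelFamily
    values: Mapping[str, float]
    t0: float = 0.0
    P0: float = 1.0
    alpha: float = field(init=False)

    def __post_init__(self) -> None:
        fam = ModelFamily(self.family)
        object.__setattr__(self, "family", fam)
        vals = {k: float(v) for k, v in dict(self.values).items()}
        missing = set(fam.param_names) - set(vals)
        extra = set(vals) - set(fam.param_names)
        if missing or extra:
            raise InvalidParameterError(
                f"{fam.name} expects parameters {fam.param_names}; "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "t0", float(self.t0))
        object.__setattr__(self, "P0", float(self.P0))
        _validate(fam, vals, self.t0, self.P0)
        object.__setattr__(self, "alpha", anchor_alpha(fam, vals, self.t0, self.P0))

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def vector(self) -> np.ndarray:
        """Free parameters in the family's canonical order."""
        return np.array([self.values[k] for k in self.family.param_names])

    def replace(self, **changes: float) -> "AnchoredParams":
        vals = {**self.values, **{k: v for k, v in changes.items() if k in self.values}}
        t0 = changes.get("t0", self.t0)
        P0 = changes.get("P0", self.P0)
        return AnchoredParams(self.family, vals, t0, P0)


def _validate(family: ModelFamily, v: Mapping[str, float], t0: float, P0: float) -> None:
    if P0 <= 0:
        raise InvalidParameterError(f"P0 must be positive, got P0={P0}")
    if t0 < 0:
        raise InvalidParameterError(f"t0 must be non-negative, got t0={t0}")
    if "gamma" in v and v["gamma"] <= 0:
        raise InvalidParameterError(f"gamma must be positive, got gamma={v['gamma']}")
    if "M" in v and v["M"] <= P0:
        raise InvalidParameterError(
            f"carrying capacity must exceed the anchor weight: M={v['M']} <= P0={P0}"
        )
    if family is ModelFamily.GOMPERTZ and (v["b"] >= 0 or v["c"] >= 0):
        raise InvalidParameterError(
            f"Gompertz requires b < 0 and c < 0, got b={v['b']}, c={v['c']}"
        )


# ---------------------------------------------------------------------------
# numerically stable helpers for the H2 form
# ---------------------------------------------------------------------------

_H2_SMALL = 30.0  # beyond this, asinh(exp(-u)) == exp(-u) to double precision


def _h2_log_s(u: np.ndarray) -> np.ndarray:
    """log(asinh(exp(-u))), using the small-argument asymptote for large u."""
    u = np.asarray(u, dtype=float)
    capped = np.minimum(u, _H2_SMALL)
    with np.errstate(divide="ignore"):
        direct = np.log(np.arcsinh(np.exp(-capped)))
    return np.where(u > _H2_SMALL, -u, direct)


def _h2_dlog_s(u: np.ndarray) -> np.ndarray:
    """d/du of log(asinh(exp(-u))); tends to -1 as u grows."""
    u = np.asarray(u, dtype=float)
    x = np.exp(-np.minimum(u, _H2_SMALL))
    val = -x / (np.sqrt(1.0 + x * x) * np.arcsinh(x))
    return np.where(u > _H2_SMALL, -1.0, val)


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

def anchor_alpha(
    family: ModelFamily,
    raw_params: Mapping[str, float] | Sequence[float],
    t0: float,
    P0: float,
) -> float:
    """Integration constant alpha that pins the curve through ``(t0, P0)``.

    ``raw_params`` may be a mapping keyed by parameter name or a sequence in
    the family's canonical order. Raises :class:`InvalidParameterError` for
    non-positive ``P0``, ``M <= P0`` or ``gamma <= 0``.
    """
    family = ModelFamily(family)
    if not isinstance(raw_params, Mapping):
        raw_params = dict(zip(family.param_names, raw_params, strict=True))
    _validate(family, raw_params, t0, P0)
    v = raw_params
    if family is ModelFamily.H1:
        return (v["M"] - P0) / P0 * np.exp(v["delta"] * t0 + v["theta"] * np.arcsinh(t0))
    if family is ModelFamily.H2:
        u0 = v["delta"] * t0 ** v["gamma"]
        return (v["M"] - P0) / (P0 * np.arcsinh(np.exp(-u0)))
    if family is ModelFamily.H3:
        return (v["M"] - P0) * np.exp(
            v["delta"] * t0 ** v["gamma"] + np.arcsinh(v["theta"] * t0)
        )
    if family is ModelFamily.GOMPERTZ:
        return P0 * np.exp(-v["b"] * np.exp(v["c"] * t0))
    # Weibull
    return (v["M"] - P0) * np.exp(v["beta"] * t0 ** v["gamma"])


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _as_time(t, allow_zero: bool = True) -> tuple[np.ndarray, bool]:
    arr = np.asarray(t, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any(arr < 0):
        raise DomainError("time must be non-negative")
    if not allow_zero and np.any(arr == 0):
        raise DomainError("t^(gamma-1) is singular at t=0 for gamma < 1")
    return arr, scalar


def _ret(x: np.ndarray, scalar: bool):
    return float(x[0]) if scalar else x


def predict(params: AnchoredParams, t) -> np.ndarray | float:
    """Closed-form curve value P(t) in grams; vectorizes over ``t``."""
    t, scalar = _as_time(t)
    fam, v, t0, P0 = params.family, params.values, params.t0, params.P0
    with np.errstate(over="ignore", under="ignore"):
        if fam is ModelFamily.H1:
            # E(t) = alpha * exp(-dt - th*asinh t), via the anchored ratio
            E = (v["M"] - P0) / P0 * np.exp(
                v["delta"] * (t0 - t) + v["theta"] * (np.arcsinh(t0) - np.arcsinh(t))
            )
            out = v["M"] / (1.0 + E)
        elif fam is ModelFamily.H2:
            A = (v["M"] - P0) / P0 * np.exp(
                _h2_log_s(v["delta"] * t ** v["gamma"])
                - _h2_log_s(v["delta"] * t0 ** v["gamma"])
            )
            out = v["M"] / (1.0 + A)
        elif fam is ModelFamily.H3:
            out = v["M"] - params.alpha * np.exp(
                -v["delta"] * t ** v["gamma"] - np.arcsinh(v["theta"] * t)
            )
        elif fam is ModelFamily.GOMPERTZ:
            out = params.alpha * np.exp(v["b"] * np.exp(v["c"] * t))
        else:  # Weibull
            out = v["M"] - params.alpha * np.exp(-v["beta"] * t ** v["gamma"])
    return _ret(out, scalar)


def _g_h1(v, t):
    return v["delta"] + v["theta"] / np.sqrt(1.0 + t * t)


def _g_h3(v, t):
    th = v["theta"]
    return v["delta"] * v["gamma"] * t ** (v["gamma"] - 1.0) + th / np.sqrt(
        1.0 + th * th * t * t
    )


def rate(params: AnchoredParams, t) -> np.ndarray | float:
    """Growth velocity dP/dt in grams/day, from the closed form's derivative."""
    fam, v, t0, P0 = params.family, params.values, params.t0, params.P0
    gamma_lt_1 = "gamma" in v and v["gamma"] < 1.0
    t, scalar = _as_time(t, allow_zero=not gamma_lt_1)
    with np.errstate(over="ignore", under="ignore"):
        if fam is ModelFamily.H1:
            E = (v["M"] - P0) / P0 * np.exp(
                v["delta"] * (t0 - t) + v["theta"] * (np.arcsinh(t0) - np.arcsinh(t))
            )
            out = v["M"] * E * _g_h1(v, t) / (1.0 + E) ** 2
        elif fam is ModelFamily.H2:
            u = v["delta"] * t ** v["gamma"]
            A = (v["M"] - P0) / P0 * np.exp(
                _h2_log_s(u) - _h2_log_s(v["delta"] * t0 ** v["gamma"])
            )
            dudt = v["delta"] * v["gamma"] * t ** (v["gamma"] - 1.0)
            out = -v["M"] * A * _h2_dlog_s(u) * dudt / (1.0 + A) ** 2
        elif fam is ModelFamily.H3:
            shrink = params.alpha * np.exp(
                -v["delta"] * t ** v["gamma"] - np.arcsinh(v["theta"] * t)
            )
            out = shrink * _g_h3(v, t)
        elif fam is ModelFamily.GOMPERTZ:
            inner = v["b"] * np.exp(v["c"] * t)
            out = params.alpha * np.exp(inner) * inner * v["c"]
        else:  # Weibull
            out = (
                params.alpha
                * v["beta"]
                * v["gamma"]
                * t ** (v["gamma"] - 1.0)
                * np.exp(-v["beta"] * t ** v["gamma"])
            )
    return _ret(out, scalar)


def _ode_rhs(params: AnchoredParams, t, P):
    """The family's printed rate-equation right-hand side f(t, P)."""
    fam, v = params.family, params.values
    t = np.asarray(t, dtype=float)
    P = np.asarray(P, dtype=float)
    if fam is ModelFamily.H1:
        return P / v["M"] * (v["M"] - P) * _g_h1(v, t)
    if fam is ModelFamily.H2:
        a = params.alpha
        return (
            a
            * v["delta"]
            * v["gamma"]
            * P**2
            * t ** (v["gamma"] - 1.0)
            * np.tanh((v["M"] - P) / (a * P))
            / v["M"]
        )
    if fam is ModelFamily.H3:
        return (v["M"] - P) * _g_h3(v, t)
    if fam is ModelFamily.GOMPERTZ:
        return P * v["b"] * v["c"] * np.exp(v["c"] * t)
    return (v["M"] - P) * v["beta"] * v["gamma"] * t ** (v["gamma"] - 1.0)


def rate_from_ode(params: AnchoredParams, t) -> np.ndarray | float:
    """dP/dt evaluated through the rate equation at P = predict(t).

    Algebraically identical to :func:`rate`; kept as an independent code
    path so transcription errors in either form are caught by comparison.
    """
    fam, v = params.family, params.values
    gamma_lt_1 = "gamma" in v and v["gamma"] < 1.0
    t, scalar = _as_time(t, allow_zero=not gamma_lt_1)
    P = np.atleast_1d(np.asarray(predict(params, t), dtype=float))
    return _ret(np.asarray(_ode_rhs(params, t, P), dtype=float), scalar)


def acceleration(params: AnchoredParams, t) -> np.ndarray | float:
    """Growth acceleration d²P/dt² in grams/day².

    Computed as df/dt + (df/dP)·f for the family's rate equation f(t, P),
    which equals the analytic second derivative of the closed form.
    """
    fam, v = params.family, params.values
    needs_pos = "gamma" in v and v["gamma"] < 2.0 and v["gamma"] != 1.0
    t, scalar = _as_time(t, allow_zero=not needs_pos)
    P = np.atleast_1d(np.asarray(predict(params, t), dtype=float))
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        if fam is ModelFamily.H1:
            g = _g_h1(v, t)
            gp = -v["theta"] * t * (1.0 + t * t) ** -1.5
            mass = P * (v["M"] - P) / v["M"]
            out = mass * (gp + (v["M"] - 2.0 * P) / v["M"] * g * g)
        elif fam is ModelFamily.H2:
            M, d, g_, P0 = v["M"], v["delta"], v["gamma"], params.P0
            u = d * t ** g_
            u0 = d * params.t0 ** g_
            logs = _h2_log_s(u)
            s = np.exp(logs)
            # alpha*tanh(s) via the anchored ratio; tanh(s)/s -> 1 as s -> 0
            tanh_over_s = np.where(s < 1e-8, 1.0 - s * s / 3.0, np.tanh(s) / np.where(s == 0, 1.0, s))
            a_tanh = (M - P0) / P0 * np.exp(logs - _h2_log_s(u0)) * tanh_over_s
            sech2 = 1.0 / np.cosh(s) ** 2
            tg = t ** (g_ - 1.0)
            f = d * g_ / M * tg * P**2 * a_tanh
            f_P = d * g_ / M * tg * (2.0 * P * a_tanh - M * sech2)
            out = (g_ - 1.0) * np.where(t == 0, 0.0, f / np.where(t == 0, 1.0, t)) + f_P * f
        elif fam is ModelFamily.H3:
            g = _g_h3(v, t)
            th = v["theta"]
            gp = v["delta"] * v["gamma"] * (v["gamma"] - 1.0) * t ** (
                v["gamma"] - 2.0
            ) - th**3 * t * (1.0 + th * th * t * t) ** -1.5
            out = (v["M"] - P) * (gp - g * g)
        elif fam is ModelFamily.GOMPERTZ:
            inner = v["b"] * np.exp(v["c"] * t)
            out = P * inner * v["c"] * (v["c"] + inner * v["c"])
        else:  # Weibull
            bg = v["beta"] * v["gamma"]
            out = (v["M"] - P) * bg * (
                (v["gamma"] - 1.0) * t ** (v["gamma"] - 2.0)
                - bg * t ** (2.0 * (v["gamma"] - 1.0))
            )
    return _ret(out, scalar)


def integrate_rate_equation(params: AnchoredParams, t_grid) -> np.ndarray:
    """Numerically integrate the family's ODE over ``t_grid``.

    The grid must be increasing; the solution starts from the closed-form
    value at the first grid point (``P0`` when the grid starts at ``t0``).
    Agreement with :func:`predict` is the package's transcription check.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0:
        raise DomainError("t_grid must be a non-empty 1-D array")
    if np.any(np.diff(t_grid) <= 0) and len(t_grid) > 1:
        raise DomainError("t_grid must be strictly increasing")
    y0 = float(predict(params, t_grid[0]))
    if len(t_grid) == 1:
        return np.array([y0])
    sol = solve_ivp(
        lambda t, y: [float(_ode_rhs(params, t, y[0]))],
        (t_grid[0], t_grid[-1]),
        [y0],
        t_eval=t_grid,
        method="DOP853",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed for {params.family.name}: {sol.message}"
        )
    return sol.y[0]
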