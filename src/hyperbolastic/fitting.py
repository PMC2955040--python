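"""Nonlinear least-squares estimation of growth-curve parameters.

The objective is ordinary (unweighted) least squares on the observed
weights, with the integration constant alpha re-anchored at the first
observation ``(t0, P0)`` at every objective evaluation, so alpha is never a
free parameter. Standard errors come from the usual linearization
``s^2 (J'J)^{-1}`` with ``s^2 = SSE/(n-k)``; 95% confidence intervals use
the Student-t critical value at ``n-k`` degrees of freedom, which is the
convention that reproduces published Wald intervals for this kind of fit.

Two numerical choices matter for the hyperbolastic type-III (H3) and
Weibull families, whose scale parameter is tiny (1e-9 .. 1e-6) and strongly
anticorrelated with the time exponent gamma:

* the scale parameter (H3 ``delta``, Weibull ``beta``) is optimized as
  log10(scale) internally, and
* the fit is restarted from several gamma values (multistart), keeping the
  lowest-SSE solution; ties (SSE within 1e-12) break toward smaller gamma.

When the Jacobian condition number at the optimum exceeds 1e8 the fit is
flagged ``rank_deficient``: the point estimates are fine but the ridge makes
individual standard errors of the correlated pair unstable. Wald intervals
are reported unclipped (they may cross a bound such as delta >= 0), matching
the convention of mainstream nonlinear-regression software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import t as student_t

from .exceptions import ConvergenceError, InitializationError, InputError
from .models import AnchoredParams, GrowthSeries, ModelFamily, predict

__all__ = ["FitResult", "fit", "default_init", "standard_errors", "format_table"]

_LOG_SCALE_PARAM = {ModelFamily.H3: "delta", ModelFamily.WEIBULL: "beta"}
_GAMMA_STARTS = (1.0, 2.0, 3.0, 5.0, 7.0)
_COND_LIMIT = 1e8


@dataclass
class FitResult:
    """Outcome of a least-squares fit of one model family to one series."""

    family: ModelFamily
    estimates: dict[str, float]
    std_errors: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    residuals: np.ndarray
    sse: float
    n_obs: int
    n_params: int
    converged: bool
    t0: float
    P0: float
    rank_deficient: bool = False
    n_starts: int = 1
    label: str = ""

    @property
    def params(self) -> AnchoredParams:
        return AnchoredParams(self.family, self.estimates, self.t0, self.P0)

    @property
    def rms(self) -> float:
        """Residual mean square SSE/(n-k)."""
        return self.sse / (self.n_obs - self.n_params)

    def to_dict(self) -> dict:
        return {
            "family": self.family.value,
            "label": self.label,
            "estimates": self.estimates,
            "std_errors": self.std_errors,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "sse": self.sse,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "rank_deficient": self.rank_deficient,
            "anchoring": {"t0": self.t0, "P0": self.P0},
        }


def default_bounds(series: GrowthSeries, family: ModelFamily) -> dict[str, tuple[float, float]]:
    """Box bounds on the free parameters, on their natural scale."""
    wmax = float(series.weights.max())
    b: dict[str, tuple[float, float]] = {}
    if family.has_capacity:
        b["M"] = (wmax + 1e-8, 10.0 * wmax)
    if family is ModelFamily.H1:
        b["delta"] = (0.0, 5.0)
        b["theta"] = (-np.inf, np.inf)
    elif family is ModelFamily.H2:
        b["delta"] = (0.0, 5.0)
        b["gamma"] = (1e-6, 10.0)
    elif family is ModelFamily.H3:
        b["delta"] = (1e-15, 100.0)
        b["gamma"] = (1e-6, 10.0)
        b["theta"] = (0.0, 10.0)
    elif family is ModelFamily.GOMPERTZ:
        b["b"] = (-50.0, -1e-10)
        b["c"] = (-5.0, -1e-10)
    else:  # Weibull
        b["beta"] = (1e-15, 100.0)
        b["gamma"] = (1e-6, 10.0)
    return b


def _weibull_linearization(series: GrowthSeries, M0: float, gamma: float | None = None):
    """Regress log(-log((M0-w)/M0)) on log t; returns (gamma0, scale0)."""
    t, w = series.times, series.weights
    mask = (t > 0) & (w < M0)
    if mask.sum() < 2:
        raise InitializationError("too few usable points for initialization")
    y = np.log(-np.log((M0 - w[mask]) / M0))
    x = np.log(t[mask])
    if gamma is None:
        gamma, intercept = np.polyfit(x, y, 1)
        gamma = float(np.clip(gamma, 0.2, 9.0))
    intercept = float(np.mean(y - gamma * x))
    return gamma, float(np.exp(intercept))


def default_init(series: GrowthSeries, family: ModelFamily) -> dict[str, float]:
    """Heuristic starting values: capacity 5% above the largest weight, time
    exponent and scale from a Weibull-type linearization, small positive
    rate parameters elsewhere."""
    family = ModelFamily(family)
    w = series.weights
    if np.ptp(w) == 0:
        raise InitializationError("constant weights: growth parameters are unidentifiable")
    M0 = 1.05 * float(w.max())
    if family is ModelFamily.H1:
        return {"M": M0, "delta": 0.05, "theta": 0.01}
    if family is ModelFamily.GOMPERTZ:
        # log(log(A0/w)) is linear in t under the model
        mask = w < M0
        y = np.log(np.log(M0 / w[mask]))
        c0, lnnegb = np.polyfit(series.times[mask], y, 1)
        c0 = float(min(c0, -1e-4))
        b0 = float(min(-np.exp(lnnegb), -1e-4))
        return {"b": b0, "c": c0}
    gamma0, scale0 = _weibull_linearization(series, M0)
    if family is ModelFamily.H2:
        return {"M": M0, "delta": min(max(scale0, 1e-8), 4.9), "gamma": gamma0}
    if family is ModelFamily.H3:
        return {"M": M0, "delta": max(scale0, 1e-14), "gamma": gamma0, "theta": 0.001}
    return {"M": M0, "beta": max(scale0, 1e-14), "gamma": gamma0}


def _to_internal(family: ModelFamily, values: Mapping[str, float]) -> np.ndarray:
    logp = _LOG_SCALE_PARAM.get(family)
    out = []
    for name in family.param_names:
        v = values[name]
        out.append(np.log10(v) if name == logp else v)
    return np.array(out, dtype=float)


def _from_internal(family: ModelFamily, x: np.ndarray) -> dict[str, float]:
    logp = _LOG_SCALE_PARAM.get(family)
    return {
        name: float(10.0 ** xi if name == logp else xi)
        for name, xi in zip(family.param_names, x)
    }


def _internal_bounds(family: ModelFamily, bounds: Mapping[str, tuple[float, float]]):
    logp = _LOG_SCALE_PARAM.get(family)
    lo, hi = [], []
    for name in family.param_names:
        lb, ub = bounds[name]
        if name == logp:
            lb, ub = np.log10(max(lb, 1e-300)), np.log10(ub)
        lo.append(lb)
        hi.append(ub)
    return np.array(lo), np.array(hi)


def _starts(series: GrowthSeries, family: ModelFamily, seed: int | None) -> list[dict[str, float]]:
    base = default_init(series, family)
    starts = [base]
    if "gamma" in family.param_names:
        M0 = base.get("M", 1.05 * float(series.weights.max()))
        scale_name = "beta" if family is ModelFamily.WEIBULL else "delta"
        for g0 in _GAMMA_STARTS:
            _, scale0 = _weibull_linearization(series, M0, gamma=g0)
            s = dict(base)
            s["gamma"] = g0
            if family is ModelFamily.H2:
                s[scale_name] = min(max(scale0, 1e-8), 4.9)
            else:
                s[scale_name] = max(scale0, 1e-14)
            starts.append(s)
    if seed is not None:
        rng = np.random.default_rng(seed)
        for _ in range(2):
            s = {k: v * float(rng.uniform(0.7, 1.3)) for k, v in base.items()}
            if "M" in s:
                s["M"] = max(s["M"], float(series.weights.max()) * 1.01)
            starts.append(s)
    return starts


def fit(
    series: GrowthSeries,
    family: ModelFamily,
    init: Mapping[str, float] | Sequence[float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    seed: int | None = 0,
    t0: float | None = None,
    P0: float | None = None,
) -> FitResult:
    """Fit one model family to a growth series by nonlinear least squares.

    Parameters
    ----------
    series : GrowthSeries
        Observations; needs at least ``n_params + 1`` points.
    family : ModelFamily
        Which growth law to fit.
    init : mapping or sequence, optional
        Starting values (natural scale). When omitted, a heuristic start
        plus a gamma multistart grid is used.
    bounds : mapping, optional
        Per-parameter ``(lower, upper)`` overrides.
    seed : int, optional
        Seed for the jittered extra starts; ``None`` disables jitter.
    t0, P0 : float, optional
        Anchor point; defaults to the first observation.
    """
    family = ModelFamily(family)
    k = family.n_params
    if len(series) < k + 1:
        raise InputError(
            f"{family.name} has {k} parameters; need at least {k + 1} observations, "
            f"got {len(series)}"
        )
    t0 = series.t0 if t0 is None else float(t0)
    P0 = series.P0 if P0 is None else float(P0)
    bnds = default_bounds(series, family)
    if bounds:
        bnds.update({k_: tuple(v) for k_, v in bounds.items()})
    lo, hi = _internal_bounds(family, bnds)

    if init is not None:
        if not isinstance(init, Mapping):
            init = dict(zip(family.param_names, init, strict=True))
        start_list = [dict(init)]
    else:
        start_list = _starts(series, family, seed)

    tgrid, w = series.times, series.weights

    def residual(x: np.ndarray) -> np.ndarray:
        params = AnchoredParams(family, _from_internal(family, x), t0, P0)
        r = np.asarray(predict(params, tgrid), dtype=float) - w
        return np.nan_to_num(r, nan=1e6, posinf=1e6, neginf=-1e6)

    best = None
    best_x = None
    n_ok = 0
    for s in start_list:
        x0 = np.clip(_to_internal(family, s), lo, hi)
        try:
            res = least_squares(
                residual, x0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except ValueError:
            continue
        if not np.isfinite(res.cost):
            continue
        n_ok += 1
        if best is None or res.cost < best.cost - 1e-12:
            best, best_x = res, res.x
        elif abs(res.cost - best.cost) <= 1e-12:
            # tie: prefer the smaller gamma solution when gamma exists
            if "gamma" in family.param_names:
                gi = family.param_names.index("gamma")
                if res.x[gi] < best_x[gi]:
                    best, best_x = res, res.x
    if best is None:
        raise ConvergenceError(f"all {len(start_list)} starts failed for {family.name}")

    estimates = _from_internal(family, best_x)
    # residuals stored observed-minus-predicted
    r = w - np.asarray(predict(AnchoredParams(family, estimates, t0, P0), tgrid))
    sse = float(r @ r)
    result = FitResult(
        family=family,
        estimates=estimates,
        std_errors={},
        ci_lower={},
        ci_upper={},
        residuals=r,
        sse=sse,
        n_obs=len(series),
        n_params=k,
        converged=bool(best.status > 0),
        t0=t0,
        P0=P0,
        n_starts=len(start_list),
        label=series.label,
    )
    se, lower, upper, rank_def = standard_errors(result, series)
    result.std_errors, result.ci_lower, result.ci_upper = se, lower, upper
    result.rank_deficient = rank_def
    return result


def _jacobian(family: ModelFamily, estimates: dict[str, float], t0: float, P0: float, t: np.ndarray) -> np.ndarray:
    """Central finite-difference Jacobian of predictions w.r.t. the free
    parameters on their natural scale (alpha re-anchored at each step)."""
    names = family.param_names
    cols = []
    for name in names:
        p = estimates[name]
        h = 1e-6 * abs(p) if p != 0 else 1e-8
        up = dict(estimates, **{name: p + h})
        dn = dict(estimates, **{name: p - h})
        fu = np.asarray(predict(AnchoredParams(family, up, t0, P0), t), dtype=float)
        fd = np.asarray(predict(AnchoredParams(family, dn, t0, P0), t), dtype=float)
        cols.append((fu - fd) / (2.0 * h))
    return np.column_stack(cols)


def standard_errors(fit_result: FitResult, series: GrowthSeries):
    """Linearized (Wald) standard errors and 95% t-intervals.

    Returns ``(std_errors, ci_lower, ci_upper, rank_deficient)`` as dicts
    keyed by parameter name plus a flag. The intervals are
    ``estimate +/- t(0.975, n-k) * SE``.
    """
    fam = fit_result.family
    names = fam.param_names
    n, k = fit_result.n_obs, fit_result.n_params
    J = _jacobian(fam, fit_result.estimates, fit_result.t0, fit_result.P0, series.times)
    s2 = fit_result.sse / (n - k)
    rank_def = False
    cond = np.linalg.cond(J)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        rank_def = True
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(J.T @ J)
        rank_def = True
    se_vec = np.sqrt(np.maximum(np.diag(cov), 0.0))
    tcrit = float(student_t.ppf(0.975, n - k))
    se = {nm: float(s) for nm, s in zip(names, se_vec)}
    lower = {nm: fit_result.estimates[nm] - tcrit * se[nm] for nm in names}
    upper = {nm: fit_result.estimates[nm] + tcrit * se[nm] for nm in names}
    return se, lower, upper, rank_def


def format_table(fits: Sequence[FitResult]) -> str:
    """Human-readable parameter table (estimate, SE, 95% CI per parameter)."""
    lines = [
        f"{'Model':<10}{'Parameter':<11}{'Estimate':>12}{'Std.Err':>12}"
        f"{'95% lower':>12}{'95% upper':>12}"
    ]
    for f in fits:
        for i, name in enumerate(f.family.param_names):
            lines.append(
                f"{f.family.name if i == 0 else '':<10}{name:<11}"
                f"{f.estimates[name]:>12.4g}{f.std_errors[name]:>12.4g}"
                f"{f.ci_lower[name]:>12.4g}{f.ci_upper[name]:>12.4g}"
            )
        note = []
        if not f.converged:
            note.append("NOT CONVERGED")
        if f.rank_deficient:
            note.append("rank-deficient Jacobian (correlated ridge)")
        if note:
            lines.append(f"{'':<10}[{'; '.join(note)}]")
    return "\n".join(lines)
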