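"""Synthetic tumor-growth series with the statistical structure the
analysis assumes.

The generator emulates the design of the combined-treatment experiment: 18
mean-weight observations on days 9-82, a sigmoidal trajectory with carrying
capacity around 7.5-8.3 g, and additive Gaussian measurement noise at the
residual scale of the real fits (residual mean squares 0.006-0.076 g^2,
i.e. sigma roughly 0.08-0.28 g). A proportional-noise option exists for
robustness studies. Weights are truncated below at 0.01 g so every
generated series is a valid positive-weight :class:`GrowthSeries`; at high
noise this truncation is a (documented) source of upward bias near zero.

The four-arm scenario reproduces the published kinetic summaries of the
untreated, IAA-only, DMSO-only and combined IAA+DMSO arms. Only the
combined arm's raw data are public, so the other arms are synthetic
stand-ins: hyperbolastic type-III parameters are calibrated by numerically
inverting the (peak time, peak rate) map at fixed carrying capacity and
asymmetry, so each arm's true curve attains the published maximum growth
rate at the published day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .dynamics import max_growth_rate
from .exceptions import InputError
from .models import AnchoredParams, GrowthSeries, ModelFamily, predict

__all__ = [
    "SimScenario",
    "generate",
    "four_arm_scenario",
    "calibrate_rate_peak",
    "ARM_TARGETS",
    "COMBINED_H3_PARAMS",
    "STUDY_TIMES",
]

#: Observation days of the combined-treatment experiment (n=18).
STUDY_TIMES: np.ndarray = np.array(
    [9, 13, 17, 21, 29, 33, 37, 40, 43, 49, 55, 57, 60, 66, 72, 74, 78, 82],
    dtype=float,
)

#: Published H3 estimates for the combined IAA+DMSO arm, anchored at (9, 0.21).
COMBINED_H3_PARAMS = AnchoredParams(
    ModelFamily.H3,
    {"M": 7.533, "delta": 3.594e-9, "gamma": 4.712, "theta": 0.004},
    t0=9.0,
    P0=0.21,
)

#: Published (t_max days, v_max g/day) kinetic summaries per treatment arm.
ARM_TARGETS: dict[str, tuple[float, float]] = {
    "untreated": (19.6933, 0.407303),
    "IAA": (37.3535, 0.192412),
    "DMSO": (46.9909, 0.192293),
    "IAA+DMSO": (57.2509, 0.184104),
}

# Carrying capacities for the synthetic stand-in arms (the combined arm uses
# its published fit). Untreated tumors run to a larger plateau; the single
# treatments plateau close to the combined arm.
_ARM_CAPACITY = {"untreated": 8.0, "IAA": 7.6, "DMSO": 7.6}
_ARM_THETA = 0.004


@dataclass(frozen=True)
class SimScenario:
    """Recipe for replicate synthetic growth series."""

    family: ModelFamily = ModelFamily.H3
    true_params: AnchoredParams = COMBINED_H3_PARAMS
    times: np.ndarray = field(default_factory=lambda: STUDY_TIMES.copy())
    noise_model: Literal["additive", "proportional"] = "additive"
    noise_scale: float = 0.08
    n_replicates: int = 1
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.noise_scale < 0:
            raise InputError("noise_scale must be non-negative")
        if self.n_replicates < 1:
            raise InputError("n_replicates must be at least 1")
        if self.noise_model not in ("additive", "proportional"):
            raise InputError(f"unknown noise model {self.noise_model!r}")
        if ModelFamily(self.family) is not self.true_params.family:
            raise InputError("scenario family and true_params.family disagree")


_FLOOR = 0.01  # grams; truncation keeps weights positive


def generate(scenario: SimScenario) -> list[GrowthSeries]:
    """Draw ``n_replicates`` noisy series; byte-identical under a fixed seed.

    Per-replicate RNG streams are spawned deterministically from the root
    seed, so replicate r is the same no matter how many replicates are drawn.
    """
    mean = np.asarray(predict(scenario.true_params, scenario.times), dtype=float)
    streams = np.random.SeedSequence(scenario.seed).spawn(scenario.n_replicates)
    out = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        eps = rng.standard_normal(len(scenario.times))
        if scenario.noise_model == "additive":
            w = mean + scenario.noise_scale * eps
        else:
            w = mean * (1.0 + scenario.noise_scale * eps)
        w = np.maximum(w, _FLOOR)
        out.append(
            GrowthSeries(scenario.times.copy(), w, label=f"{scenario.label}-{i}")
        )
    return out


@lru_cache(maxsize=32)
def _calibrate_cached(M: float, theta: float, t_peak: float, v_peak: float, t0: float, P0: float):
    hi = 3.0 * t_peak

    def residual(x):
        delta, gamma = 10.0 ** x[0], x[1]
        p = AnchoredParams(
            ModelFamily.H3,
            {"M": M, "delta": delta, "gamma": gamma, "theta": theta},
            t0,
            P0,
        )
        peak = max_growth_rate(p, (t0, hi))
        return [(peak.t_max - t_peak) / t_peak, (peak.v_max - v_peak) / v_peak]

    best = None
    for g0 in (2.0, 3.0, 4.0, 5.0):
        x0 = [np.log10(0.5) - g0 * np.log10(t_peak), g0]
        try:
            res = least_squares(residual, x0, bounds=([-15.0, 1.01], [0.0, 9.0]),
                                xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-16:
            break
    if best is None or best.cost > 1e-6:
        raise InputError(
            f"could not calibrate a type-III curve to peak {v_peak} g/day at day {t_peak}"
        )
    return 10.0 ** best.x[0], float(best.x[1])


def calibrate_rate_peak(
    t_peak: float,
    v_peak: float,
    M: float,
    theta: float = _ARM_THETA,
    t0: float = 9.0,
    P0: float = 0.21,
) -> AnchoredParams:
    """Hyperbolastic type-III parameters whose growth rate peaks at
    ``(t_peak, v_peak)``, found by inverting the peak map over (delta, gamma)
    at fixed ``(M, theta, t0, P0)``."""
    delta, gamma = _calibrate_cached(float(M), float(theta), float(t_peak), float(v_peak), float(t0), float(P0))
    return AnchoredParams(
        ModelFamily.H3,
        {"M": M, "delta": delta, "gamma": gamma, "theta": theta},
        t0,
        P0,
    )


def arm_true_params() -> dict[str, AnchoredParams]:
    """True generating curves for the four treatment arms."""
    out = {}
    for arm, (t_peak, v_peak) in ARM_TARGETS.items():
        if arm == "IAA+DMSO":
            out[arm] = COMBINED_H3_PARAMS
        else:
            out[arm] = calibrate_rate_peak(t_peak, v_peak, _ARM_CAPACITY[arm])
    return out


def four_arm_scenario(
    seed: int,
    noise_scale: float = 0.05,
    times: np.ndarray | None = None,
) -> list[GrowthSeries]:
    """One noisy series per treatment arm (untreated, IAA, DMSO, IAA+DMSO).

    The combined arm's true curve is the published fit; the other arms are
    calibrated stand-ins (see module docstring). ``noise_scale=0`` returns
    the true curves themselves.
    """
    times = STUDY_TIMES if times is None else np.asarray(times, dtype=float)
    streams = np.random.SeedSequence(seed).spawn(len(ARM_TARGETS))
    series = []
    for (arm, _), ss in zip(ARM_TARGETS.items(), streams):
        scen = SimScenario(
            family=ModelFamily.H3,
            true_params=arm_true_params()[arm],
            times=times,
            noise_scale=noise_scale,
            n_replicates=1,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            label=arm,
        )
        s = generate(scen)[0]
        series.append(GrowthSeries(s.times, s.weights, label=arm))
    return series
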