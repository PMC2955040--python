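"""Shared helper: random valid parameter sets per family, kept in ranges
where the curves are well-scaled over a 9-82 day horizon."""

import numpy as np

from hyperbolastic import AnchoredParams, ModelFamily


def random_valid_params(family: ModelFamily, rng: np.random.Generator) -> AnchoredParams:
    M = float(rng.uniform(2.0, 15.0))
    P0 = float(rng.uniform(0.05, 0.5))
    if family is ModelFamily.H1:
        vals = {
            "M": M,
            "delta": float(rng.uniform(0.02, 0.2)),
            "theta": float(rng.uniform(-0.015, 0.3)),
        }
    elif family is ModelFamily.H2:
        gamma = float(rng.uniform(0.5, 3.0))
        vals = {"M": M, "delta": float(rng.uniform(0.5, 20.0)) / 82.0**gamma, "gamma": gamma}
    elif family is ModelFamily.H3:
        gamma = float(rng.uniform(1.0, 6.0))
        vals = {
            "M": M,
            "delta": float(rng.uniform(1.0, 20.0)) / 82.0**gamma,
            "gamma": gamma,
            "theta": float(rng.uniform(0.0, 0.05)),
        }
    elif family is ModelFamily.GOMPERTZ:
        vals = {"b": float(rng.uniform(-8.0, -2.0)), "c": float(rng.uniform(-0.08, -0.01))}
    else:
        gamma = float(rng.uniform(1.0, 5.0))
        vals = {"M": M, "beta": float(rng.uniform(1.0, 20.0)) / 82.0**gamma, "gamma": gamma}
    return AnchoredParams(family, vals, t0=9.0, P0=P0)
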