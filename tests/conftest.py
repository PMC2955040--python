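import numpy as np
import pytest

from hyperbolastic import (
    AnchoredParams,
    ModelFamily,
    fit,
    load_combined_treatment_series,
)

# Published parameter estimates for the combined IAA+DMSO arm, anchored at
# the first observation (day 9, 0.21 g). The Weibull scale is stored
# positive: the source software's sign convention folds it into the
# exponential.
PUBLISHED_ESTIMATES = {
    ModelFamily.H1: {"M": 8.298, "delta": 0.087, "theta": -0.206},
    ModelFamily.H2: {"M": 8.223, "delta": 0.055, "gamma": 1.088},
    ModelFamily.H3: {"M": 7.533, "delta": 3.594e-9, "gamma": 4.712, "theta": 0.004},
    ModelFamily.GOMPERTZ: {"b": -5.418, "c": -0.025},
    ModelFamily.WEIBULL: {"M": 8.024, "beta": 8.579e-7, "gamma": 3.399},
}

# Published observed-vs-fitted table for the same arm (2 dp).
PUBLISHED_FITTED = {
    ModelFamily.H3: [0.21, 0.33, 0.46, 0.59, 0.96, 1.21, 1.53, 1.83, 2.18, 3.04,
                     4.08, 4.45, 5.00, 6.01, 6.78, 6.97, 7.24, 7.40],
    ModelFamily.H1: [0.21, 0.27, 0.36, 0.48, 0.86, 1.15, 1.51, 1.83, 2.21, 3.01,
                     4.10, 4.45, 4.96, 5.90, 6.66, 6.87, 7.23, 7.50],
    ModelFamily.H2: [0.21, 0.27, 0.36, 0.49, 0.87, 1.15, 1.51, 1.84, 2.22, 3.12,
                     4.15, 4.50, 5.01, 5.95, 6.71, 6.91, 7.26, 7.52],
    ModelFamily.WEIBULL: [0.21, 0.24, 0.30, 0.40, 0.80, 1.11, 1.51, 1.86, 2.26, 3.17,
                          4.16, 4.50, 5.00, 5.92, 6.68, 6.90, 7.25, 7.52],
    ModelFamily.GOMPERTZ: [0.21, 0.32, 0.46, 0.64, 1.15, 1.48, 1.85, 2.17, 2.50, 3.24,
                           4.04, 4.32, 4.74, 5.61, 6.49, 6.78, 7.35, 7.91],
}


@pytest.fixture(scope="session")
def combined_series():
    return load_combined_treatment_series()


@pytest.fixture(scope="session")
def published_params():
    """Published estimates wrapped as anchored parameter sets."""
    return {
        fam: AnchoredParams(fam, vals, t0=9.0, P0=0.21)
        for fam, vals in PUBLISHED_ESTIMATES.items()
    }


@pytest.fixture(scope="session")
def all_fits(combined_series):
    """One fit per family on the packaged arm (shared: fits are the slow part)."""
    return {fam: fit(combined_series, fam, seed=0) for fam in ModelFamily}


@pytest.fixture(scope="session")
def study_times(combined_series):
    return np.asarray(combined_series.times)
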