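"""Fit all five growth laws to the combined IAA+DMSO treatment arm.

Estimates the parameters of the hyperbolastic H1/H2/H3, Gompertz and
Weibull curves on the packaged 18-point mean-tumor-weight series by
nonlinear least squares (alpha anchored at the first observation, day 9 /
0.21 g), and writes the parameter table with standard errors and 95%
t-intervals to results/parameter_estimates.csv.
"""

from pathlib import Path

import pandas as pd

from hyperbolastic import ModelFamily, fit, format_table, load_combined_treatment_series

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    series = load_combined_treatment_series()
    fits = [fit(series, fam, seed=0) for fam in ModelFamily]
    print(format_table(fits))
    rows = [
        {
            "family": f.family.name,
            "parameter": name,
            "estimate": f.estimates[name],
            "std_error": f.std_errors[name],
            "ci_lower": f.ci_lower[name],
            "ci_upper": f.ci_upper[name],
            "sse": f.sse,
            "converged": f.converged,
        }
        for f in fits
        for name in f.family.param_names
    ]
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "parameter_estimates.csv", index=False)
    h3 = next(f for f in fits if f.family is ModelFamily.H3)
    print(
        f"\nH3 carrying capacity: {h3.estimates['M']:.3f} g "
        f"(95% CI {h3.ci_lower['M']:.3f}-{h3.ci_upper['M']:.3f}); "
        f"wrote {OUT / 'parameter_estimates.csv'}"
    )


if __name__ == "__main__":
    main()
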