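"""Four-arm treatment comparison on calibrated synthetic stand-ins.

Only the combined IAA+DMSO arm's raw series is public; the untreated,
IAA-only and DMSO-only arms are generated from hyperbolastic type-III
curves calibrated so their true rate peaks match the published kinetic
summaries. Fitting each (noise-free) arm and comparing kinetics shows the
treatment signature: every treated arm peaks at less than half the
untreated rate, and the delay of the peak orders IAA < DMSO < combined —
the two drugs' delays compound. Writes results/arm_comparison.csv.
"""

from pathlib import Path

from hyperbolastic import ModelFamily, compare_arms, fit, four_arm_scenario

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    arms = four_arm_scenario(SEED, noise_scale=0.0)
    fits = [fit(s, ModelFamily.H3, seed=0) for s in arms]
    table = compare_arms(fits, labels=[s.label for s in arms])
    print(table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    treated = table.iloc[1:]
    print(
        f"\ntreated-vs-untreated peak-rate ratios: "
        f"{', '.join(f'{r:.3f}' for r in treated['vmax_ratio'])} (all < 0.5); "
        f"peak delays {', '.join(f'{d:+.1f} d' for d in treated['tmax_delay'])}"
    )
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "arm_comparison.csv", index=False)
    print(f"wrote {OUT / 'arm_comparison.csv'}")


if __name__ == "__main__":
    main()
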