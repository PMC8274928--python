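#!/usr/bin/env python
"""Test the effect of age on the pressure curves and summary metrics.

Per vessel location and curve kind (area, compliance, distensibility) runs
the nested extra-sum-of-squares F-test (one curve pooled vs one per age
group); then compares maximal area / compliance / distensibility with a
two-way ANOVA (age x location) with Bonferroni-corrected location
contrasts. Writes results/curve_comparisons.csv and results/metric_anova.csv
and the per-kind curve-family figures.
"""

import pandas as pd
from pathlib import Path

import vesselmech as vm
from vesselmech.plots import plot_curve_families

OUT = Path(__file__).resolve().parents[1] / "results"
ALPHA = 0.05


def main():
    meas = vm.read_inflation_csv(OUT / "inflation_measurements.csv")
    series = vm.series_from_table(meas)
    fits = pd.read_csv(OUT / "fit_summary.csv")

    rows = []
    for loc in sorted({s.meta["location"] for s in series}):
        loc_series = [s for s in series if s.meta["location"] == loc]
        for kind in ("area", "compliance", "distensibility"):
            r = vm.nested_f_test(loc_series, kind)
            rows.append({
                "location": loc, "curve_kind": kind,
                "f_statistic": r.f_statistic, "df_num": r.df_num,
                "df_den": r.df_den, "p_value": r.p_value,
                "significant": r.p_value <= ALPHA,
            })
    cc = pd.DataFrame(rows)
    cc.to_csv(OUT / "curve_comparisons.csv", index=False)
    print("nested F-tests (age effect per location x curve kind):")
    print(cc.round(4).to_string(index=False))
    sig = cc[cc["significant"]]
    print(f"\n{len(sig)} of {len(cc)} comparisons significant at {ALPHA}")

    anovas = vm.anova_summary_metrics(fits, alpha=ALPHA)
    arows = []
    for outcome, res in anovas.items():
        for factor, r in res.effects.iterrows():
            arows.append({"outcome": outcome, "factor": factor,
                          "F": r["F"], "p_value": r["p_value"]})
        if res.letters:
            print(f"\n{outcome} location letters: {res.letters}")
    pd.DataFrame(arows).to_csv(OUT / "metric_anova.csv", index=False)

    for kind in ("area", "compliance", "distensibility"):
        plot_curve_families(series, kind, OUT / f"curves_{kind}.png")
    print(f"\nwrote {OUT / 'curve_comparisons.csv'}, metric_anova.csv, figures")


if __name__ == "__main__":
    main()
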