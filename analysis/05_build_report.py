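#!/usr/bin/env python
"""Assemble the final human-readable summary.

Collects the fitted summary metrics, curve comparisons, metric ANOVA,
histology aggregates and histology ANOVA into results/report.md plus the
machine-readable CSV companions.
"""

import pandas as pd
from pathlib import Path

import vesselmech as vm

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    fits = pd.read_csv(OUT / "fit_summary.csv")
    overall = pd.read_csv(OUT / "histology_overall.csv")
    meas = vm.read_inflation_csv(OUT / "inflation_measurements.csv")
    series = vm.series_from_table(meas)

    comparisons = []
    for loc in sorted({s.meta["location"] for s in series}):
        loc_series = [s for s in series if s.meta["location"] == loc]
        for kind in ("area", "compliance", "distensibility"):
            comparisons.append(vm.nested_f_test(loc_series, kind))

    text = vm.report(
        fit_summary=fits,
        curve_comparisons=comparisons,
        metric_anovas=vm.anova_summary_metrics(fits),
        histo_overall=overall,
        histo_anovas=vm.histo_anova(overall),
        output_dir=OUT,
    )
    print(text[:2000])
    print("...")
    print(f"full report at {OUT / 'report.md'}")


if __name__ == "__main__":
    main()
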