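#!/usr/bin/env python
"""Aggregate histology frames and test age/location effects.

Averages the five frames per slide layer, thickness-weights the two media
layers into overall wall metrics (intima-media thickness; overall area% of
elastin, smooth-muscle actin, collagen I and III), then runs the univariate
ANOVA with horse as random factor and age/location as fixed factors, with
Bonferroni-corrected location contrasts. Writes
results/histology_overall.csv and results/histo_anova.csv.
"""

import pandas as pd
from pathlib import Path

import vesselmech as vm

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    frames = vm.read_histology_csv(OUT / "histology_frames.csv")
    overall = vm.aggregate_histology(frames)
    overall.to_csv(OUT / "histology_overall.csv", index=False)

    print("per-location group means (young / old):")
    for metric in ("thickness_um", "elastin", "sma", "col1", "col3"):
        tab = overall.groupby(["location", "age_group"])[metric].mean().unstack()
        print(f"\n{metric}:")
        print(tab.round(1))

    anovas = vm.histo_anova(overall)
    rows = []
    for outcome, res in anovas.items():
        if res.degenerate:
            rows.append({"outcome": outcome, "note": res.note})
            continue
        for factor, r in res.effects.iterrows():
            rows.append({"outcome": outcome, "factor": factor, "F": r["F"],
                         "df_num": r["df_num"], "df_den": r["df_den"],
                         "p_value": r["p_value"]})
        age_p = res.effects.loc["age", "p_value"]
        print(f"\n{outcome}: age p = {age_p:.4f}"
              f"{' *' if age_p <= 0.05 else ''}; letters {res.letters}")
    pd.DataFrame(rows).to_csv(OUT / "histo_anova.csv", index=False)
    print(f"\nwrote {OUT / 'histology_overall.csv'}, histo_anova.csv")


if __name__ == "__main__":
    main()
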