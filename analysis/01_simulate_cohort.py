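#!/usr/bin/env python
"""Simulate a reference cohort: 6 young vs 14 old horses.

Generates the inflation-extension measurement table (4 tested vessel
locations x 10-point pressure grid x triplicate diameters, 2% measurement
noise, ~10% of old-group samples ruptured at 250 mmHg) and the histology
frame table (7 locations x layers x 4 stains x 5 frames), both anchored to
the reference group means. Writes the tables plus the ground-truth
parameters under results/.

Usage: python analysis/01_simulate_cohort.py [--seed 1]
"""

import argparse
from pathlib import Path

import vesselmech as vm

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    OUT.mkdir(exist_ok=True)
    meas, truth = vm.gen_inflation_dataset(
        None, 6, 14, seed=args.seed, rupture_fraction=0.10
    )
    histo = vm.gen_histology_dataset(None, 6, 14, seed=args.seed + 500_000)

    meas.to_csv(OUT / "inflation_measurements.csv", index=False)
    truth.to_csv(OUT / "inflation_truth.csv", index=False)
    histo.to_csv(OUT / "histology_frames.csv", index=False)

    n_rupt = int(truth["ruptured"].sum())
    print(f"cohort: {truth['horse_id'].nunique()} horses, "
          f"{len(truth)} vessel samples, {len(meas)} diameter readings")
    print(f"ruptured samples (old group, truncated at 250 mmHg): {n_rupt}")
    print(f"histology frames: {len(histo)} rows")
    print(f"wrote {OUT / 'inflation_measurements.csv'}")


if __name__ == "__main__":
    main()
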