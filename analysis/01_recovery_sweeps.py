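#!/usr/bin/env python
"""Unique-read recovery under across-lane splitting.

Sweeps the number of splits k, the split proportions and the GT sequencing
depth on a bulk-like synthetic library, comparing Monte-Carlo recovery
ratios with the exact hypergeometric expectation.  Writes the per-iteration
sweep and the aggregate summary under results/.
"""

import pandas as pd

from lanesplit.experiments import ExperimentConfig, run_experiment

OUT = "results/recovery"
SEED = 20


def main() -> None:
    cfg = ExperimentConfig(
        scenario="bulk",
        out_dir=OUT,
        seed=SEED,
        k_values=(1, 2, 3, 4, 5, 10),
        proportion_grid=tuple((round(p, 2), round(1 - p, 2)) for p in
                              (0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95)),
        depth_fractions=(1.0, 0.5, 0.25),
        iterations=10,
    )
    run_experiment(cfg)
    df = pd.read_csv(f"{OUT}/bulk_sweep.tsv", sep="\t")
    full = df[df["depth_fraction"] == 1.0]

    k_means = full[full["grid_point"].str.startswith("k=")].groupby("k")["recovery"].mean()
    print("mean recovery by number of splits (full depth):")
    print(k_means.round(4).to_string())
    print("-> recovery decreases monotonically with k; k=1 is the identity split")

    props = full[~full["grid_point"].str.startswith("k=")]
    p_means = props.groupby("grid_point", sort=False)["recovery"].mean()
    print("\nmean recovery by split proportions (k=2):")
    print(p_means.round(4).to_string())
    print("-> minimum at 50-50, rising as the larger lane approaches 100%")

    d_means = df[df["grid_point"] == "k=2"].groupby("depth_fraction")["recovery"].mean()
    print("\nmean recovery at k=2 by GT depth fraction:")
    print(d_means.round(4).to_string())
    print("-> shallower GT libraries lose proportionally more diversity")


if __name__ == "__main__":
    main()
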