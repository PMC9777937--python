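#!/usr/bin/env python
"""Cluster, marker and island stability in split single-cell libraries.

Runs the sc scenario: a clustered count matrix with a driver-gene island is
split at the count level (k=2, 3 iterations); clustering, markers and the
within-island nearest-neighbour fraction are recomputed on every split
sample and compared with GT, including the driver-gene-removal control.
"""

import pandas as pd

from lanesplit.experiments import ExperimentConfig, run_experiment

OUT = "results/single_cell"
SEED = 77


def main() -> None:
    cfg = ExperimentConfig(
        scenario="sc", out_dir=OUT, seed=SEED, k_values=(2,), iterations=3
    )
    run_experiment(cfg)
    df = pd.read_csv(f"{OUT}/sc_sweep.tsv", sep="\t")
    print("per-iteration concordance of the split analyses with GT:")
    cols = ["iteration", "comembership_mean", "marker_jsi_mean", "island_nn_s"]
    print(df[cols].round(3).to_string(index=False))
    print(f"\nisland within-NN fraction on GT: {df['island_nn_gt'].iloc[0]:.3f}")
    print(f"same with the driver gene removed: {df['island_nn_gt_nodriver'].iloc[0]:.3f}")
    print(
        "-> the island is discrete only while its driver gene is in the gene set; "
        "splitting erodes marker overlap and the island's separation"
    )


if __name__ == "__main__":
    main()
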