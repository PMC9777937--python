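#!/usr/bin/env python
"""Differential-expression concordance between GT and split analyses.

Builds a two-condition bulk experiment (2 vs 2 replicates, planted 4-fold
effects), applies count-level splitting to every replicate, and compares the
DE calls of the GT analysis with those of the split analyses: shared calls,
comparison-specific false positives/negatives, and fold-change drift.
"""

from pathlib import Path

import pandas as pd

from lanesplit.quantcov import de_concordance, quantile_normalize, simple_de
from lanesplit.splitsim import SplitSpec, split_count_matrix
from lanesplit.synthdata import gen_de_dataset

OUT = Path("results/de_concordance")
SEED = 4
N_SIMS = 4


def run_de(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    # point-null test + post-hoc fold cutoff, mirroring the classic DE
    # pipeline whose borderline calls are the ones splitting destabilises
    cm = quantile_normalize(pd.concat([a, b], axis=1))
    return simple_de(cm[a.columns], cm[b.columns], fold_null=0.0)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    group_a, group_b, planted = gen_de_dataset(seed=SEED)
    gt_de = run_de(group_a, group_b)
    print(f"GT analysis: {int(gt_de['de'].sum())} DE genes "
          f"({len(planted)} planted 4-fold effects)")

    sims = []
    for i in range(N_SIMS):
        spec = SplitSpec.equal(2, seed=SEED * 1000 + i)
        sa = pd.concat(
            [split_count_matrix(group_a[[c]], spec, 0) for c in group_a.columns], axis=1
        )
        sb = pd.concat(
            [split_count_matrix(group_b[[c]], spec, 0) for c in group_b.columns], axis=1
        )
        sims.append(run_de(sa, sb))

    rep = de_concordance(gt_de, sims)
    print(f"\nDE genes in any analysis: {rep.n_de_union}; shared by all: "
          f"{rep.shared_all} ({100 * rep.shared_fraction:.1f}%)")
    print(f"false negatives (DE only in GT): {rep.false_negative}")
    print(f"false positives per split analysis: {rep.false_positive}")
    print(f"DE in every split but not GT: {rep.all_s_not_gt}")
    fp_total = sum(rep.false_positive.values())
    print(f"-> {fp_total + rep.false_negative} comparison-specific calls "
          f"({fp_total} split-specific FP, {rep.false_negative} GT-only FN): "
          "splitting makes borderline DE calls irreproducible")

    rep.pairwise_delta.to_csv(OUT / "pairwise_fc_delta.tsv", sep="\t", index=False)
    upset = pd.DataFrame(
        [
            {**dict(zip(rep.set_names, pattern)), "count": count}
            for pattern, count in sorted(rep.intersections.items(), reverse=True)
        ]
    )
    upset.to_csv(OUT / "de_upset.tsv", sep="\t", index=False)
    gt_de.to_csv(OUT / "de_table_gt.tsv", sep="\t")
    print(f"\nwrote upset table, fold-change deltas and the GT DE table to {OUT}/")


if __name__ == "__main__":
    main()
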