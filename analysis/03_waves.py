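#!/usr/bin/env python
"""Group each genotype's dynamic features into named expression waves.

Standardizes the dynamic features' time-point means and soft-clusters them
with fuzzy c-means (fuzzifier 1.25, membership threshold 0.5).  The cluster
count is chosen as the largest one with pairwise non-overlapping centroids
unless --n-waves pins it.  Writes waves_<genotype>/ (centroids, memberships,
assignment) and prints each wave's name and size.
"""

import argparse
from pathlib import Path

import pandas as pd

from wavewire import dynamics, waves
from wavewire.io import read_expression


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--n-waves", type=int, default=None,
                    help="fixed cluster count (default: select automatically)")
    ap.add_argument("--c-range", type=int, nargs=2, default=(2, 8))
    args = ap.parse_args()

    study = read_expression(args.data / "matrix.tsv", args.data / "design.tsv")
    for g in study.genotypes:
        calls = pd.read_csv(args.out / f"calls_{g}.csv", index_col=0)
        dyn = list(calls.index[calls["dynamic"]])
        means = study.time_point_means(g).loc[dyn]
        ws = waves.build_waveset(
            dynamics.standardize_rows(means), g, member_log2_means=means,
            c=args.n_waves, c_range=range(args.c_range[0], args.c_range[1] + 1),
            seed=args.seed)
        waves.save_waveset(ws, args.out / f"waves_{g}")
        sizes = ", ".join(f"{ws.names[w]}: {ws.sizes[w]}"
                          for w in range(ws.n_waves))
        unassigned = int((ws.assignment == -1).sum())
        print(f"{g}: {ws.n_waves} waves ({sizes}); {unassigned} features "
              "below the membership threshold")


if __name__ == "__main__":
    main()
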