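#!/usr/bin/env python
"""Random-forest predictor importance for group resistance.

For every functional group x stressor, a 500-tree regression forest ranks
MAT, MAP and the six stoichiometry variables as predictors of per-site
group resistance by %IncMSE (per-tree OOB permutation importance), with
response-permutation p-values (99 permutations, forest refit per
permutation).

Reads results/sites.tsv, results/group_resistance.tsv;
writes results/importance.tsv
"""

from pathlib import Path

import pandas as pd

from stoichres import permutation_significance
from stoichres.pipeline import PREDICTOR_COLUMNS
from stoichres.tables import read_site_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def main():
    sites = read_site_table(RESULTS / "sites.tsv").set_index("site_id")
    gres = pd.read_csv(RESULTS / "group_resistance.tsv", sep="\t")
    frames = []
    for k, ((group, stressor), sub) in enumerate(
            gres.groupby(["group", "stressor"])):
        y = sub.set_index("site_id")["score"]
        X = sites.loc[y.index, PREDICTOR_COLUMNS]
        res = permutation_significance(X, y.to_numpy(), n_perm=99,
                                       n_trees=500, seed=SEED + k)
        res.insert(0, "stressor", stressor)
        res.insert(0, "group", group)
        frames.append(res)
        top = res.sort_values("mpi", ascending=False).iloc[0]
        print(f"{group} x {stressor}: top predictor {top.predictor} "
              f"(MPI {top.mpi:.1f}%, normalized {top.mpi_normalized:.0f}%, "
              f"P={top.p:.2f})")
    pd.concat(frames, ignore_index=True).to_csv(
        RESULTS / "importance.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
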