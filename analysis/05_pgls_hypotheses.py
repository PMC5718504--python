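"""Phylogenetic regressions: allometry, developmental constraint, latitude.

Cleans the occurrence records, summarizes each species as its mean absolute
latitude, projects the phylogeny into the shape morphospace, and fits PGLS
regressions under BM and fixed-root OU error models for the three hypothesis
tests, comparing the error models by AIC.

Usage: python analysis/05_pgls_hypotheses.py [--data results/data]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pollenmorph import (PhyloTree, clean_occurrences, mean_abs_latitude,
                         phylomorphospace, run_hypothesis_tests)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    tree = PhyloTree.from_file(args.data / "tree.nwk")
    occ = pd.read_csv(args.data / "occurrences.csv")
    clean, removed = clean_occurrences(occ)
    lat = mean_abs_latitude(clean, species=tree.tip_labels)
    print(f"occurrences: {len(occ)} records, {len(clean)} after cleaning "
          f"({removed.to_dict()}); {lat.size} species with latitude")
    clean.to_csv(args.out / "occurrences_clean.csv", index=False)

    traits = pd.DataFrame({
        "shape_pc1_equatorial":
            pd.read_csv(args.out / "scores_equatorial.csv", index_col=0)["PC1"],
        "shape_pc1_polar":
            pd.read_csv(args.out / "scores_polar.csv", index_col=0)["PC1"],
    })
    sizes = pd.read_csv(args.data / "sizes.csv").query("view == 'polar'")
    log_len = np.log(sizes.set_index("species")["length_um"])

    coords, edges = phylomorphospace(tree, traits)
    coords.to_csv(args.out / "phylomorphospace_nodes.csv")

    rep = run_hypothesis_tests(traits, log_len, lat, tree)
    rep.to_csv(args.out / "pgls_regressions.csv", index=False)
    for test, grp in rep.groupby("test"):
        best = grp.loc[grp.AIC.idxmin()]
        print(f"[{test}] best model {best.model}: slope {best.slope:+.4f}, "
              f"AIC {best.AIC:.1f}, t = {best.t:.2f}, p = {best.p:.2g}")


if __name__ == "__main__":
    main()
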