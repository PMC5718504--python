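"""Summarize pollen size by family and test group differences.

Per-family means and SDs on the micron scale, Shapiro-Wilk normality flags,
approximate randomization tests on log-transformed sizes, and post-hoc
pairwise comparisons summarized as a compact letter display.

Usage: python analysis/03_size_statistics.py [--data results/data]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pollenmorph.sizestats import (read_sizes, summarize_size,
                                   randomization_test, posthoc_letters)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--nperm", type=int, default=9999)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = read_sizes(args.data / "sizes.csv")
    summary, normality = summarize_size(table)
    print("normality (Shapiro-Wilk on raw microns; tests below use logs):")
    print(normality.to_string(index=False))

    rows = []
    for (view, meas) in [(v, m) for v in ("polar", "equatorial")
                         for m in ("length_um", "width_um")]:
        sub = table[table.view == view]
        logv = np.log(sub[meas].to_numpy())
        fams = sub["family"].to_numpy()
        if len(set(fams)) < 2:
            continue
        p_omni = randomization_test(logv, fams, n_perm=args.nperm,
                                    seed=args.seed)
        pmat, letters = posthoc_letters(logv, fams, n_perm=args.nperm,
                                        seed=args.seed, alpha=args.alpha)
        pmat.to_csv(args.out / f"pairwise_p_{view}_{meas}.csv")
        print(f"[{view} {meas}] omnibus randomization p = {p_omni:.4g}; "
              f"letters: {letters.letters}")
        for fam, let in letters.letters.items():
            rows.append({"view": view, "measurement": meas, "family": fam,
                         "letters": let, "omnibus_p": p_omni})

    summary = summary.merge(pd.DataFrame(rows),
                            on=["view", "measurement", "family"], how="left")
    summary.to_csv(args.out / "size_summary.csv", index=False)
    normality.to_csv(args.out / "size_normality.csv", index=False)
    print(f"wrote size summary for {table.family.nunique()} families "
          f"to {args.out / 'size_summary.csv'}")


if __name__ == "__main__":
    main()
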