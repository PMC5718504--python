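"""Quantify outline shape: EFA, harmonic calibration, PCA, family MANOVA.

Reads the outlines written by 01, runs elliptic Fourier analysis per view
with normalization and asymmetric-noise removal, calibrates the harmonic
count at 99% cumulative power, builds one PCA morphospace per view, and
tests family differences on the leading principal components.

Usage: python analysis/02_outline_morphometrics.py [--data results/data]
"""

import argparse
from pathlib import Path

import pandas as pd

from pollenmorph import (read_outlines, efa_forward, remove_symmetry_component,
                         calibrate_harmonic_count, write_coefficients,
                         pca_fit, manova_groups)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--power", type=float, default=0.99)
    ap.add_argument("--sym-removal", choices=["asym", "sym", "none"],
                    default="asym")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    outlines = read_outlines(args.data / "outlines.csv",
                             args.data / "outline_meta.csv")
    mode = {"asym": "asymmetric", "sym": "symmetric", "none": None}[args.sym_removal]

    for view in ("equatorial", "polar"):
        sub = [o for o in outlines if o.view == view]
        n_max = min(32, min(len(o.points) for o in sub) // 2)
        sets = [efa_forward(o, n_max) for o in sub]
        n_harm = calibrate_harmonic_count(sets, args.power)
        sets = [efa_forward(o, n_harm) for o in sub]
        if mode:
            sets = [remove_symmetry_component(c, mode) for c in sets]
        coeff_df = write_coefficients(sets, args.out / f"coeffs_{view}.csv")

        M = pd.DataFrame([c.flatten() for c in sets],
                         index=[o.species for o in sub])
        model = pca_fit(M)
        k = min(15, model.n_components)
        scores = pd.DataFrame(model.scores[:, :k], index=M.index,
                              columns=[f"PC{i+1}" for i in range(k)])
        scores.to_csv(args.out / f"scores_{view}.csv")
        pd.DataFrame({"component": range(1, len(model.variance_fractions) + 1),
                      "variance_fraction": model.variance_fractions}).to_csv(
            args.out / f"variance_{view}.csv", index=False)

        fams = [o.family for o in sub]
        res = manova_groups(model.scores, fams, m=k, seed=0)
        pc2 = (f", PC2 {model.variance_fractions[1]:.1%}"
               if model.n_components > 1 else "")
        print(f"[{view}] {len(sub)} outlines | {n_harm} harmonics at "
              f"{args.power:.0%} power | PC1 "
              f"{model.variance_fractions[0]:.1%}{pc2} of variance")
        print(f"[{view}] family MANOVA: Pillai {res.statistic:.3f}, "
              f"F({res.df1:.0f}, {res.df2:.0f}) = {res.f_approx:.2f}, "
              f"p = {res.p:.2g} (permutation p = {res.p_permutation:.3f})")
        pd.DataFrame([{"view": view, "n_outlines": len(sub),
                       "n_harmonics": n_harm,
                       "pc1_variance": model.variance_fractions[0],
                       "pillai": res.statistic, "F": res.f_approx,
                       "df1": res.df1, "df2": res.df2, "p": res.p,
                       "p_permutation": res.p_permutation}]).to_csv(
            args.out / f"manova_{view}.csv", index=False)


if __name__ == "__main__":
    main()
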