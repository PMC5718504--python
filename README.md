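# pollenmorph

Continuous analysis of pollen morphology on time-calibrated phylogenies.

Palynology has traditionally discretized pollen into character states (size
classes, shape classes, aperture types). This package implements the
alternative: treat pollen shape and size as continuous traits, quantify
outline shape by elliptic Fourier analysis (EFA), and analyze the resulting
morphospace in an explicitly phylogenetic framework — Ornstein–Uhlenbeck
shift detection for adaptive regimes, and phylogenetic regressions for
allometry, developmental constraint and latitudinal structure. It is aimed
at evolutionary biologists working with 2-D outlines (pollen, seeds,
leaves, any closed contour) and a dated tree.

## What is inside

- **`efa`** — elliptic Fourier decomposition of closed outlines
  (coefficients *a_n, b_n, c_n, d_n* per harmonic), normalization for
  translation, rotation, scale and starting point, symmetric/asymmetric
  component removal, and harmonic-count calibration by cumulative power.
- **`morphospace`** — PCA morphospaces of the coefficients, theoretical
  shape reconstruction along components, one-way MANOVA (Pillai's trace,
  F approximation, permutation p) for group differences, and
  phylomorphospace projection (ML ancestral states under Brownian motion).
- **`sizestats`** — per-family size summaries, Shapiro–Wilk normality
  flags, approximate randomization tests (exact when enumerable), and
  compact letter displays for post-hoc comparisons.
- **`oushifts`** — detection of optimum shifts under a fixed-root OU
  process: per-edge shift design, whitened L1 path search (grouped across
  traits), pBIC model selection, residual-bootstrap support, and
  convergent-regime collapse.
- **`pgls`** / **`occurrences`** — PGLS under BM and fixed-root OU error
  models with AIC comparison; occurrence-record cleaning and per-species
  mean absolute latitude.
- **`simulate`** — birth–death trees, OU traits with planted shifts,
  parametric pollen-like outline families, and occurrence records with a
  known latitude–trait relation, so the whole pipeline is testable with
  known ground truth.

The model at the core: a trait $y$ on a tree of depth $T$ evolves as
$dy = \alpha(\theta(t) - y)\,dt + \sigma\,dW$, where the optimum $\theta$
jumps at a set of edges (regimes). Tip expectations are linear in the
per-edge shift sizes — tip $i$ feels $1 - e^{-\alpha(T - t_s)}$ of a shift
on an ancestral edge starting at age $t_s$ — so candidate configurations
can be proposed by an L1-penalized regression on covariance-whitened data
and selected with a phylogenetic BIC.

## Worked example

The `analysis/` drivers run a complete synthetic study (a 64-species clade,
116 Myr deep, with one planted regime shift):

```bash
python analysis/01_simulate_dataset.py --seed 42
python analysis/02_outline_morphometrics.py
python analysis/03_size_statistics.py
python analysis/04_shift_detection.py --bootstrap 50
python analysis/05_pgls_hypotheses.py
```

which prints, among other things:

```
planted optimum shift above edge 68 (13 species, oblate_triangular)
[polar] family MANOVA: Pillai 0.904, F(1, 62) = 581.41, p = 3.4e-33 (permutation p = 0.001)
[joint] 1 shifts (pBIC), 2 regimes after convergence collapse; alpha = 0.8616/Myr
  edge 68: support 100% | pc1_equatorial=+0.059, pc1_polar=-0.015, log_length=-0.853, log_width=-0.828
[latitude_size] best model OUfixedRoot: slope -0.0764, AIC 6.1, t = -12.09, p = 5.8e-18
```

Reading this: the families separate cleanly in the shape morphospace
(MANOVA); the joint shift search on the four traits recovers exactly the
planted edge with 100% bootstrap support — the shifted clade evolved
smaller grains (negative log-size shifts) with a different outline; and the
PGLS regression recovers the planted negative latitude–size relation under
the OU error model that the AIC comparison prefers. Tables land under
`results/`.

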