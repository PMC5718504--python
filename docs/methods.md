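# Methods

This note documents the statistical machinery, the defaults and the design
choices made where the methodology left room, in enough detail to audit or
re-implement any step.

## Outline quantification (EFA)

A closed outline is an ordered polygon, normalized to counterclockwise
orientation on ingest (otherwise the signs of *c_n, d_n* flip with point
order). The elliptic Fourier coefficients are computed from the exact
piecewise-linear segment sums over chords Δx_p, Δy_p with chord lengths
Δt_p and period T equal to the perimeter — no resampling is applied, so the
decomposition is exact for the polygon as given.

Normalization proceeds in the standard order: drop the translation terms
A0, C0; rotate the starting point by the first-harmonic phase θ₁; rotate
the coordinate frame by the first-ellipse orientation ψ₁; divide by the
first-ellipse semi-major magnitude. Two conventions needed fixing:

- θ₁ is defined modulo π; the two candidates differ by the sign of every
  even harmonic. We keep the candidate whose first non-negligible
  (>1e−9) even-harmonic coefficient is positive — deterministic and
  invariant to the starting point.
- For nearly circular first ellipses ψ₁ is ill-conditioned and the whole
  normalization becomes unstable. This is a property of the method, not
  of the implementation: shapes with 3-fold symmetry (triangular polar
  outlines) have an almost-circular first ellipse. The synthetic polar
  archetypes therefore carry a mild anisotropy (stretch 1.15) that anchors
  the axis, which is also more faithful to real grains.

A noteworthy exact result used in the tests: the chord-length (≈
arc-length) parameterization that defines EFA is *not* the ellipse's own
parameter, so the first harmonic of a 2:1 ellipse has axis ratio 0.58686
(frozen from dense numerical quadrature), not 0.5. The naive 0.5 applies
only to curves sampled uniformly in the ellipse parameter.

Symmetry-component removal operates on normalized coefficients, where the
first-ellipse major axis is the symmetry axis: the asymmetric block is
(b_n, c_n), the symmetric block (a_n, d_n). Which views receive which
removal is configurable; the pipeline default applies asymmetric-noise
removal to both views. Harmonic-count calibration returns the smallest N
whose mean cumulative power fraction (power P_n = (a²+b²+c²+d²)/2, all
harmonics counted from n = 1) reaches the threshold, default 0.99. On the
synthetic archetypes, which are deliberately low-order, this picks very
small N; on digitized pollen it lands near 32.

## Morphospace

PCA is computed on column-centered, unscaled coefficients by SVD —
coefficients share a scale after EFA size normalization, so correlation
PCA is unnecessary and not used by default. Component signs are fixed by
making each component's largest-magnitude loading positive, so scores are
reproducible across platforms. The MANOVA uses Pillai's trace with its
standard F approximation (cross-checked against statsmodels in the tests)
plus a label-permutation p for small samples; Wilks' lambda is reported
alongside. Phylomorphospace ancestral states are ML estimates under BM
computed by Gaussian message passing on the tree (two passes, linear
time), which equals the dense GLS solution; a stochastic-mapping
alternative was rejected as non-deterministic.

## Size statistics

Summaries are reported on the raw micron scale; all tests run on
log-transformed values (pollen sizes are strongly right-skewed;
Shapiro–Wilk is advisory only). The omnibus k-group statistic is the
one-way F; pairwise tests use |mean difference|. Label permutations are
enumerated exhaustively when the number of distinct assignments is at most
`n_perm` (exact p = hits / total with the observed assignment included);
otherwise Monte-Carlo with the plus-one correction (1 + hits)/(1 + n_perm),
so p is never zero. Defaults: n_perm = 9999, Benjamini–Hochberg adjustment,
α = 0.05; the letter display uses insert-and-absorb, so letter sharing is
exactly equivalent to adjusted p ≥ α.

## OU shift detection

Covariances. The fixed-root OU tip covariance is
V_ij = exp(−α d_ij)(1 − exp(−2α t_ij))/(2α) with t_ij the root–MRCA time
and d_ij the patristic distance; α = 0 gives the BM matrix t_ij. On an
ultrametric tree V_OU is a scaled BM covariance on a time-rescaled tree
(h(t) = (e^{2αt} − 1)/(2α), overall factor e^{−2αT}), so log-determinants
and quadratic forms are evaluated by a linear-time pruning pass
(generalized three-point structure); a dense Cholesky route exists for
cross-checking. Trees failing ultrametricity by more than 1e−6 relative
are minimally extended at the tips and flagged, since dated supertrees
routinely carry rounding error.

Shift model. A shift β on edge e moves the optimum from the parent end of
the edge onward; tip i descending from e has mean contribution
β(1 − e^{−α(T − t_start)}). In the BM limit the optimum has no pull, so
the design column degenerates to the 0/1 descent indicator (a mean jump).
One of the two root-child edges is excluded from the candidate set (its
column is collinear with the intercept plus its sibling's column); the
convention reports a root-spanning shift on the smaller clade.

Search. For each α on a grid (20 log-spaced values of αT in [0.01, 50]
plus the BM limit), traits and design are whitened by the inverse Cholesky
factor of V(α); an L1 path over the candidate columns — multi-task
(grouped L2,1) across traits, so a shift is shared by all traits in a
joint analysis — proposes support sets; every singleton is additionally
scanned in closed form (a lone true shift can otherwise only enter the
path accompanied by correlated competitors); every candidate is refit by
ML and scored; the best support per α is pruned by backward elimination,
and the final α is refined by a bounded 1-D search. Traits are scaled to
unit variance for the search and effects are reported on original scales.

Model selection. BIC counts q(s + 3) parameters (per trait: s shift
sizes, intercept, σ², α). The phylogenetic BIC implemented here is minus
twice the exact log marginal likelihood of the configuration — flat prior
on the regression block (p = s + 1 coefficients), Jeffreys prior on each
trait's σ², both integrated out in closed form — plus search terms:

pBIC = Σ_traits [ logdet V + max(logdet X_Sᵀ V⁻¹ X_S, p log n)
                  + (n − p) log(π RSS) − 2 log Γ((n − p)/2) ]
       + 2 log C(E, s) + log n

with X_S the intercept-plus-shifts design, RSS the whitened residual sum
of squares and E the number of candidate edges. The configuration-count
term charges the search over shift placements; the design determinant
prices a shift by how identifiable it is, floored at p log n so nearly
collinear configurations are not subsidized by the flat directions of an
improper prior; and the (n − p) log RSS data term — rather than the ML
n log σ̂² — cannot diverge as a configuration approaches interpolation,
which is what lets near-saturated shift sets beat the empty model on pure
noise under naive BIC-type scoring when s is comparable to n. The exact
penalty of the originally published criterion is defined in its own
methods paper; this variant is documented here precisely, and plain BIC
is available as a reference criterion.

Bootstrap. Residuals about the fitted tip means are whitened to
uncorrelated standardized form, resampled with replacement (rows jointly
across traits), colored back, added to the fitted means, and the full
search is rerun per replicate; an edge's support is the fraction of
replicates containing it. Default 100 replicates; figure annotations use
a 50% threshold.

Convergence collapse. Tip means are re-parameterized by regime optima
(weights integrate e^{−α(T−t)} over the painted path; the root's point
mass goes to the background regime; the BM limit is the one-hot regime
indicator). Pairs of regimes are greedily merged — columns summed, GLS
refit, rescored with the same criterion, keeping the placement-count term
at the original edge count since merging changes free optima, not shift
placements — while the score improves. Merged regimes may be
non-adjacent, which is convergence.

## PGLS

GLS with V from BM or fixed-root OU; for OU, α is profiled on the same
grid with a bounded refinement (the lower bound excludes 0 — BM is a
separate model, compared by AIC with ties to BM). σ² takes its ML closed
form; AIC = 2k − 2 logL with k = 3 (BM) or 4 (OU). The slope t-test uses
the unbiased residual variance and n − 2 degrees of freedom, treating
variance parameters as nuisance — stated explicitly so p-values are
comparable across implementations. Species matching normalizes names
(trim, case-fold, underscores ↔ spaces); synonym resolution is out of
scope. Occurrence cleaning is deliberately minimal and rule-listed (exact
within-species duplicates, the (0,0) point, out-of-bounds coordinates,
optional per-species bounding box), each rule individually switchable.

## Synthetic data: what it emulates, and what it does not

- Trees: birth–death conditioned on n extant tips (dendropy), clock run
  forward by one waiting time so the n-th birth leaves no zero pendant
  edges, rescaled to 116 Myr — the crown scale of the motivating clade —
  so α and σ² magnitudes stay interpretable. Default 64 tips, Yule.
- Traits: exact OU transition sampling branch by branch; planted shifts
  change θ at chosen edges (BM limit: mean jumps). Defaults α = 0.05/Myr
  (phylogenetic half-life ≈ 14 Myr, typical of regime-shift analyses) and
  σ² = 0.1, giving stationary SD 1 so shift sizes read directly in
  stationary SDs.
- Outlines: polar view r(φ) = 1 + c cos 3φ (three-fold lobe symmetry
  mimicking tricolpate grains; c > 0 gently trilobed, c < 0 triangular
  with concave sides) with stretch 1.15; equatorial view ellipses (aspect
  1.6 prolate vs 0.7 oblate); per-outline Gaussian jitter (SD 0.03) on
  the archetype parameter; 256 points.
- Occurrences: per-species center latitude linear in a trait plus noise
  (defaults: intercept 25°, slope −8°/unit, noise SD 3°, within-species
  scatter SD 2°), longitudes uniform, latitudes clipped to ±90.

Planted-edge choice: shifts are planted on the internal edge maximizing
the GLS noncentrality of a unit shift at the generating parameters.
Detectability is governed by the number of quasi-independent descendant
lineages and the design's distinctness from drift — a shift on a basal
long-stem edge is nearly confounded with BM drift however long the edge —
so "most detectable edge" is the meaningful notion of a well-posed
recovery experiment; basal-edge confounding is a known identifiability
limit of the method, not of this implementation.

What passing tests do not show: synthetic outlines are low-order
parametric curves without digitization noise, real grains vary within
species (one outline per species here), the latitude link is generated as
exactly linear, and no taxonomic error is simulated. Reproducing the
original study's archive-dependent numbers additionally requires its
deposited outlines, dated trees and cleaned occurrence set.

## Problem sizes and numerics

Simulation-backed checks use 64-tip trees with 20 replicates (null
false-positive control, 4-stationary-SD recovery with 50 bootstrap
replicates), 100-tip trees for PGLS recovery (20 replicates), 100 random
instances for the likelihood oracle (≤10 tips, tolerance 1e−6), 100
shapes for EFA invariance (tolerance 1e−6), and 500 replicates for
randomization-test calibration. Degenerate inputs are errors with named
offenders (missing metadata, unmatched tips, constant predictors,
zero-perimeter outlines); near-singular shift designs score +∞ rather
than propagating unstable determinants; permutation p-values use the
plus-one correction except in exact exhaustive mode.
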