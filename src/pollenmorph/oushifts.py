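"""Detection of adaptive-optimum shifts on a time tree under an OU process.

Trait means under a fixed-root Ornstein-Uhlenbeck process with optimum shifts
are linear in the per-edge shift sizes, so shift configurations can be
searched with an L1 penalty: for each candidate selection strength alpha the
traits and the per-edge shift design are whitened by the inverse Cholesky
factor of the OU covariance, an L1-penalized path over the whitened columns
proposes nested candidate configurations (the penalty is grouped across
traits, so a shift is shared by all traits in a joint analysis), and every
candidate is refit by maximum likelihood and scored with an information
criterion.  The default criterion is a phylogenetic BIC (pBIC) that replaces
the naive per-shift ``log n`` penalty with a configuration-count term plus the
log-determinant of the whitened design's Gram matrix, which controls the
false-shift rate far better than AIC-type criteria.  Bootstrap support comes
from resampling phylogenetically whitened standardized residuals, and similar
regimes can afterwards be collapsed into convergent regimes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb, lgamma, log
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from sklearn.linear_model import lasso_path

from .trees import PhyloTree, ou_covariance, ou_quadratic_forms, shift_design_matrix

__all__ = ["OUModel", "ShiftFit", "CandidateFit", "ou_loglik", "detect_shifts",
           "score_criterion", "bootstrap_support", "collapse_convergent",
           "regime_painting", "ShiftWorkspace"]

TWO_PI = 2 * np.pi


@dataclass
class OUModel:
    alpha: float                  # selection strength per Myr, >= 0
    sigma2: np.ndarray            # diffusion variance per trait, > 0
    intercept: np.ndarray         # ancestral optimum per trait

    def __post_init__(self) -> None:
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        self.intercept = np.atleast_1d(np.asarray(self.intercept, dtype=float))
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be > 0")

    @property
    def stationary_sd(self) -> np.ndarray:
        if self.alpha == 0:
            return np.full_like(self.sigma2, np.inf)
        return np.sqrt(self.sigma2 / (2 * self.alpha))


@dataclass
class CandidateFit:
    """A shift configuration refit by ML at a fixed alpha (internal scale)."""

    shift_edges: tuple[int, ...]
    alpha: float
    beta: np.ndarray              # (s + 1, q): intercept row then shift rows
    sigma2: np.ndarray            # (q,) ML residual diffusion
    loglik: float
    gram_logdet: float            # log det of whitened [1 | X_S] Gram
    n: int
    q: int
    n_candidate_edges: int


@dataclass
class ShiftFit:
    shift_edges: tuple[int, ...]
    betas: np.ndarray             # (s, q) optimum shifts, original trait scale
    model: OUModel
    regimes: np.ndarray           # regime id per node (root regime 0)
    optima: np.ndarray            # (n_regimes, q), original trait scale
    loglik: float
    score: float
    criterion: str
    trait_names: list[str] = field(default_factory=list)
    supports: dict[int, float] = field(default_factory=dict)
    max_shifts: int = 50

    @property
    def n_shifts(self) -> int:
        return len(self.shift_edges)


def ou_loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray, alpha: float,
              sigma2: float, tree: PhyloTree, method: str = "tree") -> float:
    """Log-likelihood of traits ~ N(X beta, sigma2 * V_OU(alpha)).

    ``method='tree'`` evaluates the quadratic form and determinant by the
    linear-time pruning pass; ``method='dense'`` builds the covariance and
    uses a Cholesky solve.  Both agree to numerical precision.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    r = y - X @ np.atleast_1d(beta)
    n = tree.n_tips
    if method == "tree":
        logdet, Q = ou_quadratic_forms(tree, r[:, None], alpha)
        quad = float(Q[0, 0])
    elif method == "dense":
        V = ou_covariance(tree, alpha)
        try:
            L = linalg.cholesky(V, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError("singular OU covariance") from exc
        w = linalg.solve_triangular(L, r, lower=True)
        logdet = 2 * float(np.sum(np.log(np.diag(L))))
        quad = float(w @ w)
    else:
        raise ValueError("method must be 'tree' or 'dense'")
    return -0.5 * (n * log(TWO_PI * sigma2) + logdet + quad / sigma2)


# -- workspace ---------------------------------------------------------------

def _alpha_grid(T: float, n_points: int = 20) -> np.ndarray:
    """Profiling grid: log-spaced alpha*T in [0.01, 50] plus the BM limit."""
    return np.concatenate([[0.0], np.geomspace(0.01, 50.0, n_points) / T])


class ShiftWorkspace:
    """Per-(tree, alpha-grid) factorizations reused across repeated searches.

    Stores, for each grid alpha, the Cholesky factor of the OU covariance,
    the whitened intercept and candidate shift columns, and the covariance
    log-determinant.  Building it once and passing it to ``detect_shifts``
    makes residual-bootstrap loops cheap.
    """

    def __init__(self, tree: PhyloTree, alphas: np.ndarray | None = None):
        self.tree = tree
        T = tree.total_depth
        self.alphas = _alpha_grid(T) if alphas is None else np.asarray(alphas)
        self.candidate_edges = self._pick_candidates(tree)
        self.entries: dict[float, dict] = {}
        for a in self.alphas:
            self.entries[float(a)] = self._build_entry(float(a))

    @staticmethod
    def _pick_candidates(tree: PhyloTree) -> np.ndarray:
        """All edges except one root child (its column is collinear with the
        intercept plus the sibling's column); the root child with the larger
        clade is dropped, so a root-spanning shift is reported on the smaller
        clade."""
        D = tree.descent_matrix()
        root_children = tree.children[tree.root]
        drop = max(root_children, key=lambda v: (D[:, v].sum(), v))
        return np.array([e for e in tree.edges if e != drop])

    def _build_entry(self, alpha: float) -> dict:
        tree = self.tree
        V = ou_covariance(tree, alpha)
        L = linalg.cholesky(V, lower=True)
        logdet = 2 * float(np.sum(np.log(np.diag(L))))
        Xfull = shift_design_matrix(tree, alpha)
        edge_col = {int(e): i for i, e in enumerate(tree.edges)}
        Xc = Xfull[:, [edge_col[int(e)] for e in self.candidate_edges]]
        ones = np.ones((tree.n_tips, 1))
        W0 = linalg.solve_triangular(L, ones, lower=True).ravel()
        Wc = linalg.solve_triangular(L, Xc, lower=True)
        return {"alpha": alpha, "L": L, "logdet": logdet,
                "Xc": Xc, "W0": W0, "Wc": Wc}

    def entry(self, alpha: float) -> dict:
        key = float(alpha)
        if key not in self.entries:
            self.entries[key] = self._build_entry(key)
        return self.entries[key]


# -- scoring -----------------------------------------------------------------

def score_criterion(fit: CandidateFit, criterion: str = "pBIC") -> float:
    """Information-criterion score of a refit configuration (lower is better).

    BIC counts q(s + 3) parameters (per trait: s shift sizes, intercept,
    sigma2 and alpha).  pBIC is minus twice the log marginal likelihood of
    the configuration under flat priors on the regression block and a
    Jeffreys prior on each trait's sigma2, plus a configuration-count term
    ``2 log C(E, s)`` for the search over shift placements and ``log n`` for
    the profiled alpha.  Integrating beta and sigma2 out exactly gives, per
    trait,

        logdet V + logdet(X_S' V^-1 X_S) + (n - p) log(pi RSS)
                 - 2 log Gamma((n - p) / 2),         p = s + 1,

    whose data term (n - p) log RSS cannot diverge as the fit approaches
    interpolation — an ML-based ``n log sigma2`` data term would, letting
    near-saturated configurations beat the empty model on pure noise.  The
    design log-determinant is floored at p log n so nearly collinear
    (weakly identifiable) configurations are not subsidized by the flat
    directions of an improper prior.
    """
    n, q, s = fit.n, fit.q, len(fit.shift_edges)
    if criterion == "BIC":
        return -2.0 * fit.loglik + q * (s + 3) * log(n)
    if criterion == "pBIC":
        p = s + 1
        if not np.isfinite(fit.gram_logdet) or n - p < 2:
            return np.inf
        # recover q * logdet(V) from the stored ML log-likelihood
        logdetV_q = (-2.0 * fit.loglik
                     - float(np.sum(n * np.log(TWO_PI * fit.sigma2))) - q * n)
        rss = fit.sigma2 * n
        data = float(np.sum((n - p) * np.log(np.pi * rss))) \
            - 2 * q * lgamma((n - p) / 2)
        det_term = q * max(fit.gram_logdet, p * log(n))
        return (logdetV_q + det_term + data
                + 2 * log(comb(fit.n_candidate_edges, s)) + log(n))
    raise ValueError("criterion must be 'pBIC' or 'BIC'")


def _refit(ws: ShiftWorkspace, alpha: float, cols: Sequence[int],
           Ys: np.ndarray, Yw: np.ndarray | None = None) -> CandidateFit:
    """ML refit of a configuration (columns into ws.candidate_edges) at alpha."""
    ent = ws.entry(alpha)
    n, q = Ys.shape
    if Yw is None:
        Yw = linalg.solve_triangular(ent["L"], Ys, lower=True)
    W = np.column_stack([ent["W0"], ent["Wc"][:, list(cols)]])
    B, _, rank, _ = np.linalg.lstsq(W, Yw, rcond=None)
    resid = Yw - W @ B
    rss = np.sum(resid ** 2, axis=0)
    if rank < W.shape[1] or np.any(rss <= 0):
        gram_logdet = -np.inf
    else:
        sign, gram_logdet = np.linalg.slogdet(W.T @ W)
        if sign <= 0:
            gram_logdet = -np.inf
    sigma2 = np.maximum(rss / n, 1e-300)
    loglik = float(np.sum(-0.5 * (n * np.log(TWO_PI * sigma2)
                                  + ent["logdet"] + n)))
    edges = tuple(int(ws.candidate_edges[c]) for c in cols)
    return CandidateFit(shift_edges=edges, alpha=alpha, beta=B, sigma2=sigma2,
                        loglik=loglik, gram_logdet=float(gram_logdet),
                        n=n, q=q, n_candidate_edges=len(ws.candidate_edges))


def _best_singleton(ent: dict, Yw: np.ndarray) -> int | None:
    """Column index minimizing the total whitened RSS among 1-shift models.

    Closed-form 2x2 regressions [intercept, column] over all candidate
    columns at once; the winner is refit and scored exactly by the caller.
    """
    W0, Wc = ent["W0"], ent["Wc"]
    g00 = float(W0 @ W0)
    g0j = W0 @ Wc                       # (E,)
    gjj = np.sum(Wc ** 2, axis=0)       # (E,)
    b0 = W0 @ Yw                        # (q,)
    bj = Wc.T @ Yw                      # (E, q)
    det = g00 * gjj - g0j ** 2
    ok = det > 1e-12 * g00 * np.maximum(gjj, 1e-300)
    if not np.any(ok):
        return None
    # solve the 2x2 normal equations per column
    c0 = (gjj[:, None] * b0[None, :] - g0j[:, None] * bj) / det[:, None]
    cj = (g00 * bj - g0j[:, None] * b0[None, :]) / det[:, None]
    yty = np.sum(Yw ** 2, axis=0)       # (q,)
    rss = yty[None, :] - c0 * b0[None, :] - cj * bj
    total = np.where(ok, np.sum(np.log(np.maximum(rss, 1e-300)), axis=1), np.inf)
    return int(np.argmin(total))


def _path_supports(ws_entry: dict, Ys_w: np.ndarray, max_shifts: int,
                   n_path: int = 50) -> list[tuple[int, ...]]:
    """Candidate column sets along the (grouped) L1 path at one alpha."""
    W0 = ws_entry["W0"]
    Wc = ws_entry["Wc"]
    proj = W0 / (W0 @ W0)
    Xr = Wc - np.outer(W0, proj @ Wc)
    Yr = Ys_w - np.outer(W0, proj @ Ys_w)
    y_in = Yr[:, 0] if Yr.shape[1] == 1 else Yr
    with warnings.catch_warnings():
        # supports (not coefficient values) are consumed downstream, so the
        # occasional unconverged path endpoint is immaterial
        warnings.simplefilter("ignore")
        _, coefs, _ = lasso_path(Xr, y_in, alphas=n_path, eps=5e-4,
                                 max_iter=2000)
    if coefs.ndim == 3:                     # multi-task: (targets, feat, lam)
        active = np.abs(coefs).sum(axis=0) > 0
    else:
        active = np.abs(coefs) > 0
    seen, out = set(), []
    for j in range(active.shape[1]):
        cols = tuple(np.flatnonzero(active[:, j]))
        if 0 < len(cols) <= max_shifts and cols not in seen:
            seen.add(cols)
            out.append(cols)
    return out


# -- main search --------------------------------------------------------------

def _prepare_traits(traits, tree: PhyloTree) -> tuple[np.ndarray, list[str]]:
    if isinstance(traits, pd.Series):
        traits = traits.to_frame()
    if isinstance(traits, pd.DataFrame):
        idx = {str(k).strip().casefold().replace("_", " "): k
               for k in traits.index}
        Y = np.empty((tree.n_tips, traits.shape[1]))
        unmatched = []
        for i, lab in enumerate(tree.tip_labels):
            key = str(lab).strip().casefold().replace("_", " ")
            if key in idx:
                Y[i] = traits.loc[idx[key]].to_numpy(float)
            else:
                unmatched.append(lab)
        if unmatched:
            raise KeyError(f"tips without trait values: {unmatched}")
        return Y, list(map(str, traits.columns))
    Y = np.asarray(traits, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != tree.n_tips:
        raise ValueError("trait rows must equal the number of tips")
    return Y, [f"trait{j+1}" for j in range(Y.shape[1])]


def detect_shifts(traits, tree: PhyloTree, max_shifts: int = 50,
                  criterion: str = "pBIC", standardize: bool = True,
                  workspace: ShiftWorkspace | None = None,
                  refine_alpha: bool = True) -> ShiftFit:
    """Best shift configuration by L1 path search + criterion selection.

    For every alpha on the profiling grid the whitened traits are regressed
    on the whitened candidate shift columns with an L1 path (grouped over
    traits for multivariate input); every support set along the path is refit
    by ML and scored; the best-scoring configuration is then pruned by
    backward elimination and its alpha refined by a bounded 1-D search.
    Traits are scaled to unit variance for the search (multivariate mode) and
    reported effects are mapped back to the original scale.
    """
    Y, names = _prepare_traits(traits, tree)
    n, q = Y.shape
    ws = workspace or ShiftWorkspace(tree)
    sd = Y.std(axis=0, ddof=1) if standardize else np.ones(q)
    if np.any(sd == 0):
        raise ValueError("constant trait column")
    Ys = Y / sd

    best: tuple[float, CandidateFit] | None = None
    for a in ws.alphas:
        a = float(a)
        ent = ws.entry(a)
        Yw = linalg.solve_triangular(ent["L"], Ys, lower=True)
        # path supports plus the empty configuration; a vectorized scan of
        # every singleton guards against a lone true shift only ever
        # entering the path in the company of correlated competitors
        supports = [()] + _path_supports(ent, Yw, max_shifts)
        j_best = _best_singleton(ent, Yw)
        if j_best is not None:
            supports.append((j_best,))
        alpha_best: tuple[float, CandidateFit] | None = None
        for cols in supports:
            cand = _refit(ws, a, cols, Ys, Yw=Yw)
            sc = score_criterion(cand, criterion)
            if alpha_best is None or sc < alpha_best[0]:
                alpha_best = (sc, cand)
        sc, cand = _backward(ws, a, alpha_best[1], alpha_best[0], Ys, Yw,
                             criterion)
        if best is None or sc < best[0]:
            best = (sc, cand)
    assert best is not None
    score, fit = best

    if refine_alpha and fit.alpha > 0:
        cols = [int(np.flatnonzero(ws.candidate_edges == e)[0])
                for e in fit.shift_edges]
        T = tree.total_depth

        def objective(log_at: float) -> float:
            cand = _refit(ws, float(np.exp(log_at)) / T, cols, Ys)
            return score_criterion(cand, criterion)

        res = optimize.minimize_scalar(
            objective, bounds=(log(0.005), log(100.0)), method="bounded",
            options={"maxiter": 30, "xatol": 1e-3})
        if res.fun < score:
            score = float(res.fun)
            fit = _refit(ws, float(np.exp(res.x)) / T, cols, Ys)

    return _build_shiftfit(fit, score, criterion, tree, ws, sd, names,
                           max_shifts)


def _backward(ws: ShiftWorkspace, alpha: float, fit: CandidateFit,
              score: float, Ys: np.ndarray, Yw: np.ndarray,
              criterion: str) -> tuple[float, CandidateFit]:
    """Drop shifts one at a time while the criterion improves."""
    improved = True
    while improved and fit.shift_edges:
        improved = False
        cols = [int(np.flatnonzero(ws.candidate_edges == e)[0])
                for e in fit.shift_edges]
        for drop in range(len(cols)):
            cand = _refit(ws, alpha, cols[:drop] + cols[drop + 1:], Ys, Yw=Yw)
            sc = score_criterion(cand, criterion)
            if sc < score:
                score, fit = sc, cand
                improved = True
                break
    return score, fit


def _build_shiftfit(fit: CandidateFit, score: float, criterion: str,
                    tree: PhyloTree, ws: ShiftWorkspace, sd: np.ndarray,
                    names: list[str], max_shifts: int) -> ShiftFit:
    n, q = fit.n, fit.q
    intercept = fit.beta[0] * sd
    betas = fit.beta[1:] * sd if fit.shift_edges else np.zeros((0, q))
    sigma2 = fit.sigma2 * sd ** 2
    loglik = fit.loglik - n * float(np.sum(np.log(sd)))
    regimes = regime_painting(tree, fit.shift_edges)
    n_regimes = regimes.max() + 1
    optima = np.tile(intercept, (n_regimes, 1))
    # optimum of a regime = intercept + sum of shifts along the path to it
    for r in range(1, n_regimes):
        v = int(np.flatnonzero(regimes == r)[0])
        # walk up accumulating shifts
        delta = np.zeros(q)
        u = v
        while u >= 0:
            if u in fit.shift_edges:
                delta += betas[fit.shift_edges.index(u)]
            u = tree.parent[u]
        optima[r] = intercept + delta
    model = OUModel(alpha=fit.alpha, sigma2=sigma2, intercept=intercept)
    return ShiftFit(shift_edges=fit.shift_edges, betas=betas, model=model,
                    regimes=regimes, optima=optima, loglik=loglik,
                    score=score, criterion=criterion, trait_names=names,
                    max_shifts=max_shifts)


def regime_painting(tree: PhyloTree, shift_edges: Sequence[int]) -> np.ndarray:
    """Regime id per node: 0 at the root, changing exactly at shift edges."""
    shift_set = set(int(e) for e in shift_edges)
    regimes = np.zeros(tree.n_nodes, dtype=int)
    next_id = 1
    for v in list(tree.postorder)[::-1]:       # preorder
        if v == tree.root:
            continue
        if v in shift_set:
            regimes[v] = next_id
            next_id += 1
        else:
            regimes[v] = regimes[tree.parent[v]]
    return regimes


# -- bootstrap support --------------------------------------------------------

def bootstrap_support(fit: ShiftFit, traits, tree: PhyloTree,
                      n_boot: int = 100, seed: int = 0,
                      workspace: ShiftWorkspace | None = None) -> dict[int, float]:
    """Support for each detected shift from a residual bootstrap.

    Residuals around the fitted tip means are whitened to uncorrelated
    standardized form with the inverse Cholesky factor of the fitted OU
    covariance, resampled with replacement (rows jointly across traits),
    colored back and added to the fitted means; the full shift search is
    rerun per replicate and an edge's support is the fraction of replicates
    whose detected set contains it.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not fit.shift_edges:
        return {}
    Y, _ = _prepare_traits(traits, tree)
    ws = workspace or ShiftWorkspace(tree)
    ent = ws.entry(fit.model.alpha)
    mu = _fitted_means(fit, tree)
    resid = Y - mu
    Z = linalg.solve_triangular(ent["L"], resid, lower=True)
    sig = np.sqrt(np.maximum(np.mean(Z ** 2, axis=0), 1e-300))
    Z = Z / sig
    rng = np.random.default_rng(seed)
    counts = {int(e): 0 for e in fit.shift_edges}
    n = tree.n_tips
    for _ in range(n_boot):
        rows = rng.integers(0, n, size=n)
        Ystar = mu + ent["L"] @ (Z[rows] * sig)
        det = detect_shifts(Ystar, tree, max_shifts=fit.max_shifts,
                            criterion=fit.criterion, workspace=ws,
                            refine_alpha=False)
        for e in det.shift_edges:
            if e in counts:
                counts[e] += 1
    return {e: c / n_boot for e, c in counts.items()}


def _fitted_means(fit: ShiftFit, tree: PhyloTree) -> np.ndarray:
    X = shift_design_matrix(tree, fit.model.alpha)
    edge_col = {int(e): i for i, e in enumerate(tree.edges)}
    mu = np.tile(fit.model.intercept, (tree.n_tips, 1))
    for k, e in enumerate(fit.shift_edges):
        mu += np.outer(X[:, edge_col[int(e)]], fit.betas[k])
    return mu


# -- convergent-regime collapse ----------------------------------------------

def _regime_weights(tree: PhyloTree, regimes: np.ndarray, alpha: float
                    ) -> np.ndarray:
    """(n_tips, n_regimes) OU path weights; rows sum to 1.

    Tip expectation = sum_r theta_r * u_ir, where u_ir integrates
    exp(-alpha (T - t)) mass over the portions of the root-to-tip path painted
    with regime r (the root's point mass exp(-alpha T) goes to regime 0).  In
    the BM limit the weight is the one-hot indicator of the tip's regime.
    """
    R = regimes.max() + 1
    n = tree.n_tips
    U = np.zeros((n, R))
    T = tree.total_depth
    if alpha == 0:
        for i in range(n):
            U[i, regimes[i]] = 1.0
        return U
    for i in range(n):
        U[i, 0] += np.exp(-alpha * T)
        v = i
        while v != tree.root:
            t_child = tree.depth[v]
            t_par = tree.depth[tree.parent[v]]
            w = np.exp(-alpha * (T - t_child)) - np.exp(-alpha * (T - t_par))
            U[i, regimes[v]] += w
            v = tree.parent[v]
    return U


def collapse_convergent(fit: ShiftFit, traits, tree: PhyloTree,
                        criterion: str | None = None) -> ShiftFit:
    """Greedily merge regimes whose shared optimum improves the criterion.

    Pairs of regimes are tested by constraining their optima equal (summing
    their columns in the regime-weight design), refitting by GLS/ML and
    rescoring; accepted merges may join non-adjacent clades, which is
    convergence.  The shift-edge painting is unchanged — only the optimum
    labels merge.
    """
    criterion = criterion or fit.criterion
    if not fit.shift_edges:
        return fit
    Y, _ = _prepare_traits(traits, tree)
    n, q = Y.shape
    alpha = fit.model.alpha
    V = ou_covariance(tree, alpha)
    L = linalg.cholesky(V, lower=True)
    logdetV = 2 * float(np.sum(np.log(np.diag(L))))
    Yw = linalg.solve_triangular(L, Y, lower=True)
    base_regimes = fit.regimes
    U0 = _regime_weights(tree, base_regimes, alpha)
    n_edges = len(ShiftWorkspace._pick_candidates(tree))
    s_edges = len(fit.shift_edges)

    def fit_groups(groups: list[list[int]]):
        U = np.column_stack([U0[:, g].sum(axis=1) for g in groups])
        Uw = linalg.solve_triangular(L, U, lower=True)
        B, _, rank, _ = np.linalg.lstsq(Uw, Yw, rcond=None)
        rss = np.sum((Yw - Uw @ B) ** 2, axis=0)
        sigma2 = np.maximum(rss / n, 1e-300)
        loglik = float(np.sum(-0.5 * (n * np.log(TWO_PI * sigma2)
                                      + logdetV + n)))
        if rank < Uw.shape[1]:
            gld = -np.inf
        else:
            sign, gld = np.linalg.slogdet(Uw.T @ Uw)
            gld = gld if sign > 0 else -np.inf
        s_params = len(groups) - 1
        cand = CandidateFit(shift_edges=tuple(range(s_params)), alpha=alpha,
                            beta=B, sigma2=sigma2, loglik=loglik,
                            gram_logdet=float(gld), n=n, q=q,
                            n_candidate_edges=n_edges)
        # keep the placement-count term at the original edge count: merging
        # changes the number of free optima, not where shifts sit
        sc = score_criterion(cand, criterion)
        if criterion == "pBIC":
            sc += 2 * (log(comb(n_edges, s_edges)) - log(comb(n_edges, s_params)))
        return sc, B, sigma2, loglik

    groups = [[r] for r in range(base_regimes.max() + 1)]
    score, B, sigma2, loglik = fit_groups(groups)
    improved = True
    while improved and len(groups) > 1:
        improved = False
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                merged = ([groups[k] for k in range(len(groups))
                           if k not in (i, j)] + [groups[i] + groups[j]])
                res = fit_groups(merged)
                if res[0] < score and (best is None or res[0] < best[0][0]):
                    best = (res, merged)
        if best is not None:
            (score, B, sigma2, loglik), groups = best
            improved = True

    # renumber regimes by merged groups (group containing old regime 0 first)
    groups = sorted(groups, key=lambda g: min(g))
    score, B, sigma2, loglik = fit_groups(groups)
    old_to_new = {}
    for new_id, g in enumerate(groups):
        for old in g:
            old_to_new[old] = new_id
    new_regimes = np.array([old_to_new[r] for r in base_regimes])
    optima = np.asarray(B)                      # (n_groups, q)
    model = OUModel(alpha=alpha, sigma2=sigma2, intercept=optima[0])
    return ShiftFit(shift_edges=fit.shift_edges, betas=fit.betas, model=model,
                    regimes=new_regimes, optima=optima, loglik=loglik,
                    score=score, criterion=criterion,
                    trait_names=fit.trait_names, supports=fit.supports,
                    max_shifts=fit.max_shifts)
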