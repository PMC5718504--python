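"""Phylogenetic generalized least squares under BM and fixed-root OU errors.

The regression ``y = b0 + b1 x + e`` has error covariance ``sigma2 V`` with
``V`` from Brownian motion or a fixed-root OU process on the supplied time
tree.  For OU the selection strength alpha is profiled (grid plus bounded
refinement); sigma2 has its ML closed form.  The slope t-test uses n - 2
degrees of freedom, treating the variance parameters as nuisance.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .trees import PhyloTree, ou_covariance

__all__ = ["PGLSFit", "pgls_fit", "compare_models", "run_hypothesis_tests"]

TWO_PI = 2 * np.pi


@dataclass
class PGLSFit:
    slope: float
    intercept: float
    model: str                    # "BM" | "OUfixedRoot"
    alpha: float | None
    sigma2: float
    loglik: float
    aic: float
    t: float
    p: float
    n: int

    def __repr__(self) -> str:
        a = "" if self.alpha is None else f", alpha={self.alpha:.4g}"
        return (f"PGLSFit({self.model}{a}, slope={self.slope:.4g}, "
                f"AIC={self.aic:.3f}, t={self.t:.3f}, p={self.p:.4g}, n={self.n})")


def _gls(y: np.ndarray, X: np.ndarray, L: np.ndarray, logdet: float):
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    A = Xw.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ yw)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    n = len(y)
    sigma2 = rss / n
    loglik = -0.5 * (n * log(TWO_PI * sigma2) + logdet + n)
    return beta, sigma2, loglik, A, rss


def pgls_fit(y, x, tree: PhyloTree, model: str = "BM") -> PGLSFit:
    """PGLS of y on x with BM or fixed-root OU ("OUfixedRoot") errors.

    Inputs may be pandas Series indexed by species (matched to tip labels
    after name normalization) or arrays already in tip order.
    """
    y = _match(y, tree)
    x = _match(x, tree)
    n = tree.n_tips
    if n < 3:
        raise ValueError("need at least 3 matched species")
    if np.std(x) == 0:
        raise ValueError("collinear (constant) predictor")
    X = np.column_stack([np.ones(n), x])

    def fit_at(alpha: float):
        V = ou_covariance(tree, alpha)
        L = linalg.cholesky(V, lower=True)
        logdet = 2 * float(np.sum(np.log(np.diag(L))))
        return _gls(y, X, L, logdet)

    if model == "BM":
        alpha = None
        beta, sigma2, loglik, A, rss = fit_at(0.0)
        k = 3
    elif model == "OUfixedRoot":
        T = tree.total_depth

        def nll(log_at: float) -> float:
            return -fit_at(np.exp(log_at) / T)[2]

        grid = np.log(np.geomspace(0.01, 50.0, 20))
        best = min(grid, key=nll)
        res = optimize.minimize_scalar(
            nll, bounds=(best - 1.2, best + 1.2), method="bounded",
            options={"xatol": 1e-4})
        alpha = float(np.exp(res.x) / T)
        beta, sigma2, loglik, A, rss = fit_at(alpha)
        k = 4
    else:
        raise ValueError("model must be 'BM' or 'OUfixedRoot'")

    # slope t-test with n - 2 df; unbiased residual variance for the SE
    s2_resid = rss / (n - 2)
    cov = s2_resid * np.linalg.inv(A)
    t = float(beta[1] / np.sqrt(cov[1, 1]))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return PGLSFit(slope=float(beta[1]), intercept=float(beta[0]), model=model,
                   alpha=alpha, sigma2=sigma2, loglik=loglik,
                   aic=2 * k - 2 * loglik, t=t, p=p, n=n)


def _match(v, tree: PhyloTree) -> np.ndarray:
    if isinstance(v, pd.Series):
        idx = {str(k).strip().casefold().replace("_", " "): k for k in v.index}
        out = np.empty(tree.n_tips)
        missing = []
        for i, lab in enumerate(tree.tip_labels):
            key = str(lab).strip().casefold().replace("_", " ")
            if key in idx:
                out[i] = float(v.loc[idx[key]])
            else:
                missing.append(lab)
        if missing:
            raise KeyError(f"tips without data: {missing}")
        return out
    arr = np.asarray(v, dtype=float).ravel()
    if len(arr) != tree.n_tips:
        raise ValueError("vector length must equal number of tips")
    return arr


def compare_models(fits) -> PGLSFit:
    """Best fit by AIC; exact ties go to the simpler BM model."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    best = min(fits, key=lambda f: (f.aic, f.model != "BM"))
    return best


def run_hypothesis_tests(traits: pd.DataFrame, sizes: pd.Series | None,
                         latitudes: pd.Series | None, tree: PhyloTree,
                         ) -> pd.DataFrame:
    """PGLS hypothesis battery under BM and OU error models.

    ``traits`` must carry per-species columns ``shape_pc1_equatorial`` and
    ``shape_pc1_polar``; ``sizes`` is log polar length per species;
    ``latitudes`` is mean absolute latitude per species.  Runs, per error
    model: allometry (polar shape ~ log polar length), developmental
    constraint (equatorial shape ~ polar shape), and latitude tests (shape
    and size ~ mean |latitude|).
    """
    tests: list[tuple[str, pd.Series, pd.Series]] = []
    eq = traits["shape_pc1_equatorial"]
    po = traits["shape_pc1_polar"]
    if sizes is not None:
        tests.append(("allometry", po, sizes))
    tests.append(("developmental_constraint", eq, po))
    if latitudes is not None:
        tests.append(("latitude_shape", eq, latitudes))
        if sizes is not None:
            tests.append(("latitude_size", sizes, latitudes))
    rows = []
    for name, yv, xv in tests:
        for model in ("BM", "OUfixedRoot"):
            f = pgls_fit(yv, xv, tree, model=model)
            rows.append({"test": name, "model": model, "slope": f.slope,
                         "intercept": f.intercept, "alpha": f.alpha,
                         "AIC": f.aic, "t": f.t, "p": f.p, "n": f.n})
    return pd.DataFrame(rows)
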