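"""PCA morphospaces, theoretical shape reconstruction, MANOVA and
phylomorphospace projection.

The morphospace is a centered, unscaled PCA of the normalized harmonic
coefficients; EFA size normalization already puts all coefficients on a
common scale.  Family differences are tested with a one-way MANOVA (Pillai's
trace, with Wilks' lambda reported alongside) plus a label-permutation p for
small samples.  The phylomorphospace projects a time tree into trait space
using maximum-likelihood ancestral states under Brownian motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .efa import HarmonicCoefficientSet, efa_inverse, Outline
from .trees import PhyloTree

__all__ = ["MorphospaceModel", "GroupTestResult", "pca_fit", "shape_at",
           "manova_groups", "phylomorphospace"]


@dataclass
class MorphospaceModel:
    mean_vector: np.ndarray
    loadings: np.ndarray          # (n_components, n_features), orthonormal rows
    eigenvalues: np.ndarray       # component variances
    scores: np.ndarray            # (n_samples, n_components)
    variance_fractions: np.ndarray
    ids: list | None = None

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class GroupTestResult:
    statistic_name: str
    statistic: float
    f_approx: float
    df1: float
    df2: float
    p: float
    p_permutation: float | None = None
    wilks_lambda: float | None = None


def pca_fit(coeff_matrix, ids=None) -> MorphospaceModel:
    """Centered, unscaled PCA via SVD; components ordered by eigenvalue.

    Component sign is fixed by making the largest-magnitude loading entry
    positive, so scores are reproducible across platforms.
    """
    X = np.asarray(coeff_matrix, dtype=float)
    if isinstance(coeff_matrix, pd.DataFrame):
        ids = list(coeff_matrix.index) if ids is None else ids
        X = coeff_matrix.to_numpy(float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if np.isnan(X).any():
        raise ValueError("missing values in coefficient matrix")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(Xc):
        raise ValueError("constant matrix has no variance")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = int(np.sum(s > s[0] * 1e-12))
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # deterministic sign: largest |loading| entry positive per component
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    n = X.shape[0]
    eig = s ** 2 / (n - 1)
    return MorphospaceModel(
        mean_vector=mean, loadings=Vt, eigenvalues=eig,
        scores=U * s, variance_fractions=eig / eig.sum(), ids=ids,
    )


def shape_at(model: MorphospaceModel, component: int, score: float,
             n_points: int = 256) -> Outline:
    """Theoretical shape at a given score along one morphospace axis.

    Reconstructs ``mean + score * loading`` as a harmonic coefficient set and
    inverts it; requires the model to be built from normalized coefficients
    (flattened (a, b, c, d) rows).
    """
    if not 0 <= component < model.n_components:
        raise IndexError(f"component {component} out of range")
    vec = model.mean_vector + score * model.loadings[component]
    H = vec.reshape(-1, 4)
    coeffs = HarmonicCoefficientSet(A0=0.0, C0=0.0, harmonics=H,
                                    normalized=False,
                                    outline_id=f"PC{component + 1}@{score:g}")
    return efa_inverse(coeffs, n_points=n_points)


# -- MANOVA -----------------------------------------------------------------

def _pillai(scores: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Pillai's trace and Wilks' lambda from between/within scatter matrices."""
    grand = scores.mean(axis=0)
    H = np.zeros((scores.shape[1],) * 2)
    E = np.zeros_like(H)
    for g in range(n_groups):
        sub = scores[codes == g]
        d = sub.mean(axis=0) - grand
        H += len(sub) * np.outer(d, d)
        r = sub - sub.mean(axis=0)
        E += r.T @ r
    evals = np.linalg.eigvals(np.linalg.solve(E + H, H)).real
    pillai = float(np.clip(evals, 0, 1).sum())
    wilks = float(np.prod(1 - np.clip(evals, 0, 1 - 1e-15)))
    return pillai, wilks


def manova_groups(scores, labels, m: int | None = 15, n_perm: int = 999,
                  seed: int = 0) -> GroupTestResult:
    """One-way MANOVA on the first ``m`` component scores.

    Returns Pillai's trace with its standard F approximation, plus a
    permutation p (label shuffling on Pillai) and Wilks' lambda.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if m is not None:
        X = X[:, : min(m, X.shape[1])]
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = uniq[counts < 2]
        raise ValueError(f"groups with fewer than 2 members: {list(small)}")
    n, p = X.shape
    V, wilks = _pillai(X, codes, g)
    s = min(p, g - 1)
    m_ = (abs(p - (g - 1)) - 1) / 2
    n_ = (n - g - p - 1) / 2
    df1 = s * (2 * m_ + s + 1)
    df2 = s * (2 * n_ + s + 1)
    if df2 <= 0:
        raise ValueError("not enough observations for the F approximation")
    F = (df2 / df1) * (V / s) / (1 - V / s)
    pval = float(stats.f.sf(F, df1, df2))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        Vp, _ = _pillai(X, rng.permutation(codes), g)
        hits += Vp >= V
    p_perm = (1 + hits) / (1 + n_perm)
    return GroupTestResult(statistic_name="Pillai", statistic=V, f_approx=float(F),
                           df1=float(df1), df2=float(df2), p=pval,
                           p_permutation=p_perm, wilks_lambda=wilks)


# -- phylomorphospace ---------------------------------------------------------

def phylomorphospace(tree: PhyloTree, tip_coords) -> tuple[pd.DataFrame, np.ndarray]:
    """Project a phylogeny into trait space.

    Internal-node coordinates are maximum-likelihood ancestral estimates under
    Brownian motion, computed per axis by Gaussian belief propagation (a
    down-pass of precision-weighted child messages and an up-pass combining
    each node's subtree message with the rest of the tree).  Returns a frame
    of node coordinates (tips then internal nodes, index = node id) and the
    tree's edge list as (parent, child) pairs for plotting.
    """
    if isinstance(tip_coords, pd.DataFrame):
        idx = tree.tip_index(tip_coords.index)
        Y = np.full((tree.n_tips, tip_coords.shape[1]), np.nan)
        Y[idx] = tip_coords.to_numpy(float)
        colnames = list(tip_coords.columns)
    else:
        Y = np.asarray(tip_coords, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        colnames = [f"axis{i+1}" for i in range(Y.shape[1])]
    if np.isnan(Y).any():
        missing = [tree.tip_labels[i] for i in
                   np.flatnonzero(np.isnan(Y).any(axis=1))]
        raise ValueError(f"tips missing coordinates: {missing}")

    coords = np.vstack([Y, np.column_stack(
        [_bm_ancestral_states(tree, Y[:, j]) for j in range(Y.shape[1])])])
    edges = np.array([(tree.parent[v], v) for v in range(tree.n_nodes)
                      if v != tree.root])
    node_ids = list(range(tree.n_tips)) + [v for v in range(tree.n_nodes)
                                           if v >= tree.n_tips]
    df = pd.DataFrame(coords, index=node_ids, columns=colnames)
    df["is_tip"] = [v < tree.n_tips for v in node_ids]
    return df, edges


def _bm_ancestral_states(tree: PhyloTree, y: np.ndarray) -> np.ndarray:
    """ML ancestral states per internal node (tips observed exactly)."""
    n_nodes = tree.n_nodes
    # down-pass: message from each node's subtree, seen from above its edge
    mu_d = np.zeros(n_nodes)
    var_d = np.zeros(n_nodes)
    for v in tree.postorder:
        if not tree.children[v]:
            mu_d[v], var_d[v] = y[v], 0.0
        else:
            w = np.array([1.0 / (var_d[c] + tree.length[c])
                          for c in tree.children[v]])
            mus = np.array([mu_d[c] for c in tree.children[v]])
            mu_d[v] = np.sum(w * mus) / w.sum()
            var_d[v] = 1.0 / w.sum()
    # up-pass: message from the rest of the tree through the parent
    mu_u = np.zeros(n_nodes)
    var_u = np.full(n_nodes, np.inf)
    order = list(tree.postorder)[::-1]  # preorder
    for v in order:
        for c in tree.children[v]:
            parts_mu, parts_w = [], []
            if np.isfinite(var_u[v]):
                parts_mu.append(mu_u[v])
                parts_w.append(1.0 / var_u[v])
            for o in tree.children[v]:
                if o != c:
                    parts_mu.append(mu_d[o])
                    parts_w.append(1.0 / (var_d[o] + tree.length[o]))
            w = np.array(parts_w)
            mu_u[c] = np.sum(w * np.array(parts_mu)) / w.sum()
            var_u[c] = 1.0 / w.sum() + tree.length[c]
    est = np.empty(n_nodes - tree.n_tips)
    internal = [v for v in range(n_nodes) if v >= tree.n_tips]
    for k, v in enumerate(internal):
        if not np.isfinite(var_u[v]):
            est[k] = mu_d[v]
        else:
            w1, w2 = 1.0 / var_d[v] if var_d[v] > 0 else np.inf, 1.0 / var_u[v]
            if np.isinf(w1):
                est[k] = mu_d[v]
            else:
                est[k] = (w1 * mu_d[v] + w2 * mu_u[v]) / (w1 + w2)
    return est
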