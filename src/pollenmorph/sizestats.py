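"""Pollen size summaries and Monte-Carlo randomization tests.

Sizes (microns) are summarized per family on the raw scale; inference runs on
log-transformed values because pollen size distributions are strongly
right-skewed (Shapiro-Wilk is reported as an advisory flag).  Group
differences use approximate randomization tests — the omnibus statistic is
the one-way F, pairwise tests use |mean difference| — with an exact
(exhaustive) mode whenever the number of distinct label assignments is small
enough.  Post-hoc results are summarized as a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["read_sizes", "summarize_size", "randomization_test",
           "posthoc_letters", "compact_letter_display", "LetterDisplay"]

MEASUREMENTS = ("length_um", "width_um")


@dataclass
class LetterDisplay:
    letters: dict[str, str]       # group -> letter string


def read_sizes(path) -> pd.DataFrame:
    """Read a size CSV (species, view, length_um, width_um, family).

    Duplicate species x view rows are averaged; non-positive sizes are an
    error.
    """
    df = pd.read_csv(path)
    if (df[list(MEASUREMENTS)] <= 0).any().any():
        raise ValueError("non-positive size measurements")
    return (df.groupby(["species", "view", "family"], as_index=False)
              [list(MEASUREMENTS)].mean())


def summarize_size(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per family x view x measurement n/mean/SD plus a normality report.

    The summary is on the raw micron scale; the normality report carries the
    Shapiro-Wilk p per view x measurement (pooled across families) and a
    ``non_normal`` flag at p < 0.05.  Downstream tests should use
    log-transformed values regardless of the flag.
    """
    if table.empty:
        raise ValueError("empty size table")
    if (table[list(MEASUREMENTS)] <= 0).any().any():
        raise ValueError("non-positive size measurements")
    rows = []
    for (fam, view), grp in table.groupby(["family", "view"]):
        for meas in MEASUREMENTS:
            vals = grp[meas].dropna()
            rows.append({
                "family": fam, "view": view, "measurement": meas,
                "n": len(vals), "mean": vals.mean(),
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            })
    summary = pd.DataFrame(rows)
    norm_rows = []
    for view, grp in table.groupby("view"):
        for meas in MEASUREMENTS:
            vals = grp[meas].dropna().to_numpy()
            if len(vals) >= 3:
                W, p = stats.shapiro(vals)
            else:
                W, p = np.nan, np.nan
            norm_rows.append({"view": view, "measurement": meas,
                              "shapiro_W": W, "shapiro_p": p,
                              "non_normal": bool(p < 0.05) if p == p else False})
    return summary, pd.DataFrame(norm_rows)


def _f_stat(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    """One-way ANOVA F; infinite within-variance guard for tiny groups."""
    n = len(values)
    grand = values.mean()
    ss_b = ss_w = 0.0
    for g in range(k):
        sub = values[codes == g]
        m = sub.mean()
        ss_b += len(sub) * (m - grand) ** 2
        ss_w += float(np.sum((sub - m) ** 2))
    if ss_w == 0:
        return np.inf if ss_b > 0 else 0.0
    return (ss_b / (k - 1)) / (ss_w / (n - k))


def _abs_mean_diff(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    return abs(values[codes == 0].mean() - values[codes == 1].mean())


def _exhaustive_assignments(counts: np.ndarray):
    """Yield all distinct label assignments (as code arrays) for given counts."""
    n = int(counts.sum())

    def rec(avail: tuple[int, ...], group: int, codes: np.ndarray):
        if group == len(counts) - 1:
            out = codes.copy()
            out[list(avail)] = group
            yield out
            return
        for pick in combinations(avail, counts[group]):
            codes2 = codes.copy()
            codes2[list(pick)] = group
            rest = tuple(i for i in avail if i not in set(pick))
            yield from rec(rest, group + 1, codes2)

    yield from rec(tuple(range(n)), 0, np.full(n, -1, dtype=int))


def _n_assignments(counts: np.ndarray) -> int:
    total, n = 1, int(counts.sum())
    for c in counts:
        total *= comb(n, int(c))
        n -= int(c)
    return total


def randomization_test(values, labels, n_perm: int = 9999, seed: int = 0,
                       statistic: str = "F") -> float:
    """Approximate randomization test for a group difference.

    Permutes labels ``n_perm`` times, or enumerates every distinct assignment
    when their count is <= ``n_perm`` (exact mode).  Monte-Carlo p uses the
    plus-one correction (1 + hits) / (1 + n_perm); exact mode returns the
    exact permutation p (observed assignment included in the reference set).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    uniq, codes = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() == 0:
        raise ValueError("empty group")
    stat = {"F": _f_stat, "mean_diff": _abs_mean_diff}[statistic]
    if statistic == "mean_diff" and k != 2:
        raise ValueError("mean_diff statistic needs exactly 2 groups")
    obs = stat(values, codes, k)
    total = _n_assignments(counts)
    if total <= n_perm:
        hits = sum(stat(values, np.asarray(perm), k) >= obs - 1e-12
                   for perm in _exhaustive_assignments(counts))
        return hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += stat(values, rng.permutation(codes), k) >= obs - 1e-12
    return (1 + hits) / (1 + n_perm)


def posthoc_letters(values, labels, n_perm: int = 9999, seed: int = 0,
                    adjust: str = "fdr_bh", alpha: float = 0.05
                    ) -> tuple[pd.DataFrame, LetterDisplay]:
    """All pairwise randomization tests with p adjustment and letter display.

    Pairwise statistic is |mean difference|; p-values are adjusted with the
    configured statsmodels method (default Benjamini-Hochberg FDR); two
    groups share a letter iff their adjusted p >= alpha.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(map(str, np.unique(labels)))
    labels = labels.astype(str)
    pairs = list(combinations(groups, 2))
    raw = []
    for i, (g1, g2) in enumerate(pairs):
        mask = (labels == g1) | (labels == g2)
        raw.append(randomization_test(values[mask], labels[mask],
                                      n_perm=n_perm, seed=seed + i,
                                      statistic="mean_diff"))
    adj = multipletests(raw, method=adjust)[1] if pairs else np.array([])
    pmat = pd.DataFrame(np.ones((len(groups), len(groups))),
                        index=groups, columns=groups)
    sig = set()
    for (g1, g2), p in zip(pairs, adj):
        pmat.loc[g1, g2] = pmat.loc[g2, g1] = p
        if p < alpha:
            sig.add((g1, g2))
    return pmat, compact_letter_display(groups, sig)


def compact_letter_display(groups: list[str],
                           significant_pairs: set[tuple[str, str]]) -> LetterDisplay:
    """Insert-and-absorb compact letter display.

    Starts from one column holding every group; each significant pair splits
    any column containing both; columns that become subsets of others are
    absorbed.  Groups share a letter iff their pair is not significant.
    """
    sig = {frozenset(p) for p in significant_pairs}
    columns: list[set[str]] = [set(groups)]
    for pair in sig:
        g1, g2 = tuple(pair)
        new_cols = []
        for col in columns:
            if g1 in col and g2 in col:
                new_cols.extend([col - {g1}, col - {g2}])
            else:
                new_cols.append(col)
        # absorb: drop any column contained in another
        columns = [c for c in new_cols
                   if not any(c < d for d in new_cols)]
        # dedupe
        uniq = []
        for c in columns:
            if c not in uniq:
                uniq.append(c)
        columns = uniq
    columns.sort(key=lambda c: sorted(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in sorted(col):
            letters[g] += letter
    return LetterDisplay(letters=letters)
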