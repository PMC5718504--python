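"""Elliptic Fourier analysis of closed 2-D outlines.

A closed polygon is decomposed into a sum of harmonically related ellipses
(coefficients a_n, b_n, c_n, d_n per harmonic, plus translation terms A0, C0)
using the piecewise-linear chord-length parameterization of the contour.
Normalization makes the coefficients invariant to translation, rotation,
uniform scale and the choice of starting point, leaving a_1 = 1 and b_1 = 0,
which is the representation used for morphospace construction.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Outline", "HarmonicCoefficientSet",
    "read_outlines", "write_coefficients",
    "efa_forward", "efa_inverse",
    "remove_symmetry_component", "calibrate_harmonic_count",
]

VIEWS = ("equatorial", "polar")


@dataclass
class Outline:
    """An ordered closed polygon with species/view metadata.

    The polygon is implicitly closed (last point connects back to the first);
    orientation is normalized to counterclockwise on construction.
    """

    id: str
    species: str
    view: str
    points: np.ndarray
    family: str | None = None
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool = True) -> None:
        pts = np.asarray(self.points, dtype=float)
        self.points = pts
        if not validate:        # degenerate reconstructions (e.g. a point)
            return
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError(f"outline {self.id}: need >= 3 (x, y) points")
        # drop an explicit closing duplicate, then check consecutive duplicates
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0):
            raise ValueError(f"outline {self.id}: consecutive duplicate points")
        if self.view not in VIEWS:
            raise ValueError(f"outline {self.id}: view {self.view!r} not in {VIEWS}")
        if _signed_area(pts) < 0:
            pts = pts[::-1].copy()
        self.points = pts

    @property
    def perimeter(self) -> float:
        seg = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class HarmonicCoefficientSet:
    """EFA coefficients: translation terms and (a_n, b_n, c_n, d_n) rows."""

    A0: float
    C0: float
    harmonics: np.ndarray          # (N, 4) rows of (a, b, c, d)
    normalized: bool = False
    outline_id: str | None = None

    def __post_init__(self) -> None:
        H = np.asarray(self.harmonics, dtype=float)
        if H.ndim != 2 or H.shape[1] != 4 or H.shape[0] < 1:
            raise ValueError("harmonics must be an (N, 4) array with N >= 1")
        self.harmonics = H
        if self.normalized:
            a1, b1 = H[0, 0], H[0, 1]
            if not (a1 > 0 and abs(b1) <= 1e-9 and abs(self.A0) <= 1e-9
                    and abs(self.C0) <= 1e-9):
                raise ValueError("normalized set must have A0=C0=0, a1>0, b1=0")

    @property
    def n_harmonics(self) -> int:
        return self.harmonics.shape[0]

    @property
    def power(self) -> np.ndarray:
        """Per-harmonic power P_n = (a_n^2 + b_n^2 + c_n^2 + d_n^2) / 2."""
        return 0.5 * np.sum(self.harmonics ** 2, axis=1)

    def flatten(self) -> np.ndarray:
        return self.harmonics.ravel()


# -- I/O --------------------------------------------------------------------

def read_outlines(outline_table, metadata_table) -> list[Outline]:
    """Read outlines from a coordinate CSV plus a metadata CSV.

    Coordinate columns: outline_id, point_index, x, y.
    Metadata columns: outline_id, species, view, family.
    """
    coords = pd.read_csv(outline_table)
    meta = pd.read_csv(metadata_table).set_index("outline_id")
    outlines = []
    for oid, grp in coords.groupby("outline_id", sort=True):
        if oid not in meta.index:
            raise KeyError(f"outline {oid!r} has no metadata row")
        row = meta.loc[oid]
        grp = grp.sort_values("point_index")
        fam = row.get("family")
        outlines.append(Outline(
            id=str(oid), species=str(row["species"]), view=str(row["view"]),
            points=grp[["x", "y"]].to_numpy(float),
            family=None if pd.isna(fam) else str(fam),
        ))
    return outlines


def write_coefficients(coeff_sets: list[HarmonicCoefficientSet], path) -> pd.DataFrame:
    """Write a coefficient table (outline_id, A0, C0, a1..dN, normalized)."""
    N = coeff_sets[0].n_harmonics
    cols = [f"{ch}{n}" for n in range(1, N + 1) for ch in "abcd"]
    rows = []
    for cs in coeff_sets:
        if cs.n_harmonics != N:
            raise ValueError("coefficient sets differ in harmonic count")
        rows.append([cs.outline_id, cs.A0, cs.C0, *cs.flatten(), cs.normalized])
    df = pd.DataFrame(rows, columns=["outline_id", "A0", "C0", *cols, "normalized"])
    if path is not None:
        df.to_csv(path, index=False)
    return df


# -- forward / inverse transform --------------------------------------------

def efa_forward(outline: Outline, n_harmonics: int,
                normalize: bool = True) -> HarmonicCoefficientSet:
    """Elliptic Fourier decomposition of a closed polygon.

    Exact piecewise-linear segment sums on the raw polygon (no resampling);
    the period T is the perimeter.  With ``normalize`` the coefficients are
    made invariant to translation, starting point, rotation and scale.
    """
    pts = outline.points
    m = len(pts)
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if n_harmonics > m // 2:
        raise ValueError(f"n_harmonics={n_harmonics} exceeds Nyquist bound {m // 2}")
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    T = dt.sum()
    if T == 0:
        raise ValueError("degenerate outline with zero perimeter")
    t = np.concatenate([[0.0], np.cumsum(dt)])      # t_0 .. t_m, t_m = T
    phi = 2 * np.pi * t / T

    n = np.arange(1, n_harmonics + 1)[:, None]      # (N, 1)
    cos_d = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    sin_d = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    k = T / (2 * np.pi ** 2 * n.ravel() ** 2)
    a = k * (cos_d @ vx)
    b = k * (sin_d @ vx)
    c = k * (cos_d @ vy)
    dd = k * (sin_d @ vy)

    # translation terms: exact integral of the piecewise-linear curve
    xi = np.concatenate([[0.0], np.cumsum(d[:, 0])])[:-1] - vx * t[:-1]
    dlt = np.concatenate([[0.0], np.cumsum(d[:, 1])])[:-1] - vy * t[:-1]
    A0 = pts[0, 0] + float(np.sum(vx / 2 * (t[1:] ** 2 - t[:-1] ** 2) + xi * dt)) / T
    C0 = pts[0, 1] + float(np.sum(vy / 2 * (t[1:] ** 2 - t[:-1] ** 2) + dlt * dt)) / T

    H = np.column_stack([a, b, c, dd])
    if not normalize:
        return HarmonicCoefficientSet(A0=A0, C0=C0, harmonics=H,
                                      normalized=False, outline_id=outline.id)
    return HarmonicCoefficientSet(A0=0.0, C0=0.0, harmonics=_normalize(H),
                                  normalized=True, outline_id=outline.id)


def _rotate_start(H: np.ndarray, theta: float) -> np.ndarray:
    """Shift the starting point: harmonic n is phase-rotated by n*theta."""
    out = np.empty_like(H)
    for i in range(H.shape[0]):
        nth = (i + 1) * theta
        R = np.array([[np.cos(nth), -np.sin(nth)], [np.sin(nth), np.cos(nth)]])
        out[i] = (H[i].reshape(2, 2) @ R).ravel()
    return out


def _normalize(H: np.ndarray) -> np.ndarray:
    a1, b1, c1, d1 = H[0]
    theta = 0.5 * np.arctan2(2 * (a1 * b1 + c1 * d1),
                             a1 ** 2 + c1 ** 2 - b1 ** 2 - d1 ** 2)
    candidates = []
    for th in (theta, theta + np.pi):
        Hs = _rotate_start(H, th)
        psi = np.arctan2(Hs[0, 2], Hs[0, 0])
        R = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
        Hr = np.empty_like(Hs)
        for i in range(Hs.shape[0]):
            Hr[i] = (R @ Hs[i].reshape(2, 2)).ravel()
        scale = Hr[0, 0]
        candidates.append(Hr / scale)
    # theta is defined modulo pi; the two candidates differ by the sign of
    # every even harmonic.  Break the tie by the first non-negligible even
    # coefficient, kept positive -- deterministic and start-point invariant.
    ca, cb = candidates
    even = np.arange(1, H.shape[0], 2)  # harmonic 2, 4, ... (0-based rows)
    pick = ca
    for i in even:
        row = ca[i]
        j = np.flatnonzero(np.abs(row) > 1e-9)
        if j.size:
            pick = ca if row[j[0]] > 0 else cb
            break
    pick = pick.copy()
    pick[0, 1] = 0.0  # b1 is zero by construction; remove rounding dust
    return pick


def efa_inverse(coeffs: HarmonicCoefficientSet, n_points: int = 256,
                species: str = "", view: str = "equatorial") -> Outline:
    """Reconstruct the closed curve from its harmonic ellipses."""
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    x, y = reconstruct_xy(coeffs, n_points)
    pts = np.column_stack([x, y])
    degenerate = np.allclose(pts, pts[0])
    return Outline(id=coeffs.outline_id or "reconstruction",
                   species=species, view=view, points=pts,
                   validate=not degenerate)


def reconstruct_xy(coeffs: HarmonicCoefficientSet, n_points: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    x = np.full(n_points, float(coeffs.A0))
    y = np.full(n_points, float(coeffs.C0))
    for i, (a, b, c, d) in enumerate(coeffs.harmonics, start=1):
        x += a * np.cos(i * t) + b * np.sin(i * t)
        y += c * np.cos(i * t) + d * np.sin(i * t)
    return x, y


# -- symmetry removal and harmonic calibration --------------------------------

def remove_symmetry_component(coeffs: HarmonicCoefficientSet,
                              mode: str) -> HarmonicCoefficientSet:
    """Zero the coefficient block carrying (a)symmetric variation.

    After normalization the first-ellipse major axis is the x axis, so b_n and
    c_n carry variation asymmetric about it and a_n, d_n the symmetric part.
    ``mode='asymmetric'`` removes the asymmetric block (b_n = c_n = 0);
    ``mode='symmetric'`` removes the symmetric block (a_n = d_n = 0).
    """
    if not coeffs.normalized:
        raise ValueError("symmetry removal requires normalized coefficients "
                         "(the symmetry axis is the first-ellipse major axis)")
    H = coeffs.harmonics.copy()
    if mode == "asymmetric":
        H[:, 1] = 0.0
        H[:, 2] = 0.0
    elif mode == "symmetric":
        H[:, 0] = 0.0
        H[:, 3] = 0.0
    else:
        raise ValueError("mode must be 'asymmetric' or 'symmetric'")
    if mode == "symmetric":
        # a1 was zeroed; the set is no longer in normalized canonical form
        return HarmonicCoefficientSet(A0=coeffs.A0, C0=coeffs.C0, harmonics=H,
                                      normalized=False, outline_id=coeffs.outline_id)
    return HarmonicCoefficientSet(A0=coeffs.A0, C0=coeffs.C0, harmonics=H,
                                  normalized=True, outline_id=coeffs.outline_id)


def calibrate_harmonic_count(coeff_sets, power_threshold: float = 0.99) -> int:
    """Smallest N whose mean cumulative power fraction reaches the threshold.

    Power of harmonic n is (a_n^2+b_n^2+c_n^2+d_n^2)/2; the fraction is taken
    against the total over all computed harmonics, averaged over outlines.
    """
    coeff_sets = list(coeff_sets)
    if not coeff_sets:
        raise ValueError("empty collection of coefficient sets")
    if not 0 < power_threshold <= 1:
        raise ValueError("power_threshold must be in (0, 1]")
    P = np.vstack([cs.power for cs in coeff_sets])     # (n_outlines, N_max)
    cum = np.cumsum(P, axis=1) / P.sum(axis=1, keepdims=True)
    mean_cum = cum.mean(axis=0)
    idx = np.searchsorted(mean_cum, power_threshold - 1e-12)
    return int(min(idx, P.shape[1] - 1) + 1)
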