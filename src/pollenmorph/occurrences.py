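"""Occurrence-record cleaning and per-species latitude summaries.

Cleaning is deliberately minimal and rule-listed: exact within-species
coordinate duplicates, the (0, 0) point (a common georeferencing artifact),
out-of-bounds coordinates, and optionally records outside a per-species
bounding box.  Every rule can be switched off individually.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["clean_occurrences", "mean_abs_latitude"]

COLUMNS = ["species", "latitude", "longitude"]


def clean_occurrences(records: pd.DataFrame,
                      bbox_per_species: dict[str, tuple[float, float, float, float]] | None = None,
                      drop_duplicates: bool = True, drop_zero_zero: bool = True,
                      drop_out_of_bounds: bool = True,
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Filter occurrence records; returns (cleaned, removal report).

    ``bbox_per_species`` maps species to (lat_min, lat_max, lon_min, lon_max).
    The report counts removals by rule.
    """
    df = records[COLUMNS].copy()
    report = {}
    if drop_out_of_bounds:
        ok = (df.latitude.between(-90, 90) & df.longitude.between(-180, 180))
        report["out_of_bounds"] = int((~ok).sum())
        df = df[ok]
    if drop_zero_zero:
        zz = (df.latitude == 0) & (df.longitude == 0)
        report["zero_zero"] = int(zz.sum())
        df = df[~zz]
    if drop_duplicates:
        before = len(df)
        df = df.drop_duplicates(subset=COLUMNS)
        report["duplicate"] = before - len(df)
    if bbox_per_species:
        keep = np.ones(len(df), dtype=bool)
        for i, (_, row) in enumerate(df.iterrows()):
            box = bbox_per_species.get(row.species)
            if box is not None:
                la0, la1, lo0, lo1 = box
                keep[i] = la0 <= row.latitude <= la1 and lo0 <= row.longitude <= lo1
        report["outside_bbox"] = int((~keep).sum())
        df = df[keep]
    if df.empty:
        warnings.warn("all occurrence records removed by cleaning")
    return df.reset_index(drop=True), pd.Series(report, name="removed")


def mean_abs_latitude(records: pd.DataFrame,
                      species: list[str] | None = None) -> pd.Series:
    """Mean absolute latitude per species from cleaned records.

    Species with zero records are omitted with a warning when an expected
    species list is supplied.
    """
    out = records.groupby("species")["latitude"].apply(
        lambda s: float(np.mean(np.abs(s))))
    out.name = "mean_abs_latitude"
    if species is not None:
        missing = sorted(set(species) - set(out.index))
        if missing:
            warnings.warn(f"species with no occurrence records omitted: {missing}")
    return out
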