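"""Resolution of duplicate monitoring sites.

A water monitoring site is the unique combination of a Monitoring Location
Identifier (MLI) and a projected coordinate pair.  Raw records violate this
in both directions: one MLI may carry several nearby coordinate pairs
(equipment moved, eroding banks), and one coordinate pair may carry several
MLIs (projects renamed, responsibility transferred).  Coordinates within a
400 m threshold of each other collapse to the pair that appears first in the
data; identical coordinates then collapse to the first-appearing MLI.
Coordinate resolution runs first because merging coordinates can create the
exact equality that MLI merging requires.

Distances are Euclidean in the projected plane (inputs arrive in an
equal-area projection in meters); a distance exactly equal to the threshold
merges.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .config import HarmonizationConfig

__all__ = ["resolve_coordinates", "resolve_mlis", "resolve_sites"]


def resolve_coordinates(df: pd.DataFrame, threshold_m: float) -> pd.DataFrame:
    """Collapse near-duplicate coordinate pairs per MLI.

    Adds ``new_x``, ``new_y``, ``num_coords_at_loc``, ``dup_coords_flag``
    (``one_coord_set`` / ``dup_coords``) and ``combine_coords_flag``
    (``combine`` / ``keep_separate``, NA for single-coordinate MLIs).  For an
    MLI with several distinct pairs, all pairs merge to the first-appearing
    one only when every pairwise distance is within the threshold; otherwise
    the coordinates are left untouched.  Rows without coordinates pass
    through unflagged.
    """
    out = df.copy()
    out["new_x"] = out["orig_x"].astype(float)
    out["new_y"] = out["orig_y"].astype(float)
    out["num_coords_at_loc"] = 1
    out["dup_coords_flag"] = "one_coord_set"
    out["combine_coords_flag"] = pd.Series(pd.NA, index=out.index, dtype=object)

    has_xy = out["orig_x"].notna() & out["orig_y"].notna()
    sub = out.loc[has_xy].sort_values("record_id")
    for mli, grp in sub.groupby("orig_MLI", sort=False):
        pairs = list(dict.fromkeys(zip(grp["orig_x"], grp["orig_y"])))
        if len(pairs) == 1:
            continue
        idx = grp.index
        out.loc[idx, "num_coords_at_loc"] = len(pairs)
        out.loc[idx, "dup_coords_flag"] = "dup_coords"
        all_close = all(
            math.dist(a, b) <= threshold_m for a, b in itertools.combinations(pairs, 2)
        )
        if all_close:
            x0, y0 = pairs[0]
            out.loc[idx, "new_x"] = x0
            out.loc[idx, "new_y"] = y0
            out.loc[idx, "combine_coords_flag"] = "combine"
        else:
            out.loc[idx, "combine_coords_flag"] = "keep_separate"
    return out


def resolve_mlis(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate MLIs at bit-identical resolved coordinates.

    Adds ``new_MLI``, ``num_MLIs_at_loc`` and ``dup_MLI_flag``
    (``one_MLI`` / ``dup_MLI``).  For every exact (new_x, new_y) with more
    than one distinct original MLI, all records receive the MLI that appears
    first in record order; the original MLI is retained in ``orig_MLI``.
    """
    out = df.copy()
    out["new_MLI"] = out["orig_MLI"]
    out["num_MLIs_at_loc"] = 1
    out["dup_MLI_flag"] = "one_MLI"

    has_xy = out["new_x"].notna() & out["new_y"].notna()
    sub = out.loc[has_xy].sort_values("record_id")
    for (_, _), grp in sub.groupby(["new_x", "new_y"], sort=False):
        mlis = list(dict.fromkeys(grp["orig_MLI"]))
        if len(mlis) == 1:
            continue
        idx = grp.index
        out.loc[idx, "new_MLI"] = mlis[0]
        out.loc[idx, "num_MLIs_at_loc"] = len(mlis)
        out.loc[idx, "dup_MLI_flag"] = "dup_MLI"
    return out


def resolve_sites(df: pd.DataFrame, config: HarmonizationConfig) -> pd.DataFrame:
    """Full site resolution: coordinates first, then MLIs."""
    return resolve_mlis(resolve_coordinates(df, config.coord_merge_threshold_m))
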