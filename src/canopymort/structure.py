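"""Neighborhood competition indices CCTH, CC66 and CVTH.

CCTH (canopy cover taller than the central tree's height) and CC66 (cover
taller than 66% of it) are pixel fractions of a circular neighborhood,
computed on the CHM with the central tree's own crown pixels excluded from
the numerator but kept in the denominator — the indices measure how much of
the neighborhood is occupied by *other* canopy taller than the subject.
CVTH is the coefficient of variation (sample sd / mean, x100) of the
heights of all neighboring stems.  Ties do not count as "taller"
(strict inequality), and buffer membership is by pixel centre.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .canopy import SegmentMap
from .raster import Raster

DEFAULT_RADII = (15.0, 30.0, 50.0, 100.0)
NODATA = float("nan")


def canopy_cover_taller(
    chm: Raster,
    segments: SegmentMap | None,
    tree,
    radius: float,
    fraction: float = 1.0,
    exclude_own_segment: bool = True,
) -> float:
    """Percent of the circular neighborhood covered by taller canopy.

    ``tree`` needs ``x``, ``y``, ``height`` attributes (a tree-table row)
    and, when ``segments`` is given, a ``tree_id`` matching a segment
    label so its own crown can be excluded from the numerator.  The
    denominator is every buffer pixel inside the raster.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not chm.contains(tree.x, tree.y):
        raise ValueError(f"tree at ({tree.x}, {tree.y}) outside raster")
    rows, cols, dist = _buffer_pixels(chm, tree.x, tree.y, radius)
    if len(rows) == 0:
        raise ValueError("neighborhood buffer entirely outside raster")
    vals = chm.values[rows, cols]
    taller = vals > fraction * tree.height
    if exclude_own_segment and segments is not None:
        label = getattr(tree, "segment_label", getattr(tree, "tree_id", -1))
        own = segments.labels.values[rows, cols] == label
        taller = taller & ~own
    return 100.0 * float(np.count_nonzero(taller)) / len(rows)


def _buffer_pixels(chm: Raster, x: float, y: float, radius: float):
    """Grid indices of pixels whose centre lies within ``radius`` of (x, y)."""
    cs = chm.cell_size
    nrows, ncols = chm.shape
    c0 = max(0, int((x - radius - chm.origin[0]) / cs) - 1)
    c1 = min(ncols, int((x + radius - chm.origin[0]) / cs) + 2)
    r0 = max(0, int((chm.origin[1] - y - radius) / cs) - 1)
    r1 = min(nrows, int((chm.origin[1] - y + radius) / cs) + 2)
    if c0 >= c1 or r0 >= r1:
        return (np.empty(0, int),) * 2 + (np.empty(0),)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    px, py = chm.rowcol_to_xy(rows, cols)
    d = np.hypot(px - x, py - y)
    inside = d <= radius
    return rows[inside], cols[inside], d[inside]


def cvth(trees: pd.DataFrame, center_tree, radius: float) -> tuple[float, int]:
    """Coefficient of variation (%) of neighbor heights within ``radius``.

    Neighbors are all stems within the radius excluding the central tree
    itself.  Returns (cvth, n_neighbors); cvth is NaN with fewer than two
    neighbors (sample sd undefined or trivially zero-information).
    """
    dx = trees["x"].to_numpy(dtype=float) - center_tree.x
    dy = trees["y"].to_numpy(dtype=float) - center_tree.y
    within = np.hypot(dx, dy) <= radius
    if "tree_id" in trees.columns and hasattr(center_tree, "tree_id"):
        within &= trees["tree_id"].to_numpy() != center_tree.tree_id
    heights = trees.loc[within, "height"].to_numpy(dtype=float)
    n = len(heights)
    if n < 2:
        return NODATA, n
    mean = heights.mean()
    sd = heights.std(ddof=1)
    return 100.0 * sd / mean, n


def compute_all_indices(
    chm: Raster,
    segments: SegmentMap | None,
    trees: pd.DataFrame,
    radii=DEFAULT_RADII,
    fraction_cc66: float = 0.66,
    exclude_own_segment: bool = True,
) -> pd.DataFrame:
    """CCTH, CC66 and CVTH for every tree at every radius.

    Returns one record per (tree, radius) with an ``edge`` flag set when
    more than half of the buffer falls outside the raster.
    """
    records = []
    xs = trees["x"].to_numpy(dtype=float)
    ys = trees["y"].to_numpy(dtype=float)
    hs = trees["height"].to_numpy(dtype=float)
    ids = trees["tree_id"].to_numpy()
    if "segment_label" in trees.columns:
        own_labels = trees["segment_label"].to_numpy()
    else:
        own_labels = ids
    kdt = cKDTree(np.column_stack([xs, ys]))
    seg_vals = segments.labels.values if segments is not None else None
    chm_vals = chm.values
    cs = chm.cell_size
    for radius in radii:
        full_buffer = np.pi * radius**2 / cs**2
        neighbor_lists = kdt.query_ball_point(np.column_stack([xs, ys]), radius)
        for i in range(len(trees)):
            rows, cols, _ = _buffer_pixels(chm, xs[i], ys[i], radius)
            n_px = len(rows)
            if n_px == 0:
                records.append({"tree_id": ids[i], "radius": radius,
                                "ccth": np.nan, "cc66": np.nan,
                                "cvth": np.nan, "n_neighbors": 0, "edge": True})
                continue
            vals = chm_vals[rows, cols]
            if exclude_own_segment and seg_vals is not None:
                not_own = seg_vals[rows, cols] != own_labels[i]
            else:
                not_own = True
            ccth_v = 100.0 * np.count_nonzero((vals > hs[i]) & not_own) / n_px
            cc66_v = 100.0 * np.count_nonzero(
                (vals > fraction_cc66 * hs[i]) & not_own) / n_px
            nb = [j for j in neighbor_lists[i] if j != i]
            nh = hs[nb]
            if len(nh) >= 2 and nh.mean() > 0:
                cvth_v = 100.0 * nh.std(ddof=1) / nh.mean()
            else:
                cvth_v = np.nan
            records.append({
                "tree_id": ids[i], "radius": radius,
                "ccth": ccth_v, "cc66": cc66_v, "cvth": cvth_v,
                "n_neighbors": len(nh),
                "edge": n_px < 0.5 * full_buffer,
            })
    return pd.DataFrame(records)
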