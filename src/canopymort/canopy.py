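"""Individual-tree delineation from a canopy height model.

Marker-controlled watershed: markers are local maxima of the Gaussian-
smoothed CHM above a minimum height, the watershed floods the inverted CHM
from those markers, and segments whose apex is below the minimum tree
height (default 5 m) are removed.  A greedy matcher scores segmentation
against a ground-truth tree table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.segmentation import watershed as _watershed

from .raster import Raster

MIN_TREE_HEIGHT_M = 5.0


@dataclass
class SegmentMap:
    """Labelled crown segments over a CHM grid.

    ``labels`` holds one positive integer per crown pixel (0 = background);
    ``table`` has one row per segment: label, apex row/col/x/y, apex height
    (max CHM value in the segment) and pixel count.
    """

    labels: Raster
    table: pd.DataFrame

    @property
    def n_segments(self) -> int:
        return len(self.table)


def _segment_table(labels: np.ndarray, chm: Raster) -> pd.DataFrame:
    cols_out = ["label", "apex_row", "apex_col", "apex_x", "apex_y",
                "apex_height", "n_pixels"]
    lab = labels.ravel()
    fg = lab > 0
    if not fg.any():
        return pd.DataFrame(columns=cols_out)
    vals = np.asarray(chm.values, dtype=float).ravel()
    idx = np.nonzero(fg)[0]
    # sort by (label, chm value): the last entry per label is its apex
    order = idx[np.lexsort((vals[idx], lab[idx]))]
    last = np.nonzero(np.diff(lab[order], append=-1))[0]
    apex_idx = order[last]
    labs = lab[apex_idx]
    rr, cc = np.divmod(apex_idx, labels.shape[1])
    x, y = chm.rowcol_to_xy(rr, cc)
    counts = np.bincount(lab[idx])[labs]
    return pd.DataFrame({
        "label": labs.astype(int),
        "apex_row": rr.astype(int), "apex_col": cc.astype(int),
        "apex_x": np.asarray(x, float), "apex_y": np.asarray(y, float),
        "apex_height": vals[apex_idx],
        "n_pixels": counts.astype(int),
    })


def detect_markers(
    chm: Raster,
    min_height: float = MIN_TREE_HEIGHT_M,
    smooth_sigma: float = 1.0,
    min_distance: float = 2.0,
) -> np.ndarray:
    """Treetop markers: local maxima of the smoothed CHM.

    Returns an array of (row, col) marker positions.  ``min_distance`` is in
    metres and translates to a pixel radius for non-maximum suppression.
    """
    vals = np.where(chm.valid_mask, chm.values, 0.0).astype(float)
    if vals.size == 0:
        return np.empty((0, 2), dtype=int)
    smoothed = gaussian(vals, sigma=smooth_sigma, preserve_range=True)
    min_dist_px = max(1, int(round(min_distance / chm.cell_size)))
    peaks = peak_local_max(
        smoothed,
        min_distance=min_dist_px,
        threshold_abs=min_height,
        exclude_border=False,
    )
    return peaks


def watershed_segment(
    chm: Raster,
    markers: np.ndarray,
    min_height: float = MIN_TREE_HEIGHT_M,
    smooth_sigma: float = 1.0,
) -> SegmentMap:
    """Flood the inverted smoothed CHM from the markers.

    Pixels below ``min_height`` are background.  Markers that fall on
    background are dropped with a warning.  Each surviving marker yields
    exactly one segment containing it.
    """
    vals = np.where(chm.valid_mask, chm.values, 0.0).astype(float)
    mask = vals >= min_height
    marker_img = np.zeros(vals.shape, dtype=np.int32)
    kept = 0
    for i, (r, c) in enumerate(np.asarray(markers, dtype=int)):
        if not mask[r, c]:
            warnings.warn(f"marker {i} at ({r}, {c}) on background; dropped")
            continue
        kept += 1
        marker_img[r, c] = kept
    smoothed = gaussian(vals, sigma=smooth_sigma, preserve_range=True)
    if kept == 0:
        labels = np.zeros(vals.shape, dtype=np.int32)
    else:
        labels = _watershed(-smoothed, markers=marker_img, mask=mask)
    lab_raster = Raster(labels, chm.origin, chm.cell_size, nodata=-1, crs=chm.crs)
    return SegmentMap(labels=lab_raster, table=_segment_table(labels, chm))


def filter_small_trees(
    segments: SegmentMap,
    chm: Raster,
    min_tree_height: float = MIN_TREE_HEIGHT_M,
) -> SegmentMap:
    """Drop segments whose apex height is below ``min_tree_height``.

    The rule is a strict inequality: a 5.0 m apex survives the default
    threshold, 4.99 m does not.  Remaining labels are renumbered 1..n.
    """
    keep = segments.table[segments.table["apex_height"] >= min_tree_height]
    old = segments.labels.values
    relabel = np.zeros(int(old.max()) + 1 if old.size else 1, dtype=np.int32)
    for new, lab in enumerate(keep["label"], start=1):
        relabel[lab] = new
    new_labels = relabel[old]
    new_table = keep.reset_index(drop=True).copy()
    new_table["label"] = np.arange(1, len(new_table) + 1)
    lab_raster = segments.labels.copy_with(new_labels)
    return SegmentMap(labels=lab_raster, table=new_table)


def segments_to_trees(segments: SegmentMap) -> pd.DataFrame:
    """Tree table from a segment map (id, x, y, height, crown pixel count)."""
    t = segments.table
    return pd.DataFrame({
        "tree_id": t["label"].to_numpy(),
        "x": t["apex_x"].to_numpy(),
        "y": t["apex_y"].to_numpy(),
        "height": t["apex_height"].to_numpy(),
        "n_pixels": t["n_pixels"].to_numpy(),
    })


def match_to_truth(
    segments: SegmentMap,
    true_trees: pd.DataFrame,
    max_dist: float = 3.0,
    max_height_diff: float = 3.0,
) -> dict:
    """Greedy one-to-one matching of detected apices to true stems.

    Candidate pairs within ``max_dist`` (m) and ``max_height_diff`` (m) are
    matched greedily by increasing apex distance.  Returns the matching
    table and detection recall, precision and F-score.
    """
    det = segments.table
    n_det, n_true = len(det), len(true_trees)
    if n_det == 0 or n_true == 0:
        recall = 0.0
        precision = 0.0 if n_det else 0.0
        return {"matches": pd.DataFrame(columns=["label", "tree_id", "dist"]),
                "recall": recall, "precision": precision, "f_score": 0.0}
    tree_xy = true_trees[["x", "y"]].to_numpy(dtype=float)
    det_xy = det[["apex_x", "apex_y"]].to_numpy(dtype=float)
    kdt = cKDTree(tree_xy)
    pairs = []
    for i in range(n_det):
        for j in kdt.query_ball_point(det_xy[i], max_dist):
            if abs(det["apex_height"].iat[i]
                   - float(true_trees["height"].iloc[j])) <= max_height_diff:
                d = np.hypot(*(det_xy[i] - tree_xy[j]))
                pairs.append((d, i, j))
    pairs.sort()
    used_det: set[int] = set()
    used_true: set[int] = set()
    matches = []
    for d, i, j in pairs:
        if i in used_det or j in used_true:
            continue
        used_det.add(i)
        used_true.add(j)
        matches.append({"label": int(det["label"].iat[i]),
                        "tree_id": true_trees["tree_id"].iloc[j],
                        "dist": float(d)})
    tp = len(matches)
    recall = tp / n_true
    precision = tp / n_det
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return {"matches": pd.DataFrame(matches, columns=["label", "tree_id", "dist"]),
            "recall": recall, "precision": precision, "f_score": f}
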