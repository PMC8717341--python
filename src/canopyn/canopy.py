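"""Canopy height models, dominant-tree detection and crown delineation.

The workflow mirrors the standard UAV-photogrammetry chain: height points
(from a normalized point cloud) are splatted onto a grid with a sub-circle
disk to close pits, a variable-window local-maximum filter finds dominant
tree apices (window width predicted from a height -> crown-width allometry
fitted to field measurements), and marker-controlled watershed on the
inverted CHM delineates one crown per marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union
from skimage.segmentation import watershed

from .raster import CanopyHeightModel

__all__ = ["CrownSegment", "CrownWidthModel", "rasterize_chm",
           "fit_crown_width_model", "detect_trees", "segment_crowns",
           "apply_crown_overrides"]


@dataclass
class CrownWidthModel:
    """OLS line crown_width = intercept + slope * height, floored."""

    slope: float
    intercept: float
    min_width_m: float = 1.0

    def __call__(self, height_m) -> np.ndarray:
        pred = self.intercept + self.slope * np.asarray(height_m, dtype=float)
        return np.maximum(pred, self.min_width_m)


@dataclass
class CrownSegment:
    """One delineated crown: marker cell, label id, outline, apex height."""

    tree_id: int
    marker: tuple[int, int]         # (row, col) of the seed cell
    label: int                      # id in the companion label raster
    polygon: object                 # shapely Polygon in scene metres
    apex_height_m: float
    n_cells: int


def rasterize_chm(points, pixel_size_m: float, subcircle_radius_m: float = 0.5,
                  extent_m: float | None = None) -> CanopyHeightModel:
    """Grid height points into a pit-filled CHM.

    Each (x, y, height) point is splatted as a disk of the given radius; a
    cell takes the maximum height of any disk covering its center, and cells
    no disk reaches stay 0 (ground).  This is the sub-circle pit-closing
    approach used when gridding photogrammetric point clouds at coarser
    resolution than the point spacing.

    Parameters
    ----------
    points : array-like of shape (n, 3)
        Columns x, y, z with z = height above ground (>= 0).
    extent_m : float, optional
        Side of the square output grid anchored at (0, 0); defaults to the
        smallest grid covering all points (plus their disks).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("need at least one height point")
    if pts.shape[1] != 3:
        raise ValueError("points must have columns x, y, height")
    if pixel_size_m <= 0:
        raise ValueError("pixel size must be positive")
    if subcircle_radius_m < 0:
        raise ValueError("subcircle radius cannot be negative")

    if extent_m is None:
        extent_m = float(np.max(pts[:, :2]) + subcircle_radius_m + pixel_size_m)
    n_cells = max(1, int(np.ceil(extent_m / pixel_size_m)))
    heights = np.zeros((n_cells, n_cells))
    centers = (np.arange(n_cells) + 0.5) * pixel_size_m

    for x, y, z in pts:
        if subcircle_radius_m == 0:
            col = min(n_cells - 1, max(0, int(x // pixel_size_m)))
            row = min(n_cells - 1, max(0, int(y // pixel_size_m)))
            heights[row, col] = max(heights[row, col], z)
            continue
        c0 = max(0, int((x - subcircle_radius_m) // pixel_size_m))
        c1 = min(n_cells, int((x + subcircle_radius_m) // pixel_size_m) + 1)
        r0 = max(0, int((y - subcircle_radius_m) // pixel_size_m))
        r1 = min(n_cells, int((y + subcircle_radius_m) // pixel_size_m) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        dx = centers[c0:c1] - x
        dy = centers[r0:r1] - y
        covered = dx[None, :] ** 2 + dy[:, None] ** 2 <= subcircle_radius_m ** 2
        patch = heights[r0:r1, c0:c1]
        np.maximum(patch, np.where(covered, z, 0.0), out=patch)

    return CanopyHeightModel(heights, pixel_size_m, fill_method="subcircle-max")


def fit_crown_width_model(trees: pd.DataFrame,
                          min_width_m: float = 1.0) -> CrownWidthModel:
    """Fit the height -> mean crown width line from field measurements.

    Ordinary least squares on (height_m, crown_width_m); predictions are
    floored at ``min_width_m`` so the detector window never collapses.
    """
    h = np.asarray(trees["height_m"], dtype=float)
    w = np.asarray(trees["crown_width_m"], dtype=float)
    ok = np.isfinite(h) & np.isfinite(w)
    h, w = h[ok], w[ok]
    if len(h) < 2:
        raise ValueError("need at least two trees to fit the allometry")
    if np.ptp(h) == 0:
        raise ValueError("all tree heights equal; allometry is degenerate")
    slope, intercept = np.polyfit(h, w, 1)
    return CrownWidthModel(float(slope), float(intercept), min_width_m)


def _plateau_markers(candidates: np.ndarray) -> list[tuple[int, int]]:
    """Merge connected candidate plateaus; each contributes its centroid cell."""
    labels, n = ndimage.label(candidates)  # 8-connectivity default is fine here
    markers = []
    for r, c in ndimage.center_of_mass(candidates, labels, range(1, n + 1)):
        markers.append((int(round(r)), int(round(c))))
    return markers


def detect_trees(chm: CanopyHeightModel,
                 window_fn: Callable[[np.ndarray], np.ndarray],
                 min_height_m: float) -> list[tuple[int, int]]:
    """Variable-window local-maximum tree detection.

    A cell is a marker iff its height is >= ``min_height_m`` and it is the
    maximum within the square window of width ``window_fn(height)`` (metres)
    centered on it.  Cells tied across a flat plateau are merged and the
    plateau centroid becomes the single marker, which keeps the result
    deterministic and orientation-independent.

    Returns marker cells as (row, col) tuples, sorted.
    """
    h = chm.heights
    tall = h >= min_height_m
    if not tall.any():
        return []
    widths_m = np.asarray(window_fn(h), dtype=float)
    if np.any(widths_m[tall] <= 0):
        raise ValueError("window function must be positive over canopy heights")
    # half-width in cells; window size = 2k+1
    half = np.maximum(1, np.round(widths_m / 2.0 / chm.pixel_size_m)).astype(int)

    candidates = np.zeros_like(tall)
    for k in np.unique(half[tall]):
        sel = tall & (half == k)
        if not sel.any():
            continue
        local_max = ndimage.maximum_filter(h, size=2 * int(k) + 1,
                                           mode="nearest")
        candidates |= sel & (h >= local_max)
    return sorted(_plateau_markers(candidates))


def _label_polygon(labels: np.ndarray, lab: int, pixel_size_m: float):
    """Outline of one label as a shapely polygon (union of pixel squares)."""
    rows, cols = np.nonzero(labels == lab)
    squares = [box(c * pixel_size_m, r * pixel_size_m,
                   (c + 1) * pixel_size_m, (r + 1) * pixel_size_m)
               for r, c in zip(rows, cols)]
    return unary_union(squares)


def segment_crowns(chm: CanopyHeightModel, markers: Sequence[tuple[int, int]],
                   min_height_m: float, polygons: bool = True
                   ) -> tuple[list[CrownSegment], np.ndarray]:
    """Marker-controlled watershed crown delineation.

    Watershed runs on the inverted CHM seeded at the markers, restricted to
    cells at or above ``min_height_m`` (4-neighbour connectivity, matching
    the rook adjacency used for landscape aggregation).  Returns one
    :class:`CrownSegment` per marker plus the label raster (0 = unlabeled);
    segment ``tree_id`` is the marker's position in the input sequence.
    """
    h = chm.heights
    mask = h >= min_height_m
    seeds = np.zeros(h.shape, dtype=int)
    for i, (r, c) in enumerate(markers, start=1):
        if not (0 <= r < h.shape[0] and 0 <= c < h.shape[1]):
            raise ValueError(f"marker {(r, c)} outside the raster")
        if not mask[r, c]:
            raise ValueError(f"marker {(r, c)} lies below min_height_m")
        seeds[r, c] = i
    labels = watershed(-h, markers=seeds, mask=mask, connectivity=1)

    segments = []
    for i, (r, c) in enumerate(markers, start=1):
        cells = labels == i
        apex = float(h[cells].max())
        poly = _label_polygon(labels, i, chm.pixel_size_m) if polygons else None
        segments.append(CrownSegment(tree_id=i - 1, marker=(r, c), label=i,
                                     polygon=poly, apex_height_m=apex,
                                     n_cells=int(cells.sum())))
    return segments, labels


def match_crowns_to_trees(segments: list[CrownSegment], labels: np.ndarray,
                          trees: pd.DataFrame, pixel_size_m: float
                          ) -> list[CrownSegment]:
    """Re-key detected crowns by the field tree whose stem falls inside them.

    Each tree's (x, y) is looked up in the label raster; the covering
    segment is returned with ``tree_id`` set to that tree's id.  Crowns
    containing no field tree are dropped; when two trees land in one crown
    the first (table order) wins with a warning.
    """
    import dataclasses
    import warnings

    by_label = {seg.label: seg for seg in segments}
    claimed: dict[int, int] = {}
    out = []
    for row in trees.itertuples():
        r = int(row.y // pixel_size_m)
        c = int(row.x // pixel_size_m)
        if not (0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]):
            continue
        lab = int(labels[r, c])
        if lab <= 0 or lab not in by_label:
            continue
        if lab in claimed:
            warnings.warn(f"trees {claimed[lab]} and {row.tree_id} share "
                          f"crown label {lab}; keeping the first", stacklevel=2)
            continue
        claimed[lab] = row.tree_id
        out.append(dataclasses.replace(by_label[lab], tree_id=int(row.tree_id)))
    return out


def apply_crown_overrides(segments: list[CrownSegment], labels: np.ndarray,
                          overrides: dict[int, object],
                          chm: CanopyHeightModel
                          ) -> tuple[list[CrownSegment], np.ndarray]:
    """Replace selected crown outlines with externally supplied polygons.

    Stands in for the manual crown correction step of a field campaign
    (roughly a tenth of delineated sample trees typically need it):
    ``overrides`` maps ``tree_id`` to a shapely polygon in scene metres.  The
    label raster is rewritten so overridden cells carry the crown's label.
    """
    from shapely import contains_xy

    labels = labels.copy()
    ny, nx = labels.shape
    xs = (np.arange(nx) + 0.5) * chm.pixel_size_m
    ys = (np.arange(ny) + 0.5) * chm.pixel_size_m
    xx, yy = np.meshgrid(xs, ys)
    out = []
    for seg in segments:
        if seg.tree_id not in overrides:
            out.append(seg)
            continue
        poly = overrides[seg.tree_id]
        inside = contains_xy(poly, xx.ravel(), yy.ravel()).reshape(ny, nx)
        labels[labels == seg.label] = 0
        labels[inside] = seg.label
        cells = inside & (chm.heights > 0)
        apex = float(chm.heights[inside].max()) if inside.any() else 0.0
        out.append(CrownSegment(seg.tree_id, seg.marker, seg.label, poly,
                                apex, int(inside.sum())))
    return out, labels
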