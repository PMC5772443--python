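"""Extent of occurrence, range clipping, area of occupancy, sensitivity.

The extent of occurrence is the convex hull of a species' cleaned occurrence
points in degree space, buffered by 3 degrees (the package-wide equivalence of
300 km used by the IDW dispersal limit). Suitability or binary maps are
clipped by zeroing every cell whose center falls outside the buffered hull;
the clipped binary map's 1-cell count is the predicted area of occupancy.
Sensitivity (true positive rate) is the fraction of cells containing at least
one reference point that the binary map predicts present — points, not visits,
define the reference at cell level, so duplicated points in one cell count
once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint, Point
from shapely.prepared import prep

from .grid import RasterLayer, cell_centers, points_to_cells

__all__ = ["HullBuffer", "hull_buffer", "clip_to_range", "area_of_occupancy",
           "sensitivity"]


@dataclass
class HullBuffer:
    """Convex hull of occurrence points plus a buffer, in degree space."""

    hull: object  # shapely geometry (polygon, segment or point)
    buffered: object  # shapely polygon
    buffer_deg: float


def hull_buffer(points, buffer_deg: float = 3.0) -> HullBuffer:
    """Convex hull of (lon, lat) points buffered by ``buffer_deg`` degrees.

    Degenerate inputs are handled naturally: one point buffers to a disk, two
    points to a stadium around the segment.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("need at least one (lon, lat) point")
    if pts.shape[0] == 1:
        hull = Point(pts[0])
    else:
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    buffered = hull.buffer(buffer_deg) if buffer_deg > 0 else hull
    return HullBuffer(hull=hull, buffered=buffered, buffer_deg=buffer_deg)


def clip_to_range(layer: RasterLayer, hull: HullBuffer) -> RasterLayer:
    """Zero every cell whose center lies outside the buffered hull."""
    lon, lat = cell_centers(layer.grid)
    poly = prep(hull.buffered)
    inside = np.array(
        [poly.covers(Point(x, y)) for x, y in zip(lon.ravel(), lat.ravel())]
    ).reshape(layer.grid.shape)
    out = layer.copy()
    out.values = np.where(inside, out.values, 0.0)
    return out


def area_of_occupancy(bmap: RasterLayer) -> int:
    """Number of predicted-present (value 1) valid cells."""
    vals = bmap.values[bmap.valid]
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("area of occupancy requires a binary map")
    return int(vals.sum())


def sensitivity(bmap: RasterLayer, reference_points) -> float:
    """True positive rate of a binary map against reference presence points.

    Reference points are reduced to the set of valid cells they fall in;
    returns the fraction of those cells where the map is 1, or NaN when no
    reference point maps to a valid cell.
    """
    pts = np.asarray(reference_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("reference_points must be (n, 2) lon/lat")
    row, col = points_to_cells(pts[:, 0], pts[:, 1], bmap.grid)
    ok = row >= 0
    valid_cell = np.zeros_like(ok)
    valid_cell[ok] = bmap.valid[row[ok], col[ok]]
    ok &= valid_cell
    cells = {(r, c) for r, c in zip(row[ok], col[ok])}
    if not cells:
        return float("nan")
    hits = sum(1 for r, c in cells if bmap.values[r, c] == 1.0)
    return hits / len(cells)
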