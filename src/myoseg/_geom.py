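"""Shared pixel-corner geometry helpers.

A region is a set of unit-square pixels; its physical footprint is the union
of those squares.  Shape measures (convexity, Feret) are computed on the
convex hull of the pixel *corners*, so a filled axis-aligned rectangle is
exactly convex and a w-pixel-wide bar has width exactly w.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull


def region_coords(region) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a region (boolean raster or (rows, cols) pair) to index arrays."""
    if isinstance(region, tuple) and len(region) == 2:
        rows, cols = (np.asarray(a, dtype=np.int64) for a in region)
    else:
        arr = np.asarray(region)
        if arr.dtype != bool:
            arr = arr > 0
        rows, cols = np.nonzero(arr)
    if rows.size == 0:
        raise ValueError("region is empty")
    return rows, cols


def pixel_corners(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Unique (x, y) corner points of the unit squares covering the pixels."""
    pts = np.stack([cols, rows], axis=1)
    corners = np.concatenate(
        [pts + off for off in ((0, 0), (0, 1), (1, 0), (1, 1))], axis=0
    )
    return np.unique(corners, axis=0).astype(np.float64)


def corner_hull_vertices(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Convex-hull vertices (counter-clockwise (x, y)) of the pixel corners."""
    corners = pixel_corners(rows, cols)
    hull = ConvexHull(corners)
    return corners[hull.vertices]


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a simple polygon given as ordered (x, y) vertices."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
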