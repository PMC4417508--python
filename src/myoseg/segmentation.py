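"""Fiber segmentation: minima suppression, watershed, and manual separations.

The outline channel (e.g. laminin) is bright along fiber borders and dark
inside fibers, so fiber interiors are intensity basins.  Shallow basins
caused by noise are removed before the watershed so each fiber floods from
a single minimum.  Basins use 8-connectivity throughout.
"""

from __future__ import annotations

import json

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.morphology import local_minima, reconstruction
from skimage.segmentation import watershed

from .image_io import AnalysisParams, ChannelRole, SectionImage

__all__ = [
    "suppress_minima",
    "watershed_segment",
    "initial_segmentation",
    "apply_separations",
    "load_strokes",
    "overlay_boundaries",
]

_FULL = np.ones((3, 3), bool)  # 8-connectivity footprint


def suppress_minima(gray: np.ndarray, depth: float) -> np.ndarray:
    """Suppress regional minima shallower than ``depth`` (8-bit units).

    Morphological reconstruction by erosion of ``input + depth`` over the
    input: minima whose dynamics (depth below the lowest escape saddle) are
    below ``depth`` are filled, each surviving basin becomes a single flat
    lake, and the result is pointwise >= the input with ``depth == 0`` the
    identity.  A perfectly flat input is returned unchanged.
    """
    if depth < 0:
        raise ValueError(f"depth must be >= 0 (got {depth})")
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("gray must be a 2-D raster")
    f = gray.astype(np.float64)
    if depth == 0 or f.size == 0 or np.all(f == f.flat[0]):
        return f.copy()
    return reconstruction(f + depth, f, method="erosion", footprint=_FULL)


def watershed_segment(gray: np.ndarray) -> np.ndarray:
    """Watershed transform of an intensity raster into labeled basins.

    Each regional minimum (8-connected) seeds one basin; ridge pixels get
    label 0.  A perfectly flat image is a single basin with no ridge.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("watershed input must be 2-D")
    markers, n = ndi.label(local_minima(gray, connectivity=2), structure=_FULL)
    if n == 0:  # flat image: one basin, no ridges
        return np.ones(gray.shape, dtype=np.int64)
    return watershed(gray, markers, connectivity=2, watershed_line=True).astype(np.int64)


def initial_segmentation(
    image: SectionImage,
    roles: ChannelRole | None = None,
    params: AnalysisParams | None = None,
) -> np.ndarray:
    """Segment fibers from the outline channel: suppress minima, then watershed."""
    params = params or AnalysisParams()
    roles = roles or params.roles()
    gray = image.channel(roles.outline_channel)
    smoothed = suppress_minima(gray, params.segmentation_smoothing)
    return watershed_segment(smoothed)


def load_strokes(path) -> list[list[tuple[float, float]]]:
    """Read separation strokes from a JSON file: a list of [[x, y], ...] polylines."""
    with open(path) as fh:
        data = json.load(fh)
    strokes = [[(float(x), float(y)) for x, y in poly] for poly in data]
    for poly in strokes:
        if len(poly) < 2:
            raise ValueError("each separation stroke needs at least 2 vertices")
    return strokes


def apply_separations(mask: np.ndarray, strokes) -> np.ndarray:
    """Cut fibers along freehand strokes and relabel the resulting pieces.

    Stroke pixels become boundary (label 0).  A label split into several
    connected components keeps its original label on one piece; the others
    receive fresh labels above the current maximum.  Untouched labels are
    preserved.
    """
    mask = np.asarray(mask)
    if not strokes:
        return mask.copy()
    out = mask.copy()
    h, w = out.shape
    touched: set[int] = set()
    for poly in strokes:
        if len(poly) < 2:
            raise ValueError("each separation stroke needs at least 2 vertices")
        for (x0, y0), (x1, y1) in zip(poly[:-1], poly[1:]):
            for x, y in ((x0, y0), (x1, y1)):
                if not (0 <= x < w and 0 <= y < h):
                    raise ValueError(f"stroke vertex ({x}, {y}) outside image bounds")
            rr, cc = draw_line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
            touched.update(int(v) for v in np.unique(mask[rr, cc]) if v > 0)
            out[rr, cc] = 0
    next_label = int(out.max()) + 1
    for lab in sorted(touched):
        region = out == lab
        if not region.any():
            continue
        pieces, n = ndi.label(region, structure=_FULL)
        for k in range(2, n + 1):
            out[pieces == k] = next_label
            next_label += 1
    return out


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Boolean raster of background pixels adjacent (8-conn) to >= 2 labels."""
    mask = np.asarray(mask)
    # per-pixel max and min positive label over the 3x3 neighborhood
    hi = ndi.maximum_filter(mask, footprint=_FULL)
    no_bg = np.where(mask > 0, mask, np.iinfo(np.int64).max)
    lo = ndi.minimum_filter(no_bg, footprint=_FULL)
    return (mask == 0) & (hi > 0) & (lo < hi) & (lo != np.iinfo(np.int64).max)


def overlay_boundaries(image: SectionImage, mask: np.ndarray) -> np.ndarray:
    """Render the original image with inter-fiber ridge pixels painted white."""
    mask = np.asarray(mask)
    if mask.shape != image.pixels.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {image.pixels.shape[:2]}"
        )
    out = image.pixels.copy()
    out[boundary_pixels(mask)] = 255
    return out
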