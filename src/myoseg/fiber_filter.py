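"""Shape-based removal of non-fiber objects from a label mask.

Regions are rejected, in fixed order, for: touching the image edge, area
outside ``[min_fiber_area, max_fiber_area]`` μm², eccentricity above
``max_eccentricity``, or convexity below ``min_convexity``.  Only the first
failing rule is recorded per region.  A manual removal step deletes listed
labels outright.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ._geom import corner_hull_vertices, polygon_area, region_coords
from .image_io import AnalysisParams

__all__ = ["eccentricity", "convexity", "filter_fibers", "remove_objects"]


def eccentricity(region) -> float:
    """Eccentricity of the ellipse with the region's central second moments.

    0 for a circle, 1 for a line segment: the ratio of the focal distance to
    the major axis of the moment-equivalent ellipse.
    """
    rows, cols = region_coords(region)
    r = rows - rows.mean()
    c = cols - cols.mean()
    mu20 = np.mean(c * c)
    mu02 = np.mean(r * r)
    mu11 = np.mean(r * c)
    common = np.sqrt((mu20 - mu02) ** 2 + 4.0 * mu11**2)
    lam1 = 0.5 * (mu20 + mu02 + common)  # major-axis variance
    lam2 = 0.5 * (mu20 + mu02 - common)
    if lam1 <= 0:  # single pixel: degenerate, treat as circular
        return 0.0
    return float(np.sqrt(max(0.0, 1.0 - lam2 / lam1)))


def convexity(region) -> float:
    """Region area divided by the area of its pixel-corner convex hull.

    Exactly 1 for regions whose pixel-square union is convex (the hull is
    then the union's own outline); < 1 wherever there are concavities.
    """
    rows, cols = region_coords(region)
    hull_area = polygon_area(corner_hull_vertices(rows, cols))
    return float(rows.size / hull_area)


def _region_iter(mask: np.ndarray):
    """Yield (label, rows, cols, bbox_slices) for each positive label."""
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    slices = ndi.find_objects(mask, max_label=int(mask.max()) if mask.size else 0)
    for lab in labels:
        sl = slices[int(lab) - 1]
        sub = mask[sl] == lab
        rr, cc = np.nonzero(sub)
        yield int(lab), rr + sl[0].start, cc + sl[1].start, sl


def filter_fibers(
    mask: np.ndarray, params: AnalysisParams | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply the edge/area/eccentricity/convexity rules to every label.

    Returns the filtered mask (kept labels unchanged, rejected ones zeroed)
    and a report with one row per input label: ``label, kept, reason,
    area_um2, eccentricity, convexity``.
    """
    params = params or AnalysisParams()
    if not params.pixel_size > 0:
        raise ValueError("pixel_size must be set and > 0")
    mask = np.asarray(mask)
    h, w = mask.shape
    px_area = params.pixel_size**2
    rows_out = []
    out = mask.copy()
    for lab, rr, cc, _ in _region_iter(mask):
        area = rr.size * px_area
        ecc = eccentricity((rr, cc))
        conv = convexity((rr, cc))
        reason = ""
        if rr.min() == 0 or rr.max() == h - 1 or cc.min() == 0 or cc.max() == w - 1:
            reason = "edge"
        elif area < params.min_fiber_area:
            reason = "too_small"
        elif area > params.max_fiber_area:
            reason = "too_large"
        elif ecc > params.max_eccentricity:
            reason = "eccentricity"
        elif conv < params.min_convexity:
            reason = "convexity"
        kept = reason == ""
        if not kept:
            out[rr, cc] = 0
        rows_out.append(
            dict(label=lab, kept=kept, reason=reason, area_um2=area,
                 eccentricity=ecc, convexity=conv)
        )
    report = pd.DataFrame(
        rows_out, columns=["label", "kept", "reason", "area_um2", "eccentricity", "convexity"]
    )
    return out, report


def remove_objects(mask: np.ndarray, ids) -> tuple[np.ndarray, list[int]]:
    """Zero out the listed labels (manual deletion of non-fiber objects).

    Unknown ids are ignored and returned so the caller can report them.
    """
    mask = np.asarray(mask)
    out = mask.copy()
    present = set(int(v) for v in np.unique(mask) if v > 0)
    unknown = [int(i) for i in ids if int(i) not in present]
    hit = [int(i) for i in ids if int(i) in present]
    if hit:
        out[np.isin(out, hit)] = 0
    return out, unknown
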