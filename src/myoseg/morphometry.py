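"""Per-fiber geometry: centroids, Feret diameters, areas, and summaries."""

from __future__ import annotations

import warnings

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from ._geom import corner_hull_vertices, region_coords
from .fiber_filter import _region_iter

__all__ = ["feret_diameters", "fiber_properties", "summarize", "plot_histograms"]

#: Per-fiber property columns, in output order.
PROPERTY_COLUMNS = [
    "label",
    "centroid_x",
    "centroid_y",
    "max_feret_um",
    "min_feret_um",
    "feret_direction_rad",
    "area_um2",
]


def feret_diameters(region) -> tuple[float, float, float]:
    """Rotating-calipers Feret diameters of a pixel region, in pixels.

    Returns ``(min_feret, max_feret, direction)`` where ``min_feret`` is the
    smallest caliper width over all orientations, ``max_feret`` the largest
    point-pair distance, and ``direction`` the orientation in ``[0, π)``
    radians of the supporting edge at the minimal width (i.e. the direction
    along which the minimal caliper slides).  Computed on the convex hull of
    the pixel corners, so a w-pixel-wide bar has ``min_feret == w`` exactly.
    """
    rows, cols = region_coords(region)
    verts = corner_hull_vertices(rows, cols)  # CCW (x, y)
    edges = np.roll(verts, -1, axis=0) - verts
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    units = edges / lengths[:, None]
    # width against each edge: max distance of any vertex from the edge line
    rel = verts[None, :, :] - verts[:, None, :]  # [edge, vertex, xy]
    dists = np.abs(units[:, 0, None] * rel[:, :, 1] - units[:, 1, None] * rel[:, :, 0])
    widths = dists.max(axis=1)
    i = int(np.argmin(widths))
    min_feret = float(widths[i])
    direction = float(np.arctan2(units[i, 1], units[i, 0])) % np.pi
    diffs = verts[:, None, :] - verts[None, :, :]
    max_feret = float(np.sqrt((diffs**2).sum(axis=2).max()))
    return min_feret, max_feret, direction


def fiber_properties(mask: np.ndarray, pixel_size: float) -> pd.DataFrame:
    """One row of geometric properties per fiber, ordered by ascending label.

    Centroids are in pixels (x = column, y = row); Feret diameters in μm,
    areas in μm².
    """
    if not pixel_size > 0:
        raise ValueError("pixel_size must be > 0")
    mask = np.asarray(mask)
    records = []
    for lab, rr, cc, _ in _region_iter(mask):
        mn, mx, ang = feret_diameters((rr, cc))
        records.append(
            dict(
                label=lab,
                centroid_x=cc.mean(),
                centroid_y=rr.mean(),
                max_feret_um=mx * pixel_size,
                min_feret_um=mn * pixel_size,
                feret_direction_rad=ang,
                area_um2=rr.size * pixel_size**2,
            )
        )
    if not records:
        warnings.warn("mask contains no fibers; returning an empty table")
    return pd.DataFrame(records, columns=PROPERTY_COLUMNS)


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD (n-1), and SEM for each numeric per-fiber property."""
    if len(records) == 0:
        raise ValueError("cannot summarize an empty property table")
    cols = [c for c in records.columns if c != "label"]
    n = len(records)
    mean = records[cols].mean()
    sd = records[cols].std(ddof=1) if n > 1 else pd.Series(0.0, index=cols)
    sem = sd / np.sqrt(n)
    out = pd.DataFrame([mean, sd, sem], index=["mean", "sd", "sem"])
    out.insert(0, "n", n)
    return out


def plot_histograms(records: pd.DataFrame, out_path) -> bool:
    """Export min-Feret and CSA histograms; returns False (with a warning) if empty."""
    if len(records) == 0:
        warnings.warn("no fibers to plot; histogram not written")
        return False
    fig, axes = plt.subplots(2, 1, figsize=(6, 7))
    axes[0].hist(records["min_feret_um"], bins=20, color="tab:blue")
    axes[0].set_xlabel("minimum Feret diameter (μm)")
    axes[0].set_ylabel("fibers")
    axes[1].hist(records["area_um2"], bins=20, color="tab:green")
    axes[1].set_xlabel("fiber CSA (μm²)")
    axes[1].set_ylabel("fibers")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return True
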