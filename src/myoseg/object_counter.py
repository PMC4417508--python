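"""Counting of extra-fiber objects (e.g. capillaries) in a stain channel.

The channel is smoothed like the nuclear channel, thresholded (Otsu by
default), and 8-connected components become objects.  No size filtering is
applied here; per-object areas are exported so downstream users can filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .central_nuclei import smooth_bright
from .fiber_typing import otsu_threshold

__all__ = ["count_objects", "ObjectTable"]

_FULL = np.ones((3, 3), bool)


@dataclass
class ObjectTable:
    """Per-object areas/centroids plus the total count and threshold used."""

    table: pd.DataFrame  # columns: object, area_um2, centroid_x, centroid_y
    threshold: float
    smoothed: np.ndarray
    binary: np.ndarray

    @property
    def count(self) -> int:
        return len(self.table)


def count_objects(
    channel: np.ndarray,
    smoothing: float,
    pixel_size: float,
    threshold: float | None = None,
) -> ObjectTable:
    """Count 8-connected bright objects in ``channel``.

    ``threshold=None`` applies Otsu's method to the smoothed pixel
    histogram (a constant channel then raises and a manual threshold must
    be given).  Centroids are in pixels (x = column, y = row).
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    if not pixel_size > 0:
        raise ValueError("pixel_size must be > 0")
    smoothed = smooth_bright(channel, smoothing)
    if threshold is None:
        thr = otsu_threshold(smoothed.ravel())
    else:
        thr = float(threshold)
    binary = smoothed > thr
    labels, n = ndi.label(binary, structure=_FULL)
    if n:
        idx = np.arange(1, n + 1)
        sizes = ndi.sum_labels(np.ones_like(labels, float), labels, index=idx)
        centroids = ndi.center_of_mass(binary, labels, idx)
        cy, cx = np.array(centroids).T
    else:
        sizes = np.empty(0)
        cx = cy = np.empty(0)
    table = pd.DataFrame(
        dict(
            object=np.arange(1, n + 1),
            area_um2=sizes * pixel_size**2,
            centroid_x=cx,
            centroid_y=cy,
        )
    )
    return ObjectTable(table=table, threshold=thr, smoothed=smoothed, binary=binary)
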