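"""Centrally-nucleated-fiber (CNF) detection.

A fiber is a CNF when thresholded nuclear staining of at least
``min_nuclear_size`` μm² (aggregated over pixels) lies deeper than
``nuclear_border_distance`` μm inside the fiber.  The nuclear channel is
smoothed by suppressing shallow *maxima* (the polarity-correct counterpart
of the minima suppression used for segmentation, since nuclei are bright),
then thresholded with Otsu's method unless a manual threshold is given.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .fiber_typing import otsu_threshold
from .segmentation import suppress_minima

__all__ = [
    "central_region_mask",
    "smooth_bright",
    "detect_nuclei",
    "classify_cnf",
    "CNFResult",
    "NucleiDetection",
]

_FULL = np.ones((3, 3), bool)


def smooth_bright(channel: np.ndarray, depth: float) -> np.ndarray:
    """Suppress bright local maxima shallower than ``depth`` (8-bit units)."""
    channel = np.asarray(channel, dtype=np.float64)
    return 255.0 - suppress_minima(255.0 - channel, depth)


def central_region_mask(
    mask: np.ndarray, border_distance: float, pixel_size: float
) -> np.ndarray:
    """Erode each fiber to the pixels deeper than ``border_distance`` μm inside it.

    Distance is exact Euclidean, measured to the nearest pixel that is not
    part of the fiber (another label, background, or off the image edge).
    Fibers smaller than the border distance vanish entirely.
    """
    if border_distance < 0:
        raise ValueError("border_distance must be >= 0")
    if not pixel_size > 0:
        raise ValueError("pixel_size must be > 0")
    mask = np.asarray(mask)
    d_px = border_distance / pixel_size
    out = np.zeros_like(mask)
    slices = ndi.find_objects(mask, max_label=int(mask.max()) if mask.size else 0)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        # pad the bounding box by 1 so the distance transform sees the
        # surroundings; image edges pad as non-fiber
        rs = slice(max(sl[0].start - 1, 0), min(sl[0].stop + 1, mask.shape[0]))
        cs = slice(max(sl[1].start - 1, 0), min(sl[1].stop + 1, mask.shape[1]))
        inside = np.pad(mask[rs, cs] == lab, 1, constant_values=False)
        dist = ndi.distance_transform_edt(inside)
        keep = dist > d_px
        sub = out[rs, cs]
        sub[keep[1:-1, 1:-1]] = lab
    return out


class NucleiDetection(NamedTuple):
    binary: np.ndarray
    threshold: float
    smoothed: np.ndarray


def detect_nuclei(
    channel: np.ndarray,
    smoothing: float,
    pixel_size: float,
    threshold: float | None = None,
    min_nuclear_size: float = 0.0,
) -> NucleiDetection:
    """Smooth, threshold, and size-filter the nuclear channel.

    Otsu's threshold over the smoothed pixel histogram is used when
    ``threshold`` is None; a constant channel then raises, and a manual
    threshold must be supplied instead.  8-connected components smaller than
    ``min_nuclear_size`` μm² are discarded as random staining.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    smoothed = smooth_bright(channel, smoothing)
    if threshold is None:
        thr = otsu_threshold(smoothed.ravel())
    else:
        thr = float(threshold)
    binary = smoothed > thr
    if min_nuclear_size > 0 and binary.any():
        labels, n = ndi.label(binary, structure=_FULL)
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes * pixel_size**2 < min_nuclear_size) + 1
        if small.size:
            binary &= ~np.isin(labels, small)
    return NucleiDetection(binary=binary, threshold=thr, smoothed=smoothed)


@dataclass
class CNFResult:
    """Per-fiber central-nuclear areas and CNF calls, with group summaries."""

    table: pd.DataFrame  # columns: label, area_um2, central_nuclear_area_um2, call
    threshold: float
    summary: pd.DataFrame  # rows all/cnf/non_cnf

    @property
    def percent_cnf(self) -> float:
        return 100.0 * self.table["call"].sum() / len(self.table)


def classify_cnf(
    mask: np.ndarray,
    central: np.ndarray,
    nuclei: np.ndarray,
    min_nuclear_size: float,
    pixel_size: float,
    threshold: float = float("nan"),
) -> CNFResult:
    """Call each fiber CNF (1) or PNF (0) from nuclear area in its central region."""
    mask = np.asarray(mask)
    central = np.asarray(central)
    nuclei = np.asarray(nuclei, dtype=bool)
    if not mask.shape == central.shape == nuclei.shape:
        raise ValueError("mask, central regions, and nuclei rasters must share a shape")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("mask contains no fibers")
    px2 = pixel_size**2
    fiber_px = ndi.sum_labels(np.ones_like(mask, float), labels=mask, index=labels)
    central_nuc = np.where(nuclei, central, 0)
    nuc_px = ndi.sum_labels(np.ones_like(mask, float), labels=central_nuc, index=labels)
    table = pd.DataFrame(
        dict(
            label=labels.astype(int),
            area_um2=fiber_px * px2,
            central_nuclear_area_um2=nuc_px * px2,
            call=(nuc_px * px2 >= min_nuclear_size).astype(int),
        )
    )
    groups = {
        "all": table,
        "cnf": table[table["call"] == 1],
        "non_cnf": table[table["call"] == 0],
    }
    rows = []
    for name, sub in groups.items():
        rows.append(
            dict(
                group=name,
                n=len(sub),
                mean_area_um2=sub["area_um2"].mean() if len(sub) else np.nan,
                mean_central_nuclear_area_um2=(
                    sub["central_nuclear_area_um2"].mean() if len(sub) else np.nan
                ),
                percent_of_fibers=100.0 * len(sub) / len(table),
            )
        )
    return CNFResult(table=table, threshold=threshold, summary=pd.DataFrame(rows))


def render_cnf_overlay(
    image_pixels: np.ndarray,
    mask: np.ndarray,
    central: np.ndarray,
    nuclei: np.ndarray,
    calls: pd.DataFrame,
) -> np.ndarray:
    """Diagnostic rendering: border ring red, thresholded nuclei blue, CNFs white."""
    out = np.asarray(image_pixels).copy()
    border_ring = (mask > 0) & (central == 0)
    out[border_ring] = [180, 40, 40]
    out[np.asarray(nuclei, bool)] = [40, 40, 220]
    cnf_labels = calls.loc[calls["call"] == 1, "label"].to_numpy()
    out[np.isin(mask, cnf_labels) & np.asarray(nuclei, bool)] = [255, 255, 255]
    return out
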