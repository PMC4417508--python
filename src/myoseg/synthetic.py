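"""Ground-truthed synthetic immunofluorescent muscle sections.

Fibers are the cells of a Lloyd-relaxed Voronoi tessellation.  The outline
channel paints a bright band along cell bisectors over dark interiors (the
"laminin" stain); the type channel fills a chosen subset of fibers; the
nuclei channel places one deep central disk per CNF fiber and peripheral
disks for the rest; the object channel puts disks at tessellation junctions
(interstitial "capillaries").  Everything is deterministic given the seed,
and the returned ground truth records the label map, per-fiber type and CNF
flags, and object centroids.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .image_io import SectionImage, read_mask, write_mask

__all__ = ["SectionSpec", "GroundTruth", "generate_section", "write_ground_truth",
           "read_ground_truth"]


@dataclass
class SectionSpec:
    """Parameters of a synthetic section.  All intensities are 8-bit."""

    size: int = 512
    pixel_size: float = 0.645
    n_fibers: int = 60
    boundary_width: float = 3.0
    boundary_intensity: int = 200
    interior_intensity: int = 20
    fraction_positive: float = 0.3
    positive_intensity: int = 180
    negative_intensity: int = 30
    fraction_cnf: float = 0.3
    nucleus_radius: int = 4
    nucleus_intensity: int = 200
    #: central nuclei are placed deeper than this many px from the boundary
    #: band, so they clear the default 10 μm border region with margin
    central_depth_px: float = 20.0
    peripheral_nuclei: bool = True
    n_objects: int = 7
    object_radius: int = 3
    object_intensity: int = 220
    background_intensity: int = 10
    noise_sd: float = 0.0
    streak_amplitude: float = 0.0
    stain: str = "type"  # what the green channel carries: "type" or "object"
    lloyd_iterations: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_positive", "fraction_cnf"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("boundary_intensity", "interior_intensity", "positive_intensity",
                     "negative_intensity", "nucleus_intensity", "object_intensity",
                     "background_intensity"):
            if not 0 <= getattr(self, name) <= 255:
                raise ValueError(f"{name} must be in [0, 255]")
        if self.stain not in ("type", "object"):
            raise ValueError("stain must be 'type' or 'object'")
        if self.n_fibers < 1 or self.size < 8:
            raise ValueError("need n_fibers >= 1 and size >= 8")
        if self.size * self.size / self.n_fibers < 100:
            raise ValueError(
                f"infeasible packing: {self.n_fibers} fibers in a {self.size}px square"
            )


@dataclass
class GroundTruth:
    """Truth tables matching a generated section."""

    label_map: np.ndarray
    fibers: pd.DataFrame  # columns: label, area_px, interior, positive, cnf
    objects: pd.DataFrame  # columns: object, x, y

    @property
    def n_interior(self) -> int:
        return int(self.fibers["interior"].sum())

    @property
    def percent_positive(self) -> float:
        inter = self.fibers[self.fibers["interior"]]
        return 100.0 * inter["positive"].sum() / len(inter)

    @property
    def percent_cnf(self) -> float:
        inter = self.fibers[self.fibers["interior"]]
        return 100.0 * inter["cnf"].sum() / len(inter)


def _lloyd_labels(spec: SectionSpec, rng: np.random.Generator):
    """Relax seed points and return (label_map, d1, d2, d3) per pixel."""
    s = spec.size
    pts = rng.uniform(0, s, size=(spec.n_fibers, 2))
    rr, cc = np.mgrid[0:s, 0:s]
    grid = np.stack([rr.ravel() + 0.5, cc.ravel() + 0.5], axis=1)
    for _ in range(spec.lloyd_iterations):
        _, idx = cKDTree(pts).query(grid, k=1)
        for lab in range(spec.n_fibers):
            sel = idx == lab
            if not sel.any():
                raise ValueError("infeasible packing: a fiber received no pixels")
            pts[lab] = grid[sel].mean(axis=0)
    dists, idx = cKDTree(pts).query(grid, k=3)
    label_map = (idx[:, 0] + 1).reshape(s, s).astype(np.int64)
    d = dists.reshape(s, s, 3)
    return label_map, d[:, :, 0], d[:, :, 1], d[:, :, 2]


def _disk(center_rc, radius, shape):
    r0, c0 = center_rc
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2


def generate_section(spec: SectionSpec) -> tuple[SectionImage, GroundTruth]:
    """Generate one synthetic section and its ground truth.

    The red channel always carries the fiber outlines and the blue channel
    the nuclei; the green channel carries the type stain or the object
    stain depending on ``spec.stain`` (emulating serial sections).  The
    geometry, truth tables, and random draws are identical for both stain
    variants at the same seed.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.size
    label_map, d1, d2, d3 = _lloyd_labels(spec, rng)
    band = (d2 - d1) <= spec.boundary_width

    # outline channel: band brightest on the bisector crest and sloping toward
    # the interiors, so the watershed ridge lands deterministically mid-band
    red = np.full((s, s), spec.interior_intensity, dtype=np.float64)
    crest_drop = min(60.0, (spec.boundary_intensity - spec.interior_intensity) / 2.0)
    profile = spec.boundary_intensity - (d2 - d1) * (crest_drop / max(spec.boundary_width, 1e-9))
    red[band] = profile[band]

    labels = np.arange(1, spec.n_fibers + 1)
    edge_labels = np.unique(
        np.concatenate([label_map[0], label_map[-1], label_map[:, 0], label_map[:, -1]])
    )
    interior = ~np.isin(labels, edge_labels)
    interior_labels = labels[interior]
    if interior_labels.size == 0:
        raise ValueError("no interior fibers; increase size or reduce n_fibers")

    # depth of each pixel: distance to the nearest band pixel or image edge
    depth = ndi.distance_transform_edt(np.pad(~band, 1, constant_values=False))[1:-1, 1:-1]

    # fiber type assignment (interior fibers only; edge fibers stay negative)
    n_pos = int(round(spec.fraction_positive * interior_labels.size))
    positive_labels = rng.choice(interior_labels, size=n_pos, replace=False)
    positive = np.isin(labels, positive_labels)

    # CNF assignment among interior fibers deep enough to hold a central nucleus
    max_depth = ndi.maximum(depth, labels=label_map, index=labels)
    n_cnf = int(round(spec.fraction_cnf * interior_labels.size))
    eligible = interior_labels[
        max_depth[interior_labels - 1] > spec.central_depth_px + spec.nucleus_radius
    ]
    if eligible.size < n_cnf:
        raise ValueError("infeasible packing: too few fibers can hold a central nucleus")
    cnf_labels = rng.choice(eligible, size=n_cnf, replace=False)
    cnf = np.isin(labels, cnf_labels)

    # nuclei channel
    blue = np.full((s, s), spec.background_intensity, dtype=np.float64)
    for lab in labels:
        cell = label_map == lab
        if cnf[lab - 1]:
            flat = np.argmax(np.where(cell, depth, -1.0))
            center = np.unravel_index(flat, (s, s))
            blue[_disk(center, spec.nucleus_radius, (s, s))] = spec.nucleus_intensity
        elif spec.peripheral_nuclei:
            on_band = cell & band
            rr, cc = np.nonzero(on_band)
            if rr.size:
                k = rr.size // 2
                blue[_disk((rr[k], cc[k]), spec.nucleus_radius, (s, s))] = (
                    spec.nucleus_intensity
                )
    if spec.streak_amplitude > 0:
        stripe_rows = rng.choice(s, size=max(1, s // 40), replace=False)
        for r0 in stripe_rows:
            blue[r0] = np.minimum(255.0, blue[r0] + spec.streak_amplitude)

    # objects at 3-way junctions, kept apart from each other and the border
    margin = 3 * spec.object_radius
    junction = (d3 - d1) <= max(2.0, spec.boundary_width)
    junction[:margin], junction[-margin:] = False, False
    junction[:, :margin], junction[:, -margin:] = False, False
    jr, jc = np.nonzero(junction)
    order = rng.permutation(jr.size)
    min_sep = max(6 * spec.object_radius + 4, 12)
    centers: list[tuple[int, int]] = []
    for i in order:
        p = (int(jr[i]), int(jc[i]))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep**2 for q in centers):
            centers.append(p)
            if len(centers) == spec.n_objects:
                break
    if len(centers) < spec.n_objects:
        raise ValueError("infeasible packing: could not place the requested objects")

    # green channel: type stain or object stain
    green = np.full((s, s), spec.background_intensity, dtype=np.float64)
    if spec.stain == "type":
        fill = ~band
        pos_map = np.isin(label_map, labels[positive])
        green[fill & pos_map] = spec.positive_intensity
        green[fill & ~pos_map] = spec.negative_intensity
    else:
        for p in centers:
            green[_disk(p, spec.object_radius, (s, s))] = spec.object_intensity

    channels = np.stack([red, green, blue], axis=2)
    if spec.noise_sd > 0:
        # correlated staining noise: smoothed white noise rescaled to
        # noise_sd, hard-clipped to +/-2.2 so its total relief stays below
        # the default suppression depth of 5 -- ground truth must remain
        # valid, so noise may never fake a fiber boundary (at noise_sd > 2
        # the clip lowers the effective SD; see docs)
        raw = rng.normal(0.0, 1.0, size=channels.shape)
        noise = ndi.gaussian_filter(raw, sigma=(3.0, 3.0, 0.0))
        noise *= spec.noise_sd / noise.std()
        channels = channels + np.clip(noise, -2.2, 2.2)
    pixels = np.clip(np.round(channels), 0, 255).astype(np.uint8)

    # truth CSA uses the mask convention that the 1-px ridge line between
    # touching fibers belongs to neither: each cell gives up half of its
    # boundary-transition pixels
    cell_px = ndi.sum_labels(np.ones_like(label_map, float), labels=label_map, index=labels)
    trans = ndi.maximum_filter(label_map, size=3) != ndi.minimum_filter(label_map, size=3)
    trans_px = ndi.sum_labels(trans.astype(float), labels=label_map, index=labels)
    area_px = cell_px - 0.5 * trans_px
    fibers = pd.DataFrame(
        dict(label=labels, area_px=area_px, interior=interior,
             positive=positive, cnf=cnf)
    )
    objects = pd.DataFrame(
        dict(
            object=np.arange(1, len(centers) + 1),
            x=[c + 0.0 for _, c in centers],
            y=[r + 0.0 for r, _ in centers],
        )
    )
    gt = GroundTruth(label_map=label_map, fibers=fibers, objects=objects)
    return SectionImage(pixels=pixels, pixel_size=spec.pixel_size), gt


def write_ground_truth(gt: GroundTruth, out_dir, prefix: str = "truth") -> dict:
    """Write the truth label map (TIFF) and tables (CSV); returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "label_map": os.path.join(out_dir, f"{prefix}_labels.tif"),
        "fibers": os.path.join(out_dir, f"{prefix}_fibers.csv"),
        "objects": os.path.join(out_dir, f"{prefix}_objects.csv"),
    }
    write_mask(gt.label_map, paths["label_map"])
    gt.fibers.to_csv(paths["fibers"], index=False)
    gt.objects.to_csv(paths["objects"], index=False)
    return paths


def read_ground_truth(out_dir, prefix: str = "truth") -> GroundTruth:
    label_map = read_mask(os.path.join(out_dir, f"{prefix}_labels.tif"))
    fibers = pd.read_csv(os.path.join(out_dir, f"{prefix}_fibers.csv"))
    for col in ("interior", "positive", "cnf"):
        fibers[col] = fibers[col].astype(bool)
    objects = pd.read_csv(os.path.join(out_dir, f"{prefix}_objects.csv"))
    return GroundTruth(label_map=label_map, fibers=fibers, objects=objects)
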