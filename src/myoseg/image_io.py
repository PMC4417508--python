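"""Image, mask, parameter, and table I/O.

All raster coordinates are 0-based ``(row, col)``; centroids are reported as
``x = col``, ``y = row``.  Channel indices are 1-based (1=red, 2=green,
3=blue) in configs and on the CLI, matching common usage, and converted to
0-based only at the point of pixel access.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ChannelRole",
    "SectionImage",
    "AnalysisParams",
    "load_image",
    "write_mask",
    "read_mask",
    "load_params",
    "load_params_xlsx",
    "write_params",
    "write_table",
]


@dataclass(frozen=True)
class ChannelRole:
    """1-based channel assignment (1=red, 2=green, 3=blue)."""

    outline_channel: int = 1
    nuclei_channel: int = 3
    type_channel: int = 2
    object_channel: int = 2

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v not in (1, 2, 3):
                raise ValueError(f"{f.name} must be 1, 2, or 3 (got {v!r})")
        if self.outline_channel == self.nuclei_channel:
            raise ValueError("outline_channel and nuclei_channel must differ")


@dataclass
class SectionImage:
    """An RGB section raster with a physical pixel size in μm/pixel."""

    pixels: np.ndarray  # (H, W, 3) uint8
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8 (0-255)")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def channel(self, index: int) -> np.ndarray:
        """Return one channel as a 2-D uint8 array (``index`` is 1-based)."""
        if index not in (1, 2, 3):
            raise ValueError(f"channel index must be 1, 2, or 3 (got {index!r})")
        return self.pixels[:, :, index - 1]


#: Built-in defaults for every analysis parameter.
_DEFAULTS = dict(
    pixel_size=0.645,
    outline_channel=1,
    nuclei_channel=3,
    type_channel=2,
    object_channel=2,
    segmentation_smoothing=5.0,
    nuclear_smoothing=5.0,
    object_smoothing=10.0,
    min_fiber_area=100.0,
    max_fiber_area=5000.0,
    max_eccentricity=0.95,
    min_convexity=0.8,
    nuclear_border_distance=10.0,
    min_nuclear_size=5.0,
    output_folder="output",
)


@dataclass
class AnalysisParams:
    """User parameters for every pipeline stage.

    Lengths are μm, areas μm²; smoothing factors are depths on the 8-bit
    intensity scale (0-255).
    """

    pixel_size: float = _DEFAULTS["pixel_size"]
    outline_channel: int = _DEFAULTS["outline_channel"]
    nuclei_channel: int = _DEFAULTS["nuclei_channel"]
    type_channel: int = _DEFAULTS["type_channel"]
    object_channel: int = _DEFAULTS["object_channel"]
    segmentation_smoothing: float = _DEFAULTS["segmentation_smoothing"]
    nuclear_smoothing: float = _DEFAULTS["nuclear_smoothing"]
    object_smoothing: float = _DEFAULTS["object_smoothing"]
    min_fiber_area: float = _DEFAULTS["min_fiber_area"]
    max_fiber_area: float = _DEFAULTS["max_fiber_area"]
    max_eccentricity: float = _DEFAULTS["max_eccentricity"]
    min_convexity: float = _DEFAULTS["min_convexity"]
    nuclear_border_distance: float = _DEFAULTS["nuclear_border_distance"]
    min_nuclear_size: float = _DEFAULTS["min_nuclear_size"]
    output_folder: str = _DEFAULTS["output_folder"]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not self.min_fiber_area < self.max_fiber_area:
            raise ValueError(
                "min_fiber_area must be < max_fiber_area "
                f"({self.min_fiber_area} >= {self.max_fiber_area})"
            )
        if not 0.0 <= self.max_eccentricity <= 1.0:
            raise ValueError("max_eccentricity must be in [0, 1]")
        if not 0.0 <= self.min_convexity <= 1.0:
            raise ValueError("min_convexity must be in [0, 1]")
        for name in ("segmentation_smoothing", "nuclear_smoothing", "object_smoothing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nuclear_border_distance < 0:
            raise ValueError("nuclear_border_distance must be >= 0")
        if self.min_nuclear_size < 0:
            raise ValueError("min_nuclear_size must be >= 0")
        self.roles()  # channel-index validation

    def roles(self) -> ChannelRole:
        return ChannelRole(
            outline_channel=self.outline_channel,
            nuclei_channel=self.nuclei_channel,
            type_channel=self.type_channel,
            object_channel=self.object_channel,
        )

    def replace(self, **kwargs) -> "AnalysisParams":
        return replace(self, **kwargs)


def load_image(path, pixel_size: float, roles: ChannelRole | None = None) -> SectionImage:
    """Read an RGB image file (.bmp/.jpg/.png/.tif) into a :class:`SectionImage`.

    RGBA alpha is dropped; higher bit depths are linearly rescaled so that
    the dtype maximum maps to 255.  Grayscale input is rejected because the
    channel roles would be undefined.
    """
    if not os.path.exists(path):
        raise IOError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not read image file {path}: {exc}") from exc
    if arr.ndim == 2:
        raise ValueError(
            f"{path} is single-channel; RGB input is required so channel roles are defined"
        )
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"{path}: unsupported image shape {arr.shape}")
    arr = arr[:, :, :3]
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer):
            maxval = np.iinfo(arr.dtype).max
        else:
            maxval = float(arr.max()) or 1.0
        arr = np.round(arr.astype(np.float64) * (255.0 / maxval)).astype(np.uint8)
    return SectionImage(pixels=arr, pixel_size=pixel_size)


def write_mask(mask: np.ndarray, path) -> None:
    """Persist a label mask as a single-channel TIFF (16-bit, or 32-bit if needed)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if mask.min() < 0:
        raise ValueError("mask labels must be non-negative")
    dtype = np.uint16 if mask.max() <= np.iinfo(np.uint16).max else np.uint32
    tifffile.imwrite(str(path), mask.astype(dtype))


def read_mask(path) -> np.ndarray:
    """Read a label mask written by :func:`write_mask`."""
    if not os.path.exists(path):
        raise IOError(f"mask file not found: {path}")
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-channel label mask")
    return arr.astype(np.int64)


_INT_FIELDS = {"outline_channel", "nuclei_channel", "type_channel", "object_channel"}


def _coerce(name: str, value: str):
    if name == "output_folder":
        return value
    if name in _INT_FIELDS:
        as_float = float(value)
        if as_float != int(as_float):
            raise ValueError(f"{name} must be an integer (got {value})")
        return int(as_float)
    return float(value)


def load_params(path=None) -> AnalysisParams:
    """Load analysis parameters from a ``key = value`` text file.

    With ``path=None`` (or a missing optional file) the built-in defaults
    are returned.  Unknown keys and out-of-range values raise ``ValueError``
    naming the offending field.
    """
    if path is None:
        return AnalysisParams()
    if not os.path.exists(path):
        raise IOError(f"parameter file not found: {path}")
    values = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in _DEFAULTS:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            try:
                values[key] = _coerce(key, val)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad value for {key!r}: {val!r}") from exc
    return AnalysisParams(**values)


def write_params(params: AnalysisParams, path) -> None:
    with open(path, "w") as fh:
        for f in fields(params):
            fh.write(f"{f.name} = {getattr(params, f.name)}\n")


# Row labels of the conventional two-column defaults spreadsheet, mapped to
# parameter names.  Matching is case-insensitive on a normalized prefix.
_XLSX_ROWS = {
    "pixel size": "pixel_size",
    "fiber outline channel": "outline_channel",
    "nuclei channel": "nuclei_channel",
    "fiber type channel": "type_channel",
    "object channel": "object_channel",
    "segmentation smoothing factor": "segmentation_smoothing",
    "nuclear smoothing factor": "nuclear_smoothing",
    "object smoothing factor": "object_smoothing",
    "minimum fiber area": "min_fiber_area",
    "maximum fiber area": "max_fiber_area",
    "maximum eccentricity": "max_eccentricity",
    "minimum convexity": "min_convexity",
    "nuclear distance from boarder": "nuclear_border_distance",
    "nuclear distance from border": "nuclear_border_distance",
    "minimum nuclear size": "min_nuclear_size",
    "output folder": "output_folder",
}


def load_params_xlsx(path) -> AnalysisParams:
    """Convenience reader for a two-column (name, value) defaults spreadsheet."""
    df = pd.read_excel(path, header=None)
    values = {}
    for _, row in df.iterrows():
        name = str(row.iloc[0]).strip().lower()
        for prefix, field_name in _XLSX_ROWS.items():
            if name.startswith(prefix):
                raw = row.iloc[1]
                values[field_name] = (
                    str(raw) if field_name == "output_folder" else _coerce(field_name, str(raw))
                )
                break
    return AnalysisParams(**values)


def write_table(df: pd.DataFrame, path, xlsx: bool = False) -> None:
    """Write a table as CSV, and additionally as .xlsx when requested."""
    df.to_csv(path, index=False)
    if xlsx:
        df.to_excel(os.path.splitext(str(path))[0] + ".xlsx", index=False)
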