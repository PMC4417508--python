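"""Fiber typing from mean stain intensity with an Otsu-initialized threshold.

Each fiber's mean intensity in the type channel is computed over its mask
region; a threshold (automatic by default) splits fibers into positive (1)
and negative (0).  The call rule is strictly greater-than, so ties go
negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = ["mean_fiber_intensity", "otsu_threshold", "classify_fiber_types", "TypingResult"]


def mean_fiber_intensity(mask: np.ndarray, channel: np.ndarray) -> pd.Series:
    """Arithmetic mean of channel values over each label's pixels."""
    mask = np.asarray(mask)
    channel = np.asarray(channel)
    if mask.shape != channel.shape:
        raise ValueError(f"mask shape {mask.shape} != channel shape {channel.shape}")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return pd.Series(dtype=float)
    means = ndi.mean(channel.astype(np.float64), labels=mask, index=labels)
    return pd.Series(means, index=labels.astype(int))


def otsu_threshold(values) -> float:
    """Otsu threshold of a value set on the 8-bit scale.

    Exhaustively minimizes the total within-class sum of squared deviations
    over the 256 integer candidate thresholds 0..255, where a value v is in
    the low class iff ``v <= t``.  Returns the smallest minimizing t.
    Raises if all values are identical (no split exists).
    """
    v = np.sort(np.asarray(values, dtype=np.float64).ravel())
    n = v.size
    if n < 2 or v[0] == v[-1]:
        raise ValueError("Otsu threshold undefined: need >= 2 distinct values")
    cum = np.concatenate([[0.0], np.cumsum(v)])
    cum2 = np.concatenate([[0.0], np.cumsum(v * v)])
    cand = np.arange(256, dtype=np.float64)
    k = np.searchsorted(v, cand, side="right")
    s0, ss0 = cum[k], cum2[k]
    s1, ss1 = cum[-1] - s0, cum2[-1] - ss0
    with np.errstate(divide="ignore", invalid="ignore"):
        intra = np.where(k > 0, ss0 - s0**2 / np.maximum(k, 1), 0.0) + np.where(
            k < n, ss1 - s1**2 / np.maximum(n - k, 1), 0.0
        )
    intra[(k == 0) | (k == n)] = np.inf  # a threshold must actually split
    if not np.isfinite(intra).any():
        raise ValueError("Otsu threshold undefined: values admit no 8-bit split")
    return float(cand[int(np.argmin(intra))])


@dataclass
class TypingResult:
    """Per-fiber typing calls plus the threshold and group summaries."""

    table: pd.DataFrame  # columns: label, mean_intensity, area_um2, call
    threshold: float
    auto_threshold: bool
    summary: pd.DataFrame  # rows all/positive/negative: n, mean_area_um2, mean_intensity

    @property
    def percent_positive(self) -> float:
        return 100.0 * self.table["call"].sum() / len(self.table)


def _group_summary(table: pd.DataFrame, flag_col: str) -> pd.DataFrame:
    groups = {
        "all": table,
        "positive": table[table[flag_col] == 1],
        "negative": table[table[flag_col] == 0],
    }
    rows = []
    for name, sub in groups.items():
        rows.append(
            dict(
                group=name,
                n=len(sub),
                mean_area_um2=sub["area_um2"].mean() if len(sub) else np.nan,
                mean_intensity=sub["mean_intensity"].mean() if len(sub) else np.nan,
            )
        )
    return pd.DataFrame(rows)


def classify_fiber_types(
    mask: np.ndarray,
    channel: np.ndarray,
    pixel_size: float,
    threshold: float | None = None,
) -> TypingResult:
    """Call each fiber positive/negative for the stain in ``channel``.

    ``threshold=None`` selects Otsu's threshold on the distribution of
    per-fiber mean intensities; an explicit value in [0, 255] overrides it.
    """
    means = mean_fiber_intensity(mask, channel)
    if means.empty:
        raise ValueError("mask contains no fibers to type")
    auto = threshold is None
    if auto:
        thr = otsu_threshold(means.to_numpy())
    else:
        thr = float(threshold)
        if not 0.0 <= thr <= 255.0:
            raise ValueError("threshold must be in [0, 255]")
    mask = np.asarray(mask)
    areas = ndi.sum_labels(np.ones_like(mask, dtype=np.float64), labels=mask,
                           index=means.index.to_numpy())
    table = pd.DataFrame(
        dict(
            label=means.index.to_numpy(),
            mean_intensity=means.to_numpy(),
            area_um2=areas * pixel_size**2,
            call=(means.to_numpy() > thr).astype(int),
        )
    )
    return TypingResult(
        table=table,
        threshold=thr,
        auto_threshold=auto,
        summary=_group_summary(table, "call"),
    )


def plot_typing(result: TypingResult, out_path) -> None:
    """Intensity histogram with threshold line, and CSA histograms (positive over all)."""
    t = result.table
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].hist(t["mean_intensity"], bins=32, color="tab:gray")
    axes[0].axvline(result.threshold, color="tab:red", label=f"threshold {result.threshold:g}")
    axes[0].set_xlabel("mean fiber intensity")
    axes[0].set_ylabel("fibers")
    axes[0].legend()
    axes[1].hist(t["area_um2"], bins=24, color="tab:blue", label="all fibers")
    axes[1].hist(t.loc[t["call"] == 1, "area_um2"], bins=24, color="tab:red",
                 label="positive fibers")
    axes[1].set_xlabel("fiber CSA (μm²)")
    axes[1].set_ylabel("fibers")
    axes[1].legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
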