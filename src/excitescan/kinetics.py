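"""Pixel filtering and time-trace extraction from detection-map series.

Whole-field or single-cell signal traces computed by averaging every
pixel in a region dilute genuine kinetics with background or weakly
labeled pixels. A pixel filter keeps only pixels whose detector output
passes a threshold — derived from the sensitivity analysis (MDL), from
Otsu's method, or set manually — before averaging, which can reveal
transients and oscillations that plain region averages wash out.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DegenerateInputError, DetectionMap

__all__ = [
    "PixelFilter",
    "TimeTrace",
    "otsu_threshold",
    "apply_filter",
    "extract_trace",
]


@dataclass(frozen=True)
class PixelFilter:
    """A detection threshold plus how it was obtained.

    ``direction`` follows the detection map convention: ``greater`` keeps
    pixels strictly above the threshold (abundance maps), ``less`` keeps
    pixels strictly below it (angle maps). ``method='none'`` disables
    filtering entirely (threshold forced to 0, all pixels pass).
    """

    threshold: float = 0.0
    method: str = "manual"
    direction: str = "greater"

    def __post_init__(self) -> None:
        if self.method not in ("none", "tsa", "otsu", "manual"):
            raise ValueError(f"unknown filter method {self.method!r}")
        if self.direction not in ("greater", "less"):
            raise ValueError("direction must be 'greater' or 'less'")
        if self.method == "none" and self.threshold != 0:
            raise ValueError("method 'none' requires threshold 0")


@dataclass
class TimeTrace:
    """Mean detector output over a region's passing pixels, per frame.

    Frames where no pixel passes the filter carry NaN, not zero — a zero
    would fabricate a signal dip.
    """

    times_s: np.ndarray
    values: np.ndarray
    n_pixels: np.ndarray
    mask_name: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times_s, "mean": self.values,
                             "n_pixels": self.n_pixels})


def otsu_threshold(dmap, n_bins: int = 256) -> float:
    """Otsu's threshold: the histogram bin edge maximizing between-class
    variance.

    The histogram has ``n_bins`` equal bins over [min, max]; candidate
    thresholds are the interior bin edges, ties broken toward the lowest
    threshold. A constant image has no meaningful split and raises
    :class:`DegenerateInputError`.
    """
    values = dmap.values if isinstance(dmap, DetectionMap) else dmap
    v = np.asarray(values, dtype=float).ravel()
    lo, hi = v.min(), v.max()
    if lo == hi:
        raise DegenerateInputError("constant image has no Otsu threshold")
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts / counts.sum()
    # cumulative class probabilities / means for splits after bin k
    omega0 = np.cumsum(w)[:-1]
    omega1 = 1.0 - omega0
    mu_cum = np.cumsum(w * centers)
    mu_total = mu_cum[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = mu_cum[:-1] / omega0
        mu1 = (mu_total - mu_cum[:-1]) / omega1
        sigma_b = omega0 * omega1 * (mu0 - mu1) ** 2
    sigma_b = np.where(np.isfinite(sigma_b), sigma_b, -np.inf)
    # splits across empty bins leave the partition unchanged; only the
    # lowest edge of each such plateau is a candidate, which realizes the
    # tie-break toward the lowest threshold
    candidate = np.concatenate([[True], counts[1:n_bins - 1] > 0])
    sigma_b = np.where(candidate, sigma_b, -np.inf)
    k = int(np.argmax(sigma_b))  # argmax takes the first maximum: lowest tie
    return float(edges[k + 1])


def apply_filter(dmap, pixel_filter: PixelFilter) -> np.ndarray:
    """Boolean pass mask for one detection map under a filter."""
    values = dmap.values if isinstance(dmap, DetectionMap) else np.asarray(dmap)
    if pixel_filter.method == "none":
        return np.ones(values.shape, dtype=bool)
    if pixel_filter.direction == "less":
        return values < pixel_filter.threshold
    return values > pixel_filter.threshold


def extract_trace(maps_over_time: Sequence, region_mask: np.ndarray,
                  pixel_filter: PixelFilter | None = None,
                  filter_mode: str = "per_frame",
                  reference_frame: int = 0,
                  times_s=None,
                  mask_name: str = "") -> TimeTrace:
    """Mean filtered detector output inside a region, frame by frame.

    ``filter_mode='per_frame'`` recomputes the pass mask on every frame;
    ``'reference_frame'`` freezes the mask from the designated frame and
    applies it throughout (useful when pixel identity should be stable
    across the series).
    """
    if pixel_filter is None:
        pixel_filter = PixelFilter(method="none")
    if filter_mode not in ("per_frame", "reference_frame"):
        raise ValueError(f"unknown filter_mode {filter_mode!r}")
    region = np.asarray(region_mask, dtype=bool)
    if not region.any():
        raise ValueError("empty region mask")

    arrays = [m.values if isinstance(m, DetectionMap) else np.asarray(m)
              for m in maps_over_time]
    if not arrays:
        raise ValueError("no frames supplied")
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError("all frames must share one shape")
    if region.shape != arrays[0].shape:
        raise ValueError("region mask shape must match frames")

    if times_s is None:
        times = np.arange(len(arrays), dtype=float)
    else:
        times = np.asarray(times_s, dtype=float)
        if times.size != len(arrays):
            raise ValueError("times_s length must match frame count")

    frozen = None
    if filter_mode == "reference_frame":
        frozen = apply_filter(arrays[reference_frame], pixel_filter)

    means = np.empty(len(arrays))
    counts = np.empty(len(arrays), dtype=int)
    for i, frame in enumerate(arrays):
        passing = frozen if frozen is not None else apply_filter(frame,
                                                                 pixel_filter)
        sel = region & passing
        counts[i] = int(sel.sum())
        means[i] = frame[sel].mean() if counts[i] else np.nan
    return TimeTrace(times_s=times, values=means, n_pixels=counts,
                     mask_name=mask_name)
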