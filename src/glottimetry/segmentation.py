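"""Color-based glottal gap segmentation.

The glottal gap appears dark against bright-pink mucosa, so segmentation
thresholds a darkness channel (luminance by default), keeps the largest
connected component after morphological cleaning, and applies validity rules
(minimum area, not truncated by the image border) in place of the manual
confirmation step a human rater would perform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk

__all__ = ["SegmentationConfig", "GlottalMask", "segment_frame", "clean_mask",
           "validate_mask", "darkness_channel", "dice"]


class FrameFormatError(ValueError):
    """Raised for frames that are not non-empty RGB images."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the gap detector.

    channel
        Darkness channel: ``luminance`` (0.299R + 0.587G + 0.114B),
        ``value`` (the V of HSV, i.e. max of RGB) or ``red_minus_green``
        (exploits the pink tissue / dark gap color contrast).
    threshold_mode
        ``auto`` picks an Otsu (between-class variance) threshold per frame;
        ``fixed`` uses ``fixed_threshold``.
    """

    channel: Literal["luminance", "value", "red_minus_green"] = "luminance"
    threshold_mode: Literal["auto", "fixed"] = "auto"
    fixed_threshold: float = 100.0
    open_radius_px: int = 1
    min_area_frac: float = 0.001
    fill_holes: bool = True
    border_frac_limit: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.fixed_threshold <= 255:
            raise ValueError("fixed_threshold must lie in [0, 255]")
        if not 0 <= self.min_area_frac <= 0.5:
            raise ValueError("min_area_frac must lie in [0, 0.5]")
        if self.open_radius_px < 0:
            raise ValueError("open_radius_px must be >= 0")


@dataclass
class GlottalMask:
    """A per-frame segmentation result with QC verdict."""

    mask: np.ndarray  # 2-D bool
    frame_index: int = 0
    valid: bool = True
    reason: str = ""
    threshold_used: float = np.nan


def darkness_channel(image: np.ndarray, channel: str) -> np.ndarray:
    """Scalar channel on which the gap is darker than the mucosa."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
        raise FrameFormatError("expected a non-empty RGB image (rows, cols, 3)")
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    if channel == "luminance":
        return 0.299 * r + 0.587 * g + 0.114 * b
    if channel == "value":
        return img.max(axis=2)
    if channel == "red_minus_green":
        return r - g
    raise ValueError(f"unknown channel {channel!r}")


def candidate_mask(image: np.ndarray, config: SegmentationConfig) -> tuple[np.ndarray, float]:
    """Raw below-threshold candidate pixels and the threshold used.

    Automatic mode maximizes the Otsu between-class variance, then moves the
    cut to the midpoint of the two class means: the histogram-binned Otsu
    value can fall inside a narrow dark mode (it is a bin center), which
    would split the gap itself on near-noiseless frames.
    """
    chan = darkness_channel(image, config.channel)
    if config.threshold_mode == "fixed":
        thr = float(config.fixed_threshold)
    else:
        if chan.min() == chan.max():
            return np.zeros(chan.shape, bool), float(chan.min())
        thr = float(threshold_otsu(chan))
        lo, hi = chan[chan <= thr], chan[chan > thr]
        if lo.size and hi.size:
            thr = 0.5 * (float(lo.mean()) + float(hi.mean()))
    return chan < thr, thr


def clean_mask(
    raw: np.ndarray | GlottalMask, config: SegmentationConfig | None = None
) -> GlottalMask:
    """Morphological opening, largest 8-connected component, hole filling."""
    config = config or SegmentationConfig()
    if isinstance(raw, GlottalMask):
        frame_index, thr = raw.frame_index, raw.threshold_used
        arr = raw.mask.astype(bool)
    else:
        frame_index, thr = 0, np.nan
        arr = np.asarray(raw).astype(bool)
    if config.open_radius_px > 0 and arr.any():
        arr = ndimage.binary_opening(arr, structure=disk(config.open_radius_px))
    if arr.any():
        labels = label(arr, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        arr = labels == counts.argmax()
        if config.fill_holes:
            arr = ndimage.binary_fill_holes(arr)
    return GlottalMask(arr, frame_index=frame_index, threshold_used=thr)


def validate_mask(
    mask: GlottalMask | np.ndarray, config: SegmentationConfig | None = None
) -> tuple[bool, str]:
    """QC verdict for a cleaned mask.

    Invalid when empty ("no gap component"), smaller than
    ``min_area_frac`` of the frame ("below-min-area"), or occupying at least
    ``border_frac_limit`` of the image border pixels — the gap is then
    presumed truncated off-frame ("border-truncated").
    """
    config = config or SegmentationConfig()
    arr = mask.mask if isinstance(mask, GlottalMask) else np.asarray(mask).astype(bool)
    area = int(arr.sum())
    if area == 0:
        return False, "no gap component"
    if area < config.min_area_frac * arr.size:
        return False, "below-min-area"
    border = np.concatenate([arr[0, :], arr[-1, :], arr[1:-1, 0], arr[1:-1, -1]])
    if border.mean() >= config.border_frac_limit:
        return False, "border-truncated"
    return True, ""


def segment_frame(
    image: np.ndarray,
    config: SegmentationConfig | None = None,
    frame_index: int = 0,
) -> GlottalMask:
    """Segment the glottal gap in one RGB frame.

    Thresholds the darkness channel, cleans the candidate mask and attaches
    the QC verdict.  Never raises on scene content — an unusable frame comes
    back flagged invalid with a reason string.
    """
    config = config or SegmentationConfig()
    cand, thr = candidate_mask(image, config)
    result = clean_mask(cand, config)
    result.frame_index = frame_index
    result.threshold_used = thr
    result.valid, result.reason = validate_mask(result, config)
    return result


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|X∩Y| / (|X|+|Y|) between two binary masks."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
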