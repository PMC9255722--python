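"""Per-frame glottal morphometry: area A, long-axis length L, and A/L.

A is the pixel count of the segmented glottal-gap mask; L is the maximum
Feret (caliper) diameter between mask pixel centers, computed on the convex
hull of the mask boundary; A/L is the normalized "elongatedness" statistic
in pixel lengths — smaller values mean a more elongated (more closed)
glottis.  No spatial calibration is applied: all quantities are in pixels,
so comparisons are valid within a fixed recording geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .segmentation import GlottalMask

__all__ = [
    "FrameMeasurement",
    "area_of_mask",
    "long_axis_length",
    "a_over_l",
    "measure_series",
]


class UndefinedRatioError(ZeroDivisionError):
    """Raised when A/L is requested for a zero-length mask."""


class EmptySeriesError(ValueError):
    """Raised when a measurement series is requested for no frames."""


@dataclass(frozen=True)
class FrameMeasurement:
    """Morphometry of one frame.

    ``a_over_l_px`` carries the paper-standard "pixel length" units of the
    A/L statistic; ``valid`` is False when the mask failed segmentation QC or
    the geometry is degenerate (L = 0), in which case the numeric fields are
    NaN.
    """

    frame_index: int
    time_s: float
    area_px2: float
    length_px: float
    a_over_l_px: float
    valid: bool = True
    reason: str = ""


def _as_bool_mask(mask: GlottalMask | np.ndarray) -> tuple[np.ndarray, bool, str]:
    if isinstance(mask, GlottalMask):
        return mask.mask, mask.valid, mask.reason
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    return arr.astype(bool), True, ""


def area_of_mask(mask: GlottalMask | np.ndarray) -> float:
    """Glottal gap area A: the count of mask pixels, in pixel²."""
    arr, _, _ = _as_bool_mask(mask)
    return float(np.count_nonzero(arr))


def _boundary_coords(arr: np.ndarray) -> np.ndarray:
    """Pixel-center coordinates of the mask's boundary pixels."""
    eroded = ndimage.binary_erosion(arr, border_value=0)
    boundary = arr & ~eroded
    return np.argwhere(boundary).astype(float)


def _max_pairwise_distance(points: np.ndarray) -> float:
    diffs = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diffs**2).sum(-1)).max())


def long_axis_length(mask: GlottalMask | np.ndarray) -> float:
    """Long-axis length L: maximum Feret diameter in pixels.

    Defined as the largest center-to-center Euclidean distance between any
    two mask pixels, evaluated on the convex hull of the boundary pixels.
    Degenerate (collinear) masks fall back to the extent along their span.
    """
    arr, _, _ = _as_bool_mask(mask)
    pts = _boundary_coords(arr)
    if len(pts) < 2:
        raise ValueError("long axis undefined for masks of fewer than 2 pixels")
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except QhullError:
        # collinear points: length is the distance between the extremes
        centered = pts - pts.mean(0)
        direction = centered[np.abs(centered).sum(1).argmax()]
        norm = np.linalg.norm(direction)
        if norm == 0:
            return 0.0
        proj = centered @ (direction / norm)
        return float(proj.max() - proj.min())
    return _max_pairwise_distance(verts)


def a_over_l(area_px2: float, length_px: float) -> float:
    """The normalized motion statistic A/L, in pixel lengths."""
    if length_px <= 0:
        raise UndefinedRatioError("A/L undefined for L <= 0")
    return float(area_px2) / float(length_px)


def measure_series(
    masks: Sequence[GlottalMask | np.ndarray] | Iterable,
    fps: float,
    frame_indices: Sequence[int] | None = None,
) -> list[FrameMeasurement]:
    """Measure an ordered mask sequence into per-frame A, L and A/L.

    Invalid masks are retained in the output, flagged invalid with NaN
    measurements, so the time base stays intact for cycle analysis.
    """
    masks = list(masks)
    if not masks:
        raise EmptySeriesError("no masks to measure")
    if fps <= 0:
        raise ValueError("fps must be > 0")
    out: list[FrameMeasurement] = []
    for i, mask in enumerate(masks):
        idx = int(frame_indices[i]) if frame_indices is not None else i
        t = idx / fps
        arr, valid, reason = _as_bool_mask(mask)
        if not valid:
            out.append(FrameMeasurement(idx, t, np.nan, np.nan, np.nan,
                                        valid=False, reason=reason))
            continue
        a = area_of_mask(arr)
        if a < 2:
            out.append(FrameMeasurement(idx, t, a, np.nan, np.nan,
                                        valid=False, reason="degenerate mask"))
            continue
        length = long_axis_length(arr)
        if length <= 0:
            out.append(FrameMeasurement(idx, t, a, length, np.nan,
                                        valid=False, reason="zero-length axis"))
            continue
        out.append(FrameMeasurement(idx, t, a, length, a_over_l(a, length)))
    return out
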