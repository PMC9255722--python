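"""Breath-cycle analysis of the A/L time series.

The final 30 seconds of a recording (the period of lightest anesthesia) are
windowed out, optionally median-smoothed, and segmented into respiratory
cycles: peaks of A/L (maximal abduction) are found by prominence, and each
cycle spans trough-to-trough around one peak.  Per-cycle extrema are read
from the raw, unsmoothed measurements so that smoothing localizes cycles
without attenuating them.  The cycle with the greatest A/L Max − A/L Min is
the study endpoint: one clear abduction is taken as sufficient evidence of
laryngeal motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .morphometry import FrameMeasurement

__all__ = [
    "AOverLSeries",
    "BreathCycle",
    "CycleConfig",
    "extract_final_window",
    "smooth_series",
    "detect_breath_cycles",
    "select_greatest_cycle",
]


class WindowInsufficiencyError(ValueError):
    """Recording shorter than the requested analysis window."""


class NoCycleError(ValueError):
    """No breath cycle available to select from."""


@dataclass
class AOverLSeries:
    """Ordered per-frame A/L measurements at a fixed frame rate."""

    measurements: list[FrameMeasurement]
    fps: float

    def __post_init__(self) -> None:
        times = [m.time_s for m in self.measurements]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def values(self) -> np.ndarray:
        """A/L per frame, NaN where invalid."""
        return np.array(
            [m.a_over_l_px if m.valid else np.nan for m in self.measurements]
        )

    @property
    def times(self) -> np.ndarray:
        return np.array([m.time_s for m in self.measurements])

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([m.frame_index for m in self.measurements])

    @property
    def n_valid(self) -> int:
        return sum(m.valid for m in self.measurements)

    @property
    def duration_s(self) -> float:
        return len(self.measurements) / self.fps


@dataclass(frozen=True)
class BreathCycle:
    """One respiratory abduction–adduction cycle of the glottis."""

    start_frame: int
    end_frame: int
    max_a_over_l: float
    min_a_over_l: float
    peak_frame: int
    trough_frame: int

    @property
    def difference(self) -> float:
        return self.max_a_over_l - self.min_a_over_l


@dataclass(frozen=True)
class CycleConfig:
    """Cycle-analysis parameters.

    ``min_prominence_frac`` (default 0.10 of the window's A/L range) keeps
    breath modulation while rejecting residual noise peaks — well below the
    ~20% change that direct visual observation can resolve.
    """

    window_s: float = 30.0
    smooth_halfwidth: int = 3
    min_prominence_frac: float = 0.10


def extract_final_window(series: AOverLSeries, window_s: float = 30.0) -> AOverLSeries:
    """Trailing ``window_s`` seconds of the recording."""
    n_keep = round(window_s * series.fps)
    if len(series) < n_keep:
        raise WindowInsufficiencyError(
            f"recording holds {len(series) / series.fps:.1f} s, "
            f"needs >= {window_s} s"
        )
    return AOverLSeries(series.measurements[len(series) - n_keep:], series.fps)


def smooth_series(series: AOverLSeries, halfwidth_frames: int) -> AOverLSeries:
    """Moving-median filter over ``2*halfwidth + 1`` frames.

    Invalid frames are excluded from each window; a frame whose whole window
    is invalid stays invalid.  ``halfwidth_frames = 0`` is the identity.
    """
    if halfwidth_frames < 0:
        raise ValueError("halfwidth_frames must be >= 0")
    if halfwidth_frames == 0:
        return series
    vals = series.values
    n = len(vals)
    out = []
    for i, m in enumerate(series.measurements):
        lo, hi = max(0, i - halfwidth_frames), min(n, i + halfwidth_frames + 1)
        window = vals[lo:hi]
        window = window[~np.isnan(window)]
        if window.size == 0:
            out.append(m)
            continue
        med = float(np.median(window))
        out.append(
            FrameMeasurement(m.frame_index, m.time_s, m.area_px2, m.length_px,
                             med, valid=True, reason=m.reason)
        )
    return AOverLSeries(out, series.fps)


def _interpolate_nan(v: np.ndarray) -> np.ndarray:
    out = v.copy()
    bad = np.isnan(out)
    if bad.all() or not bad.any():
        return out
    idx = np.arange(len(out))
    out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out


def detect_breath_cycles(
    series: AOverLSeries,
    min_prominence_frac: float = 0.10,
    raw: AOverLSeries | None = None,
) -> list[BreathCycle]:
    """Segment the (smoothed) series into trough-to-trough breath cycles.

    Peaks are local maxima whose prominence is at least
    ``min_prominence_frac`` of the window's A/L range; the series endpoints
    close the first and last cycle.  Per-cycle extrema come from ``raw``
    (the unsmoothed series; defaults to ``series``).  Fewer than 5 cycles
    triggers a warning, not an error; a flat series yields no cycles.
    """
    if not 0 < min_prominence_frac <= 1:
        raise ValueError("min_prominence_frac must lie in (0, 1]")
    raw = raw if raw is not None else series
    if len(raw) != len(series):
        raise ValueError("raw series must align with the smoothed series")
    v = series.values
    finite = v[~np.isnan(v)]
    if finite.size == 0:
        warnings.warn("no valid frames in window")
        return []
    vrange = float(finite.max() - finite.min())
    if vrange == 0:
        warnings.warn("no detectable motion")
        return []
    vi = _interpolate_nan(v)
    peaks, _ = find_peaks(vi, prominence=min_prominence_frac * vrange)
    if peaks.size == 0:
        warnings.warn("no detectable motion")
        return []
    # trough between consecutive peaks; series endpoints bound the outer cycles
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(a + int(np.argmin(vi[a:b + 1])))
    bounds.append(len(vi) - 1)

    raw_v = raw.values
    idx = series.frame_indices
    cycles: list[BreathCycle] = []
    for k, peak in enumerate(peaks):
        lo, hi = bounds[k], bounds[k + 1]
        seg = raw_v[lo:hi + 1]
        if np.isnan(seg).all():
            continue
        i_max = lo + int(np.nanargmax(seg))
        i_min = lo + int(np.nanargmin(seg))
        cycles.append(
            BreathCycle(
                start_frame=int(idx[lo]),
                end_frame=int(idx[hi]),
                max_a_over_l=float(raw_v[i_max]),
                min_a_over_l=float(raw_v[i_min]),
                peak_frame=int(idx[i_max]),
                trough_frame=int(idx[i_min]),
            )
        )
    if len(cycles) < 5:
        warnings.warn(
            f"only {len(cycles)} breath cycles detected (expected at least 5)"
        )
    return cycles


def select_greatest_cycle(cycles: list[BreathCycle]) -> BreathCycle:
    """The cycle with the greatest A/L Max − A/L Min; ties go to the earliest."""
    if not cycles:
        raise NoCycleError("no breath cycles to select from")
    best = cycles[0]
    for c in cycles[1:]:
        if c.difference > best.difference:
            best = c
    return best
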