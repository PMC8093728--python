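"""Time-depth-recorder processing: zero-offset correction, dive detection,
dive-phase metrics and per-trip dive summaries.

Depth is recorded at a fixed 1 s or 5 s interval, positive downwards.
Pressure sensors drift slowly, so raw surface readings wander away from
0 m; a rolling low-quantile baseline is subtracted before dives are
detected.  A dive is a maximal run of samples at or below the minimum
dive threshold (5 m by default), which excludes travel/surface activity.

Per dive we report duration, maximum depth, bottom time (time spent at
>= 80% of maximum depth), descent rate (max depth over time to reach the
bottom phase) and vertical distance (2 x max depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class DepthSeries:
    """A raw or corrected depth record for one individual.

    Attributes
    ----------
    individual_id : str
    t : ndarray of float
        POSIX timestamps in seconds, strictly increasing.
    depth : ndarray of float
        Depth in metres, positive downwards.
    sample_interval : float
        Nominal sampling interval in seconds (1 or 5).
    """

    individual_id: str
    t: np.ndarray
    depth: np.ndarray
    sample_interval: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.t.shape != self.depth.shape:
            raise ValueError("timestamps and depths differ in length")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self):
        return self.t.size


@dataclass
class Dive:
    """One detected dive and its phase metrics."""

    individual_id: str
    start: float
    end: float
    duration: float
    max_depth: float
    bottom_time: float
    descent_rate: float
    vertical_distance: float
    is_daylight: Optional[bool] = None
    benthic_index: Optional[float] = None
    is_benthic: Optional[bool] = None
    capture_probability: Optional[float] = None
    # sample slice retained for phase/index recomputation
    sample_t: np.ndarray = field(default=None, repr=False)
    sample_depth: np.ndarray = field(default=None, repr=False)


@dataclass
class TripDiveMetrics:
    """Per-trip dive behaviour summary."""

    n_dives: int
    prop_benthic: float
    prop_daylight: float
    dive_rate: float  # m h^-1, total vertical distance / time at sea
    modal_depth: float  # m, mode of 1 m-binned max depths


def infer_sample_interval(t: np.ndarray) -> float:
    """Median spacing of a timestamp vector, for 1 s vs 5 s auto-detection."""
    t = np.asarray(t, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two samples to infer the interval")
    return float(np.median(np.diff(t)))


def zero_offset_correct(series: DepthSeries, window_s: float = 1800.0,
                        quantile: float = 0.05) -> DepthSeries:
    """Remove slow pressure-sensor drift from a depth series.

    A centred rolling ``quantile`` of the raw depths over ``window_s``
    estimates the surface baseline (the animal surfaces regularly, so the
    low quantile tracks the offset, not the dives).  The baseline is
    subtracted and corrected depths are clipped at >= 0 m.
    """
    if len(series) == 0:
        raise ValueError("empty depth series")
    n_win = max(int(round(window_s / series.sample_interval)), 1)
    if n_win < 3:
        raise ValueError("zero-offset window shorter than 3 samples")
    n_win = min(n_win, len(series))
    s = pd.Series(series.depth)
    baseline = s.rolling(n_win, min_periods=1, center=True).quantile(quantile).to_numpy()
    corrected = np.clip(series.depth - baseline, 0.0, None)
    return replace(series, depth=corrected)


def detect_dives(series: DepthSeries, threshold_m: float = 5.0) -> list[Dive]:
    """Detect dives as maximal runs of depth >= ``threshold_m``.

    The series must already be zero-offset corrected.  Excursions that
    never reach the threshold are discarded.  Dive duration spans the
    submerged run plus one sample interval (the sample itself occupies
    its interval).
    """
    if len(series) == 0:
        return []
    if np.any(np.diff(series.t) <= 0):
        raise ValueError("unsorted timestamps")
    wet = series.depth >= threshold_m
    if not wet.any():
        return []
    edges = np.diff(wet.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)
    if wet[0]:
        starts = np.concatenate(([0], starts))
    if wet[-1]:
        ends = np.concatenate((ends, [wet.size - 1]))
    dives = []
    for i0, i1 in zip(starts, ends):
        t_seg = series.t[i0:i1 + 1]
        d_seg = series.depth[i0:i1 + 1]
        descent_rate, bottom_time, vertical = dive_phases(t_seg, d_seg,
                                                          interval=series.sample_interval)
        dives.append(Dive(
            individual_id=series.individual_id,
            start=float(t_seg[0]),
            end=float(t_seg[-1]),
            duration=float(t_seg[-1] - t_seg[0] + series.sample_interval),
            max_depth=float(d_seg.max()),
            bottom_time=bottom_time,
            descent_rate=descent_rate,
            vertical_distance=vertical,
            sample_t=t_seg,
            sample_depth=d_seg,
        ))
    return dives


def dive_phases(t: np.ndarray, depth: np.ndarray, interval: float,
                bottom_fraction: float = 0.8) -> tuple[float, float, float]:
    """Phase metrics for one dive's samples.

    The bottom phase is every sample at >= ``bottom_fraction`` of the
    maximum depth; bottom time is the span of that phase.  Descent rate is
    maximum depth divided by the time from dive start to the first
    bottom-phase sample.  Vertical distance is 2 x maximum depth (down
    and back up), which is robust to the sampling interval.
    """
    t = np.asarray(t, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if t.size < 1:
        raise ValueError("degenerate dive with no samples")
    dmax = float(depth.max())
    bottom = depth >= bottom_fraction * dmax
    ib = np.flatnonzero(bottom)
    bottom_time = float(t[ib[-1]] - t[ib[0]] + interval)
    t_to_bottom = float(t[ib[0]] - t[0])
    if t_to_bottom <= 0:
        t_to_bottom = interval  # bottom reached within the first sample
    descent_rate = dmax / t_to_bottom
    return descent_rate, bottom_time, 2.0 * dmax


def modal_depth(max_depths: Sequence[float], bin_width: float = 1.0) -> float:
    """Mode of binned maximum dive depths; ties break toward the deeper bin.

    Returns the centre of the winning ``bin_width``-metre bin.
    """
    d = np.asarray(max_depths, dtype=float)
    if d.size == 0:
        raise ValueError("no dives")
    bins = np.floor(d / bin_width).astype(int)
    counts = np.bincount(bins)
    best = counts.max()
    winner = np.flatnonzero(counts == best)[-1]  # deepest bin wins ties
    return (winner + 0.5) * bin_width


def flag_daylight(dives: list[Dive], daylight_window: tuple[float, float] = (7.0, 18.0),
                  utc_offset_hours: float = 0.0) -> None:
    """Set each dive's ``is_daylight`` from its start time in local clock
    hours (daylight defined as a fixed clock window, default 07:00-18:00)."""
    lo, hi = daylight_window
    for d in dives:
        local_h = ((d.start / 3600.0) + utc_offset_hours) % 24.0
        d.is_daylight = bool(lo <= local_h < hi)


def trip_dive_summary(dives: list[Dive], trip_duration_h: float,
                      daylight_window: tuple[float, float] = (7.0, 18.0),
                      utc_offset_hours: float = 0.0) -> TripDiveMetrics:
    """Summarise a trip's dives into the four per-trip dive metrics.

    ``dive_rate`` is total vertical distance travelled (m) divided by the
    total time at sea (h).  Benthic labels must already be set.
    """
    if not dives:
        raise ValueError("a trip must contain at least one dive")
    if trip_duration_h <= 0:
        raise ValueError("non-positive trip duration")
    if any(d.is_benthic is None for d in dives):
        raise ValueError("benthic labels not set")
    flag_daylight(dives, daylight_window, utc_offset_hours)
    n = len(dives)
    prop_benthic = sum(bool(d.is_benthic) for d in dives) / n
    prop_daylight = sum(bool(d.is_daylight) for d in dives) / n
    dive_rate = sum(d.vertical_distance for d in dives) / trip_duration_h
    return TripDiveMetrics(
        n_dives=n,
        prop_benthic=prop_benthic,
        prop_daylight=prop_daylight,
        dive_rate=dive_rate,
        modal_depth=modal_depth([d.max_depth for d in dives]),
    )
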