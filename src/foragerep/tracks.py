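"""GPS track processing for a central-place forager.

Raw FastLoc GPS fixes (nominally every 10 min while at the surface) are
speed-filtered, linearly interpolated to a fine time step, stripped of
positions inside haul-out buffers, and segmented into foraging trips:
continuous periods away from the breeding colony of at least 6 h that
contain at least one dive, with any time spent at haul-out sites
subtracted from the trip duration.

Interpolation and buffering are done in a local azimuthal-equidistant
plane centred on the colony; ranges and bearings are great-circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dives import Dive, DepthSeries, TripDiveMetrics
from .geo import LocalProjection, haversine_m, initial_bearing_deg


@dataclass
class GpsTrack:
    """Timestamped WGS84 fixes for one individual."""

    individual_id: str
    t: np.ndarray      # POSIX seconds, strictly increasing
    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if not (self.t.shape == self.lon.shape == self.lat.shape):
            raise ValueError("t, lon, lat must have identical shapes")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self):
        return self.t.size


@dataclass
class Trip:
    """One foraging trip: its retained fixes, dives and behaviour metrics."""

    trip_id: str
    individual_id: str
    start: float
    end: float
    t: np.ndarray = field(repr=False)
    lon: np.ndarray = field(repr=False)
    lat: np.ndarray = field(repr=False)
    dives: list[Dive] = field(repr=False)
    duration_h: float = 0.0          # at-sea time minus haul-out time
    total_distance_km: float = 0.0   # horizontal path + dive vertical distance
    max_range_km: float = 0.0
    bearing_distal: float = 0.0      # degrees [0, 360)
    dive_metrics: Optional[TripDiveMetrics] = None


def speed_filter(track: GpsTrack, vmax: float = 6.0) -> GpsTrack:
    """Remove fixes implying travel faster than ``vmax`` (m s^-1).

    Forward-sequential (McConnell-style single pass): the first fix is
    always retained; each subsequent fix is kept only if the great-circle
    speed from the previously *retained* fix is <= ``vmax``.
    """
    if len(track) < 2:
        raise ValueError("need at least two fixes to speed-filter")
    keep = [0]
    last = 0
    for i in range(1, len(track)):
        dt = track.t[i] - track.t[last]
        dist = haversine_m(track.lon[last], track.lat[last], track.lon[i], track.lat[i])
        if dist / dt <= vmax:
            keep.append(i)
            last = i
    if len(keep) < 2:
        raise ValueError("speed filter removed (almost) every fix; track corrupt")
    idx = np.array(keep)
    return GpsTrack(track.individual_id, track.t[idx], track.lon[idx], track.lat[idx])


def interpolate_track(track: GpsTrack, proj: LocalProjection, step_s: float = 10.0) -> GpsTrack:
    """Linearly interpolate a speed-filtered track at ``step_s`` intervals.

    Interpolation is linear in the projected plane.  The output time grid
    is the union of the regular grid and the original fix times, so
    original positions are preserved exactly.
    """
    if len(track) < 2:
        raise ValueError("cannot interpolate a single-fix track")
    x, y = proj.forward(track.lon, track.lat)
    grid = np.arange(track.t[0], track.t[-1] + 0.5 * step_s, step_s)
    t_new = np.union1d(grid, track.t)
    xi = np.interp(t_new, track.t, x)
    yi = np.interp(t_new, track.t, y)
    lon, lat = proj.inverse(xi, yi)
    return GpsTrack(track.individual_id, t_new, np.atleast_1d(lon), np.atleast_1d(lat))


def buffer_mask(track: GpsTrack, sites: Sequence[tuple[float, float]],
                buffer_km: float = 1.0) -> np.ndarray:
    """Boolean mask of fixes within ``buffer_km`` of any site (lon, lat)."""
    if not sites:
        raise ValueError("empty site list")
    mask = np.zeros(len(track), dtype=bool)
    for lon_s, lat_s in sites:
        mask |= haversine_m(track.lon, track.lat, lon_s, lat_s) <= buffer_km * 1000.0
    return mask


def dry_periods(track: GpsTrack, depth: Optional[DepthSeries],
                min_dry_s: float = 600.0, wet_depth_m: float = 0.5,
                stationary_m: float = 200.0) -> list[tuple[float, float]]:
    """Haul-out (dry) periods: >= ``min_dry_s`` with no depth activity.

    A period is dry when the depth record shows no sample deeper than
    ``wet_depth_m`` (or no samples at all — the wet/dry sensor only logs
    in water) and the track is essentially stationary over the period.
    """
    if depth is None or len(depth) == 0:
        return []
    wet_t = depth.t[depth.depth > wet_depth_m]
    # candidate dry windows: gaps between consecutive wet samples
    bounds = np.concatenate(([track.t[0]], wet_t, [track.t[-1]]))
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < min_dry_s:
            continue
        sel = (track.t >= a) & (track.t <= b)
        if sel.sum() >= 2:
            lon_sel, lat_sel = track.lon[sel], track.lat[sel]
            span = haversine_m(lon_sel.min(), lat_sel.min(), lon_sel.max(), lat_sel.max())
            if span > stationary_m:
                continue
        out.append((float(a), float(b)))
    return out


def exclude_haulouts(track: GpsTrack, haulout_sites: Sequence[tuple[float, float]],
                     depth: Optional[DepthSeries] = None, buffer_km: float = 1.0,
                     min_dry_s: float = 600.0) -> np.ndarray:
    """Exclusion mask: fixes inside any haul-out buffer, or inside a dry
    (hauled-out) period of at least ``min_dry_s``.

    The site list must include the colony itself.
    """
    mask = buffer_mask(track, haulout_sites, buffer_km)
    for a, b in dry_periods(track, depth, min_dry_s):
        mask |= (track.t >= a) & (track.t <= b)
    return mask


def segment_trips(track: GpsTrack, dives: list[Dive], colony: tuple[float, float],
                  haulout_sites: Optional[Sequence[tuple[float, float]]] = None,
                  depth: Optional[DepthSeries] = None, buffer_km: float = 1.0,
                  min_hours: float = 6.0, min_dry_s: float = 600.0) -> list[Trip]:
    """Segment an interpolated track into foraging trips.

    Trip boundaries are crossings of the colony's own 1 km buffer.  Time
    spent within any other haul-out buffer (or hauled out dry) inside a
    trip is subtracted from the trip duration and those fixes are
    dropped.  Candidates shorter than ``min_hours`` (after subtraction)
    or with no dive are discarded.  Dives are attached to their trip by
    start time and joined to the nearest-in-time retained fix.
    """
    sites = list(haulout_sites) if haulout_sites else []
    if colony not in sites:
        sites = [colony] + sites
    away_sites = [s for s in sites if s != colony]

    if dives:
        starts = np.array([d.start for d in dives])
        lo, hi = track.t[0], track.t[-1]
        if starts.min() < lo - 1.0 or starts.max() > hi + 1.0:
            raise ValueError("dive timestamps fall outside the track span")

    at_colony = buffer_mask(track, [colony], buffer_km)
    away = ~at_colony
    if not away.any():
        return []
    edges = np.diff(away.astype(np.int8))
    seg_starts = np.flatnonzero(edges == 1) + 1
    seg_ends = np.flatnonzero(edges == -1)
    if away[0]:
        seg_starts = np.concatenate(([0], seg_starts))
    if away[-1]:
        seg_ends = np.concatenate((seg_ends, [away.size - 1]))

    excl = np.zeros(len(track), dtype=bool)
    if away_sites:
        excl |= buffer_mask(track, away_sites, buffer_km)
    haulout_windows = dry_periods(track, depth, min_dry_s)
    for a, b in haulout_windows:
        excl |= (track.t >= a) & (track.t <= b)

    dive_starts = np.array([d.start for d in dives]) if dives else np.empty(0)
    trips = []
    for k, (i0, i1) in enumerate(zip(seg_starts, seg_ends)):
        t_seg = track.t[i0:i1 + 1]
        keep = ~excl[i0:i1 + 1]
        if keep.sum() < 2:
            continue
        # at-sea duration: span minus time attributable to excluded fixes
        dt = np.diff(t_seg)
        seg_excl_time = dt[~keep[1:]].sum()
        duration_h = (t_seg[-1] - t_seg[0] - seg_excl_time) / 3600.0
        if duration_h < min_hours:
            continue
        in_trip = (dive_starts >= t_seg[0]) & (dive_starts <= t_seg[-1])
        trip_dives = [d for d, ok in zip(dives, in_trip) if ok]
        # drop dives occurring during excluded (hauled-out) windows
        trip_dives = [d for d in trip_dives
                      if not any(a <= d.start <= b for a, b in haulout_windows)]
        if not trip_dives:
            continue
        tt = t_seg[keep]
        lon = track.lon[i0:i1 + 1][keep]
        lat = track.lat[i0:i1 + 1][keep]
        trips.append(Trip(
            trip_id=f"{track.individual_id}-T{len(trips) + 1:02d}",
            individual_id=track.individual_id,
            start=float(t_seg[0]), end=float(t_seg[-1]),
            t=tt, lon=lon, lat=lat, dives=trip_dives,
            duration_h=float(duration_h),
        ))
    return trips


def join_dives_to_fixes(trip: Trip) -> np.ndarray:
    """Index of the nearest-in-time trip fix for each dive (by dive start)."""
    idx = np.searchsorted(trip.t, [d.start for d in trip.dives])
    idx = np.clip(idx, 1, len(trip.t) - 1)
    left = np.abs(trip.t[idx - 1] - [d.start for d in trip.dives])
    right = np.abs(trip.t[idx] - [d.start for d in trip.dives])
    return np.where(left <= right, idx - 1, idx)


def trip_spatial_metrics(trip: Trip, colony: tuple[float, float]) -> tuple[float, float, float]:
    """(total_distance_km, max_range_km, bearing_distal_deg) for a trip.

    Max range is the greatest great-circle distance of any retained fix
    from the colony; the bearing is the initial great-circle bearing from
    the colony to that most distal fix.  Total distance is the horizontal
    path length through the retained fixes plus the summed dive vertical
    distances.
    """
    rng = haversine_m(colony[0], colony[1], trip.lon, trip.lat)
    i_far = int(np.argmax(rng))
    max_range_km = float(rng[i_far]) / 1000.0
    bearing = float(initial_bearing_deg(colony[0], colony[1], trip.lon[i_far], trip.lat[i_far]))
    horiz = float(np.sum(haversine_m(trip.lon[:-1], trip.lat[:-1], trip.lon[1:], trip.lat[1:])))
    vert = sum(d.vertical_distance for d in trip.dives)
    total_km = (horiz + vert) / 1000.0
    trip.total_distance_km = total_km
    trip.max_range_km = max_range_km
    trip.bearing_distal = bearing % 360.0
    return total_km, max_range_km, trip.bearing_distal
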