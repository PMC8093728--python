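"""GPS filtering, interpolation, haul-out exclusion, trip segmentation
and spatial metrics."""

import numpy as np
import pytest

from foragerep.dives import DepthSeries, Dive
from foragerep.geo import LocalProjection, haversine_m
from foragerep.tracks import (GpsTrack, Trip, buffer_mask, dry_periods,
                              exclude_haulouts, interpolate_track, segment_trips,
                              speed_filter, trip_spatial_metrics)
from oracles import forward_speed_scan

COLONY = (146.30, -39.155)
PROJ = LocalProjection(*COLONY)


def track_from_xy(t, x, y, iid="X"):
    lon, lat = PROJ.inverse(np.asarray(x, float), np.asarray(y, float))
    return GpsTrack(iid, np.asarray(t, float), np.atleast_1d(lon), np.atleast_1d(lat))


def fake_dive(start, duration=120.0, max_depth=40.0, iid="X"):
    return Dive(iid, start, start + duration, duration, max_depth,
                duration * 0.5, 1.0, 2 * max_depth)


class TestGeo:
    def test_projection_round_trip(self):
        lon = np.array([146.0, 146.5, 147.2])
        lat = np.array([-39.0, -39.5, -38.8])
        x, y = PROJ.forward(lon, lat)
        lon2, lat2 = PROJ.inverse(x, y)
        assert np.allclose(lon, lon2, atol=1e-9)
        assert np.allclose(lat, lat2, atol=1e-9)

    def test_projected_distance_matches_haversine_near_centre(self):
        x, y = PROJ.forward(146.8, -39.5)
        d_proj = np.hypot(x, y)
        d_gc = haversine_m(*COLONY, 146.8, -39.5)
        assert d_proj == pytest.approx(d_gc, rel=1e-6)  # AEQ: exact from centre


class TestSpeedFilter:
    def test_constant_slow_track_unchanged(self):
        t = np.arange(0, 6000, 600.0)
        x = 2.0 * t  # 2 m/s due east
        tr = track_from_xy(t, x, np.zeros_like(t))
        out = speed_filter(tr, vmax=6.0)
        assert len(out) == len(tr)

    def test_teleporting_fix_removed(self):
        t = np.arange(0, 6000, 600.0)
        x = 1.0 * t
        x[4] += 30000.0  # implies ~50 m/s for one fix
        tr = track_from_xy(t, x, np.zeros_like(t))
        out = speed_filter(tr, vmax=6.0)
        keep = forward_speed_scan(tr.t, tr.lon, tr.lat, 6.0, haversine_m)
        assert len(out) == len(keep) == len(tr) - 1
        assert np.array_equal(out.t, tr.t[keep])

    def test_stationary_fixes_retained(self):
        tr = track_from_xy([0.0, 600.0], [100.0, 100.0], [0.0, 0.0])
        assert len(speed_filter(tr)) == 2


class TestInterpolation:
    def test_fix_count_inclusive(self):
        tr = track_from_xy([0.0, 600.0], [0.0, 600.0], [0.0, 0.0])
        out = interpolate_track(tr, PROJ, step_s=10.0)
        assert len(out) == 61

    def test_midpoint_is_segment_midpoint(self):
        tr = track_from_xy([0.0, 600.0], [0.0, 1000.0], [0.0, 2000.0])
        out = interpolate_track(tr, PROJ, step_s=10.0)
        x, y = PROJ.forward(out.lon, out.lat)
        i = int(np.flatnonzero(out.t == 300.0)[0])
        assert x[i] == pytest.approx(500.0, abs=0.5)
        assert y[i] == pytest.approx(1000.0, abs=0.5)

    def test_path_length_preserved(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 12000, 600.0)
        x = np.cumsum(rng.normal(0, 400, t.size))
        y = np.cumsum(rng.normal(0, 400, t.size))
        tr = track_from_xy(t, x, y)
        out = interpolate_track(tr, PROJ, step_s=10.0)
        seg = np.sum(haversine_m(tr.lon[:-1], tr.lat[:-1], tr.lon[1:], tr.lat[1:]))
        fine = np.sum(haversine_m(out.lon[:-1], out.lat[:-1], out.lon[1:], out.lat[1:]))
        assert fine == pytest.approx(seg, rel=1e-3)

    def test_single_fix_rejected(self):
        tr = GpsTrack("X", np.array([0.0]), np.array([146.3]), np.array([-39.1]))
        with pytest.raises(ValueError):
            interpolate_track(tr, PROJ)


class TestHauloutExclusion:
    def test_buffer_rule(self):
        # 0.5 km from the site -> excluded; 1.5 km -> retained
        tr = track_from_xy([0.0, 600.0], [10000.0, 10000.0], [500.0, 1500.0])
        site_lon, site_lat = PROJ.inverse(10000.0, 0.0)
        mask = buffer_mask(tr, [(float(site_lon), float(site_lat))], buffer_km=1.0)
        assert mask.tolist() == [True, False]

    def test_dry_stationary_period_is_haulout(self):
        # 15 min with no wet depth samples while stationary -> haul-out
        t = np.arange(0, 3600, 60.0)
        x = np.full(t.size, 5000.0)
        tr = track_from_xy(t, x, np.zeros_like(t))
        wet_t = np.concatenate([np.arange(0, 1000, 5.0), np.arange(1900, 3600, 5.0)])
        depth = DepthSeries("X", wet_t, np.full(wet_t.size, 10.0), 5.0)
        periods = dry_periods(tr, depth, min_dry_s=600.0)
        assert len(periods) == 1
        a, b = periods[0]
        assert b - a >= 600.0

    def test_moving_gap_not_haulout(self):
        t = np.arange(0, 3600, 60.0)
        x = 1.5 * t  # steadily moving
        tr = track_from_xy(t, x, np.zeros_like(t))
        wet_t = np.concatenate([np.arange(0, 1000, 5.0), np.arange(1900, 3600, 5.0)])
        depth = DepthSeries("X", wet_t, np.full(wet_t.size, 10.0), 5.0)
        assert dry_periods(tr, depth, min_dry_s=600.0) == []

    def test_empty_site_list_rejected(self):
        tr = track_from_xy([0.0, 600.0], [0.0, 100.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            exclude_haulouts(tr, [])


def out_and_back(duration_h, step_s=60.0, range_m=20000.0, t0=0.0):
    """Symmetric out-and-back excursion leaving/returning to the colony."""
    n = int(duration_h * 3600 / step_s)
    t = t0 + np.arange(n + 1) * step_s
    frac = np.arange(n + 1) / n
    y = range_m * (1.0 - np.abs(2.0 * frac - 1.0))
    return t, np.zeros_like(t), y


class TestSegmentTrips:
    def _track(self, duration_h, dive_times, t0_colony_h=2.0, range_m=20000.0):
        step = 60.0
        pre_t = np.arange(0, t0_colony_h * 3600, step)
        trip_t, trip_x, trip_y = out_and_back(duration_h, step, range_m,
                                              t0=pre_t[-1] + step)
        post_t = np.arange(trip_t[-1] + step, trip_t[-1] + 3600, step)
        t = np.concatenate([pre_t, trip_t, post_t])
        x = np.concatenate([np.zeros(pre_t.size), trip_x, np.zeros(post_t.size)])
        y = np.concatenate([np.zeros(pre_t.size), trip_y, np.zeros(post_t.size)])
        tr = track_from_xy(t, x, y)
        dives = [fake_dive(s) for s in dive_times]
        return tr, dives, trip_t

    def test_short_bout_is_not_a_trip(self):
        tr, dives, tt = self._track(5.0, dive_times=[])
        dives = [fake_dive(tt[len(tt) // 2])]
        assert segment_trips(tr, dives, COLONY) == []

    def test_seven_hour_bout_with_one_dive_is_a_trip(self):
        tr, dives, tt = self._track(7.0, dive_times=[])
        dives = [fake_dive(tt[len(tt) // 2])]
        trips = segment_trips(tr, dives, COLONY)
        assert len(trips) == 1
        assert trips[0].duration_h >= 6.0
        assert len(trips[0].dives) == 1

    def test_bout_without_dives_dropped(self):
        tr, _, _ = self._track(8.0, dive_times=[])
        assert segment_trips(tr, [], COLONY) == []

    def test_haulout_time_subtracted_from_duration(self):
        # 20 h bout with a 2 h stationary dry period at a distant site
        step = 60.0
        t = np.arange(0, 20 * 3600, step)
        y = np.minimum(1.2 * t, 25000.0)
        # park at 25 km between hours 8 and 10
        x = np.zeros_like(t)
        inside = (t >= 8 * 3600) & (t <= 10 * 3600)
        y = y.copy()
        y[t > 10 * 3600] = np.maximum(25000.0 - 1.2 * (t[t > 10 * 3600] - 10 * 3600), 500.0)
        pre = np.arange(-3600, 0, step)
        t_all = np.concatenate([pre, t])
        x_all = np.concatenate([np.zeros(pre.size), x])
        y_all = np.concatenate([np.zeros(pre.size), y])
        tr = track_from_xy(t_all, x_all, y_all)
        site = PROJ.inverse(0.0, 25000.0)
        # wet depth everywhere except the haul-out window
        wet_t = t[~inside][::5]
        depth = DepthSeries("X", wet_t.astype(float),
                            np.full(wet_t.size, 8.0), 60.0)
        dives = [fake_dive(4 * 3600.0), fake_dive(14 * 3600.0)]
        trips = segment_trips(tr, dives, COLONY,
                              haulout_sites=[COLONY, (float(site[0]), float(site[1]))],
                              depth=depth)
        assert len(trips) == 1
        span_h = (trips[0].end - trips[0].start) / 3600.0
        assert trips[0].duration_h < span_h - 1.5  # ~2 h subtracted

    def test_dive_outside_track_span_rejected(self):
        tr, _, tt = self._track(7.0, dive_times=[])
        with pytest.raises(ValueError):
            segment_trips(tr, [fake_dive(tr.t[-1] + 7200.0)], COLONY)


class TestTripSpatialMetrics:
    def _trip(self, x, y, t=None, dives=()):
        t = np.arange(len(x)) * 60.0 if t is None else t
        lon, lat = PROJ.inverse(np.asarray(x, float), np.asarray(y, float))
        return Trip("X-T01", "X", t[0], t[-1], np.asarray(t, float),
                    np.atleast_1d(lon), np.atleast_1d(lat), list(dives),
                    duration_h=(t[-1] - t[0]) / 3600.0)

    def test_due_south_bearing(self):
        trip = self._trip([0.0, 0.0, 0.0], [0.0, -20000.0, 0.0])
        _, _, bearing = trip_spatial_metrics(trip, COLONY)
        assert bearing == pytest.approx(180.0, abs=0.2)

    def test_out_and_back_distances(self):
        n = 101
        y = np.concatenate([np.linspace(0, 50000.0, n), np.linspace(50000.0, 0, n)[1:]])
        trip = self._trip(np.zeros_like(y), y)
        total, max_range, _ = trip_spatial_metrics(trip, COLONY)
        assert max_range == pytest.approx(50.0, rel=1e-3)
        assert total == pytest.approx(100.0, rel=1e-3)

    def test_bearing_always_in_range(self, pipeline_result):
        b = pipeline_result.trips["bearing_distal"]
        assert ((b >= 0) & (b < 360)).all()

    def test_total_distance_bounds_max_range(self, pipeline_result):
        df = pipeline_result.trips
        assert (df["total_distance_km"] >= 2 * df["max_range_km"] - 0.5).all()

    def test_trips_do_not_overlap_within_individual(self, pipeline_result):
        df = pipeline_result.trips
        for _, sub in df.groupby("individual_id"):
            sub = sub.sort_values("start")
            assert (sub["end"].iloc[:-1].values <= sub["start"].iloc[1:].values).all()
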