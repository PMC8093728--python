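"""Synthetic biologging data for a central-place foraging population.

Generates GPS tracks (10 min fixes), time-depth records (1 or 5 s) and
morphometrics for a population of lactating otariid females breeding at
a single colony over a shallow (~60-70 m) shelf, together with the full
ground truth (latent individual means, trip boundaries, per-dive
benthic labels, realized repeatabilities) that downstream tests check
against.

Each individual carries latent means for bearing to its foraging patch,
log trip duration and logit benthic propensity; trips draw around those
means, so the between- vs within-individual variance of every behaviour
is controlled by the configuration and the realized repeatability
R = var_between / (var_between + var_within) is known exactly from the
drawn values.  A trip is an outbound correlated-random-walk leg along
the trip's bearing, an area-restricted-search loop at the distal patch,
and a return leg; cruising speed is 1 m s^-1 (well under the 6 m s^-1
error filter, so clean tracks pass it untouched).  Dives are trapezoids:
benthic dives reach the local seafloor with a long bottom phase (~50% of
the dive), pelagic dives reach 30-70% of the seafloor depth with a short
bottom phase (~15%).  Surface intervals are log-normal (median 90 s).
A linear pressure drift and Gaussian sensor noise are added to the raw
depth record to exercise the zero-offset correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .dives import DepthSeries
from .geo import LocalProjection
from .tracks import GpsTrack

# 2010-01-01T00:00:00Z
DEFAULT_EPOCH = 1262304000.0

MORPH_COLUMNS = ("mass_kg", "standard_length_cm", "flipper_length_cm",
                 "axis_length_cm", "axillary_girth_cm")
MORPH_MEANS = (70.4, 151.4, 42.5, 63.2, 99.2)
MORPH_SDS = (8.0, 6.0, 1.8, 2.8, 4.5)


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic population.

    Defaults emulate the deployment the pipeline is built for: 34
    individuals with 3-12 trips each of roughly 2-11 days, a colony on
    Kanowna Island (Bass Strait), a 60-70 m seafloor, ~75% benthic
    diving, and low-to-moderate between-individual variance.
    """

    n_individuals: int = 34
    trips_per_individual: tuple = (3, 12)     # int or (lo, hi) inclusive
    gps_interval: float = 600.0               # s
    depth_interval: float = 5.0               # s (1 or 5)
    colony: tuple = (146.30, -39.155)         # lon, lat
    utc_offset_hours: float = 10.0            # local clock = UTC + offset

    # seafloor: smooth deterministic field in [base-amp, base+amp] m
    seafloor_base: float = 65.0
    seafloor_amplitude: float = 4.0
    seafloor_length_km: float = 80.0

    # behaviour latents: between-individual / within-individual variances
    bearing_mean: float = 203.5               # degrees
    bearing_var_between: float = 1225.0       # deg^2 (sd 35)
    bearing_var_within: float = 1225.0
    log_duration_mean: float = float(np.log(96.0))   # trips ~4 days median
    duration_var_between: float = 0.05        # on log-hours scale
    duration_var_within: float = 0.11
    benthic_propensity_mean: float = 0.75
    benthic_var_between: float = 0.35         # on logit scale
    benthic_var_within: float = 0.25

    # movement
    patch_distance_mean_km: float = 80.0
    patch_distance_sd_km: float = 18.0        # between individuals
    patch_distance_cv_within: float = 0.05
    patch_jitter_km: float = 5.0              # per-trip isotropic patch jitter
    cruise_speed: float = 1.0                 # m s^-1 (< 2, under the filter)
    ars_speed: float = 0.4
    ars_radius_km: float = 4.0
    heading_sd_transit: float = 12.0          # deg, AR(1) CRW noise
    heading_sd_ars: float = 60.0

    # diving
    descent_rate_mean: float = 1.3            # m s^-1
    descent_rate_sd: float = 0.12
    benthic_bottom_fraction: float = 0.5
    pelagic_bottom_fraction: float = 0.15
    pelagic_depth_range: tuple = (0.3, 0.7)   # fraction of local seafloor
    surface_gap_median_s: float = 90.0
    surface_gap_sigma: float = 0.6
    long_gap_prob: float = 0.08               # occasional extended surface bout
    long_gap_factor: float = 8.0
    depth_noise_sd: float = 0.12              # m
    drift_amplitude_m: float = 1.5            # linear drift over deployment

    # schedule
    start_epoch: float = DEFAULT_EPOCH
    pre_trip_hours: float = 6.0
    inter_trip_days: tuple = (0.5, 2.0)
    daylight_window: tuple = (7.0, 18.0)

    # optional mid-trip haul-out visits (sites must lie near the patches)
    haulout_sites: tuple = ()
    haulout_probability: float = 0.0
    haulout_duration_h: float = 2.0

    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        lo, hi = self.trip_range
        if lo < 1:
            raise ValueError("at least one trip per individual is required")
        for name in ("bearing_var_between", "bearing_var_within",
                     "duration_var_between", "duration_var_within",
                     "benthic_var_between", "benthic_var_within"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.benthic_propensity_mean <= 1.0):
            raise ValueError("benthic_propensity_mean must be in [0, 1]")
        if self.gps_interval <= 0 or self.depth_interval <= 0:
            raise ValueError("sampling intervals must be positive")

    @property
    def trip_range(self) -> tuple[int, int]:
        t = self.trips_per_individual
        if isinstance(t, (int, np.integer)):
            return int(t), int(t)
        return int(t[0]), int(t[1])

    def seafloor(self, x_m, y_m):
        """Deterministic seafloor depth (m) at projected metres east/north."""
        L = self.seafloor_length_km * 1000.0
        return self.seafloor_base + self.seafloor_amplitude * \
            np.sin(2 * np.pi * np.asarray(x_m) / L) * np.cos(2 * np.pi * np.asarray(y_m) / L)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated population."""

    individuals: pd.DataFrame   # latent means and home patches
    trips: pd.DataFrame         # boundaries + per-trip latent draws
    dives: pd.DataFrame         # per-dive labels and true depths
    realized_r: dict            # behaviour -> realized repeatability

    def __post_init__(self):
        for v in self.realized_r.values():
            if not (0.0 <= v <= 1.0):
                raise ValueError("realized R outside [0, 1]")


def _calibrated_logit_mean(p_target: float, total_var: float) -> float:
    """Latent logit mean such that E[expit(N(mu, total_var))] == p_target,
    correcting the Jensen bias of the logit-normal (Gauss-Hermite)."""
    if total_var <= 0 or p_target in (0.0, 1.0):
        return float(logit(np.clip(p_target, 1e-9, 1 - 1e-9)))
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)

    def mean_minus_target(mu):
        return float(weights @ expit(mu + np.sqrt(total_var) * nodes)) / weights.sum() - p_target

    lo, hi = logit(p_target) - 5.0, logit(p_target) + 5.0
    return float(brentq(mean_minus_target, lo, hi, xtol=1e-10))


def _wrap_deg(a):
    return np.mod(a, 360.0)


def _morphometrics(rng: np.random.Generator, ids: Sequence[str]) -> pd.DataFrame:
    """Morphometrics near the population means, with realistic collinearity
    (mass correlates strongly with girth and standard length)."""
    corr = np.array([
        # mass  len   flip  axis  girth
        [1.00, 0.75, 0.30, 0.45, 0.85],
        [0.75, 1.00, 0.35, 0.50, 0.55],
        [0.30, 0.35, 1.00, 0.25, 0.20],
        [0.45, 0.50, 0.25, 1.00, 0.35],
        [0.85, 0.55, 0.20, 0.35, 1.00],
    ])
    sds = np.array(MORPH_SDS)
    cov = corr * np.outer(sds, sds)
    vals = rng.multivariate_normal(MORPH_MEANS, cov, size=len(ids),
                                   method="cholesky")
    df = pd.DataFrame(vals, columns=list(MORPH_COLUMNS))
    df.insert(0, "individual_id", list(ids))
    return df


class _TripBuilder:
    """Generates one trip's GPS path, dives and depth record."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator,
                 proj: LocalProjection):
        self.cfg = cfg
        self.rng = rng
        self.proj = proj

    def build(self, t0: float, duration_h: float, p_benthic: float,
              patch_xy: tuple[float, float]):
        cfg, rng = self.cfg, self.rng
        dt = cfg.gps_interval
        T = duration_h * 3600.0
        px, py = patch_xy
        ars_r = cfg.ars_radius_km * 1000.0

        ts, xs, ys = [t0], [0.0], [0.0]
        t, x, y = t0, 0.0, 0.0
        noise = 0.0
        # outbound leg
        budget = t0 + 0.48 * T
        while np.hypot(px - x, py - y) > ars_r and t < budget:
            az = np.degrees(np.arctan2(px - x, py - y))
            noise = 0.5 * noise + rng.normal(0.0, cfg.heading_sd_transit)
            h = np.radians(az + noise)
            step = cfg.cruise_speed * dt
            x += step * np.sin(h)
            y += step * np.cos(h)
            t += dt
            ts.append(t); xs.append(x); ys.append(y)
        # area-restricted search at the patch
        while True:
            time_home = np.hypot(x, y) / cfg.cruise_speed * 1.2
            if t + time_home + dt >= t0 + T:
                break
            if np.hypot(px - x, py - y) > ars_r:
                az = np.degrees(np.arctan2(px - x, py - y)) + rng.normal(0.0, 20.0)
            else:
                az = rng.uniform(0.0, 360.0)
            h = np.radians(az)
            step = cfg.ars_speed * dt
            x += step * np.sin(h)
            y += step * np.cos(h)
            t += dt
            ts.append(t); xs.append(x); ys.append(y)
        # return leg
        noise = 0.0
        while np.hypot(x, y) > 400.0:
            az = np.degrees(np.arctan2(-x, -y))
            noise = 0.5 * noise + rng.normal(0.0, cfg.heading_sd_transit * 0.6)
            h = np.radians(az + noise)
            step = min(cfg.cruise_speed * dt, max(np.hypot(x, y) - 200.0, 50.0))
            x += step * np.sin(h)
            y += step * np.cos(h)
            t += dt
            ts.append(t); xs.append(x); ys.append(y)
        ts.append(t + dt); xs.append(0.0); ys.append(0.0)
        ts = np.asarray(ts); xs = np.asarray(xs); ys = np.asarray(ys)
        t_end = float(ts[-1])

        dives = self._dives(t0, t_end, ts, xs, ys, p_benthic)
        return ts, xs, ys, t_end, dives

    def _dives(self, t0, t_end, ts, xs, ys, p_benthic):
        """Dive cycle over the trip: (start, duration, max_depth, descent
        rate, bottom fraction, is_benthic) tuples on the sample raster."""
        cfg, rng = self.cfg, self.rng
        out = []
        mu_gap = np.log(cfg.surface_gap_median_s)
        t = t0 + 300.0
        while True:
            gap = rng.lognormal(mu_gap, cfg.surface_gap_sigma)
            if rng.random() < cfg.long_gap_prob:
                gap *= cfg.long_gap_factor
            t += gap
            x = np.interp(t, ts, xs)
            y = np.interp(t, ts, ys)
            floor = float(self.cfg.seafloor(x, y))
            benthic = bool(rng.random() < p_benthic)
            if benthic:
                depth = max(floor + rng.normal(0.0, 0.4), 8.0)
                bf = np.clip(cfg.benthic_bottom_fraction + rng.normal(0.0, 0.04),
                             0.35, 0.65)
            else:
                depth = max(rng.uniform(*cfg.pelagic_depth_range) * floor, 8.0)
                bf = np.clip(cfg.pelagic_bottom_fraction + rng.normal(0.0, 0.03),
                             0.05, 0.25)
            rate = max(rng.normal(cfg.descent_rate_mean, cfg.descent_rate_sd), 0.6)
            dur = 2.0 * (depth / rate) / (1.0 - bf)
            if t + dur + 60.0 > t_end:
                break
            # snap the start to the depth-sample raster
            t_snap = t0 + np.ceil((t - t0) / cfg.depth_interval) * cfg.depth_interval
            out.append((t_snap, dur, depth, rate, bf, benthic))
            t = t_snap + dur
        return out


def _trip_depth_block(cfg: SimulationConfig, t0: float, t_end: float,
                      dives: list) -> tuple[np.ndarray, np.ndarray]:
    """Sampled true depth trace (no noise/drift) for one trip."""
    n = int(np.floor((t_end - t0) / cfg.depth_interval)) + 1
    t = t0 + np.arange(n) * cfg.depth_interval
    depth = np.zeros(n)
    for (ds, dur, dmax, rate, bf, _b) in dives:
        t_desc = dmax / rate
        t_bot = dur * bf
        t_asc = dur - t_desc - t_bot
        if t_asc <= 0:  # keep the trapezoid well-formed
            t_bot = max(dur - 2 * t_desc, 0.0)
            t_asc = t_desc
        i0 = int(np.round((ds - t0) / cfg.depth_interval))
        i1 = min(int(np.floor((ds + dur - t0) / cfg.depth_interval)), n - 1)
        off = t[i0:i1 + 1] - ds
        prof = np.interp(off, [0.0, t_desc, t_desc + t_bot, dur],
                         [0.0, dmax, dmax, 0.0])
        depth[i0:i1 + 1] = np.maximum(depth[i0:i1 + 1], prof)
    return t, depth


def simulate_population(config: SimulationConfig):
    """Simulate the population.

    Returns
    -------
    gps : dict individual_id -> GpsTrack (raw fixes incl. colony attendance)
    depth : dict individual_id -> DepthSeries (raw, drifting, wet-only)
    morphometrics : DataFrame
    truth : SimulationTruth
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    proj = LocalProjection(*cfg.colony)
    ids = [f"F{i + 1:02d}" for i in range(cfg.n_individuals)]
    morph = _morphometrics(rng, ids)

    mu_logit = _calibrated_logit_mean(cfg.benthic_propensity_mean,
                                      cfg.benthic_var_between + cfg.benthic_var_within)
    lo_trips, hi_trips = cfg.trip_range

    gps, depth = {}, {}
    ind_rows, trip_rows, dive_rows = [], [], []
    draws = {"bearing": ([], []), "log_duration": ([], []),
             "logit_benthic": ([], [])}  # (alpha draws, eps draws)

    for iid in ids:
        a_bear = rng.normal(0.0, np.sqrt(cfg.bearing_var_between))
        a_dur = rng.normal(0.0, np.sqrt(cfg.duration_var_between))
        a_ben = rng.normal(0.0, np.sqrt(cfg.benthic_var_between))
        d_home = np.clip(rng.normal(cfg.patch_distance_mean_km,
                                    cfg.patch_distance_sd_km), 30.0, 140.0)
        draws["bearing"][0].append(a_bear)
        draws["log_duration"][0].append(a_dur)
        draws["logit_benthic"][0].append(a_ben)

        n_trips = int(rng.integers(lo_trips, hi_trips + 1))
        builder = _TripBuilder(cfg, rng, proj)
        t_cursor = cfg.start_epoch + rng.uniform(0.0, 24.0) * 3600.0
        all_t, all_x, all_y = [], [], []
        dep_t, dep_d = [], []
        dive_t_shift = []

        def colony_block(t_from, hours):
            n = max(int(hours * 3600.0 / cfg.gps_interval), 2)
            tt = t_from + np.arange(n) * cfg.gps_interval
            all_t.append(tt)
            all_x.append(rng.normal(0.0, 60.0, n))
            all_y.append(rng.normal(0.0, 60.0, n))
            return float(tt[-1] + cfg.gps_interval)

        t_cursor = colony_block(t_cursor, cfg.pre_trip_hours)
        home_bearing = _wrap_deg(cfg.bearing_mean + a_bear)
        hx = d_home * 1000.0 * np.sin(np.radians(home_bearing))
        hy = d_home * 1000.0 * np.cos(np.radians(home_bearing))

        for k in range(n_trips):
            e_bear = rng.normal(0.0, np.sqrt(cfg.bearing_var_within))
            e_dur = rng.normal(0.0, np.sqrt(cfg.duration_var_within))
            e_ben = rng.normal(0.0, np.sqrt(cfg.benthic_var_within))
            draws["bearing"][1].append(e_bear)
            draws["log_duration"][1].append(e_dur)
            draws["logit_benthic"][1].append(e_ben)

            bearing_t = _wrap_deg(cfg.bearing_mean + a_bear + e_bear)
            dur_latent = float(np.exp(cfg.log_duration_mean + a_dur + e_dur))
            dur_h = float(np.clip(dur_latent, 12.0, 400.0))
            p_ben = float(expit(mu_logit + a_ben + e_ben))
            d_t = d_home * (1.0 + rng.normal(0.0, cfg.patch_distance_cv_within))
            # cap the patch so the trip can reach it and return
            d_t = min(d_t, 0.42 * dur_h * 3600.0 * cfg.cruise_speed / 1000.0)
            px = d_t * 1000.0 * np.sin(np.radians(bearing_t))
            py = d_t * 1000.0 * np.cos(np.radians(bearing_t))
            jx, jy = rng.normal(0.0, cfg.patch_jitter_km * 1000.0, 2)
            t0 = float(np.round(t_cursor))
            ts, xs, ys, t_end, dives = builder.build(t0, dur_h, p_ben,
                                                     (px + jx, py + jy))
            if cfg.haulout_probability > 0 and cfg.haulout_sites and \
                    rng.random() < cfg.haulout_probability:
                ts, xs, ys, dives = _inject_haulout(cfg, rng, proj, ts, xs, ys, dives)
            all_t.append(ts); all_x.append(xs); all_y.append(ys)
            bt, bd = _trip_depth_block(cfg, t0, t_end, dives)
            dep_t.append(bt); dep_d.append(bd)
            trip_rows.append({
                "individual_id": iid, "trip_index": k + 1, "start": t0,
                "end": t_end, "bearing_latent": bearing_t,
                "duration_h_latent": dur_latent, "benthic_propensity": p_ben,
                "patch_x_m": px + jx, "patch_y_m": py + jy,
                "seafloor_at_patch_m": float(cfg.seafloor(px + jx, py + jy)),
            })
            for (ds, ddur, dmax, _r, _bf, benthic) in dives:
                dive_rows.append({"individual_id": iid, "trip_index": k + 1,
                                  "start": ds, "duration_s": ddur,
                                  "max_depth_m": dmax, "is_benthic": benthic})
            gap_h = rng.uniform(*cfg.inter_trip_days) * 24.0
            t_cursor = colony_block(t_end + cfg.gps_interval, gap_h)
        t_cursor = colony_block(t_cursor, cfg.pre_trip_hours)

        tt = np.concatenate(all_t)
        xx = np.concatenate(all_x)
        yy = np.concatenate(all_y)
        order = np.argsort(tt)
        tt, xx, yy = tt[order], xx[order], yy[order]
        keep = np.concatenate(([True], np.diff(tt) > 0))
        lon, lat = proj.inverse(xx[keep], yy[keep])
        gps[iid] = GpsTrack(iid, np.round(tt[keep]), np.atleast_1d(lon),
                            np.atleast_1d(lat))

        dt_all = np.concatenate(dep_t)
        dd_all = np.concatenate(dep_d)
        order = np.argsort(dt_all)
        dt_all, dd_all = dt_all[order], dd_all[order]
        kp = np.concatenate(([True], np.diff(dt_all) > 0))
        dt_all, dd_all = dt_all[kp], dd_all[kp]
        span = (dt_all[-1] - dt_all[0]) or 1.0
        drift = cfg.drift_amplitude_m * (dt_all - dt_all[0]) / span
        raw = dd_all + drift + rng.normal(0.0, cfg.depth_noise_sd, dd_all.size)
        depth[iid] = DepthSeries(iid, dt_all, raw, cfg.depth_interval)

        ind_rows.append({
            "individual_id": iid, "bearing_mean": home_bearing,
            "log_duration_mean": cfg.log_duration_mean + a_dur,
            "logit_benthic_mean": mu_logit + a_ben,
            "patch_distance_km": d_home, "patch_x_m": hx, "patch_y_m": hy,
            "seafloor_at_patch_m": float(cfg.seafloor(hx, hy)),
            "n_trips": n_trips,
        })

    realized_r = {}
    for name, (alphas, epss) in draws.items():
        va = float(np.var(alphas, ddof=1)) if len(alphas) > 1 else 0.0
        ve = float(np.var(epss, ddof=1)) if len(epss) > 1 else 0.0
        realized_r[name] = va / (va + ve) if (va + ve) > 0 else 0.0

    truth = SimulationTruth(
        individuals=pd.DataFrame(ind_rows),
        trips=pd.DataFrame(trip_rows),
        dives=pd.DataFrame(dive_rows),
        realized_r=realized_r,
    )
    return gps, depth, morph, truth


def _inject_haulout(cfg, rng, proj, ts, xs, ys, dives):
    """Pin the track to a haul-out site for ``haulout_duration_h`` in the
    middle of the trip and drop the dives in that window (the animal is
    dry, so the depth record has a gap there)."""
    site = cfg.haulout_sites[int(rng.integers(len(cfg.haulout_sites)))]
    sx, sy = proj.forward(*site)
    mid = ts[0] + 0.5 * (ts[-1] - ts[0])
    w0, w1 = mid, mid + cfg.haulout_duration_h * 3600.0
    sel = (ts >= w0) & (ts <= w1)
    xs = xs.copy(); ys = ys.copy()
    xs[sel] = float(sx) + rng.normal(0.0, 30.0, sel.sum())
    ys[sel] = float(sy) + rng.normal(0.0, 30.0, sel.sum())
    dives = [d for d in dives if not (w0 <= d[0] <= w1)]
    return ts, xs, ys, dives


# ---------------------------------------------------------------------------
# fixtures on disk

def _iso(t: np.ndarray) -> pd.Series:
    return pd.to_datetime(np.asarray(t).astype("int64"), unit="s", utc=True) \
        .strftime("%Y-%m-%dT%H:%M:%SZ")


def write_fixtures(gps: dict, depth: dict, morph: pd.DataFrame,
                   truth: SimulationTruth, directory) -> list[Path]:
    """Write the simulated population as the documented CSV fixture set.

    Per individual: ``gps_<id>.csv`` (individual_id, timestamp_iso8601,
    lon, lat) and ``depth_<id>.csv`` (individual_id, timestamp_iso8601,
    depth_m); plus ``morphometrics.csv`` and the truth tables.  Round-trips
    losslessly through the readers in :mod:`foragerep.io`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for iid, track in gps.items():
        df = pd.DataFrame({"individual_id": iid,
                           "timestamp_iso8601": _iso(track.t),
                           "lon": track.lon, "lat": track.lat})
        p = directory / f"gps_{iid}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    for iid, series in depth.items():
        df = pd.DataFrame({"individual_id": iid,
                           "timestamp_iso8601": _iso(series.t),
                           "depth_m": series.depth})
        p = directory / f"depth_{iid}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    p = directory / "morphometrics.csv"
    morph.to_csv(p, index=False)
    written.append(p)
    for name, df in (("truth_individuals", truth.individuals),
                     ("truth_trips", truth.trips), ("truth_dives", truth.dives)):
        p = directory / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    p = directory / "truth_meta.json"
    p.write_text(json.dumps({"realized_r": truth.realized_r}, indent=2))
    written.append(p)
    return written
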