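"""End-to-end orchestration: sensor streams -> trips -> behaviour table
-> fidelity, success/efficiency indices, repeatability and consistency
models, with a manifest accounting for every dropped record.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import benthic, consistency, dives as dv, fidelity as fid, indices as fx, \
    repeatability as rpt, tracks as tk
from .config import PipelineConfig
from .geo import LocalProjection
from .io import iso8601, load_fixture_dir
from .simulate import MORPH_COLUMNS

GAUSSIAN_BEHAVIORS = {
    "max_range_km": None,
    "total_distance_km": np.cbrt,
    "duration_h": np.cbrt,
    "dive_rate": np.cbrt,
    "modal_depth": None,
}
PROPORTION_BEHAVIORS = ("prop_benthic", "prop_daylight")


@dataclass
class RunManifest:
    config_hash: str
    overrides: dict
    stages: dict = field(default_factory=dict)   # stage -> {in, out, dropped: {reason: n}}
    warnings: list = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int, dropped: dict):
        attributed = sum(dropped.values())
        if n_in != n_out + attributed:
            raise RuntimeError(
                f"stage {stage}: {n_in} in != {n_out} out + {attributed} dropped")
        self.stages[stage] = {"in": int(n_in), "out": int(n_out),
                              "dropped": {k: int(v) for k, v in dropped.items()}}

    def warn(self, msg: str):
        self.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)

    def to_json(self) -> str:
        return json.dumps({"config_hash": self.config_hash,
                           "overrides": self.overrides,
                           "stages": self.stages,
                           "warnings": self.warnings}, indent=2, default=str)


@dataclass
class PipelineResult:
    trips: pd.DataFrame
    dives: pd.DataFrame
    fidelity: pd.DataFrame
    repeatability: pd.DataFrame
    consistency_profiles: pd.DataFrame
    consistency_models: dict
    manifest: RunManifest

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trips.to_csv(out / "trips.csv", index=False)
        self.dives.to_csv(out / "dives.csv", index=False)
        self.fidelity.to_csv(out / "fidelity.csv", index=False)
        self.trips[["trip_id", "individual_id", "ftsi", "ftei"]].to_csv(
            out / "indices.csv", index=False)
        self.repeatability.to_csv(out / "repeatability.csv", index=False)
        reports = {}
        for resp, rep in self.consistency_models.items():
            reports[resp] = {
                "formula": rep.formula, "df": rep.df_model, "aic": rep.aic,
                "loglik": rep.loglik, "l_ratio": rep.lratio, "p": rep.p_lratio,
                "r2": rep.r2,
                "coefficients": [
                    {"covariate": name, "est": row["est"], "se": row["se"],
                     "t": row["t"], "ci_low": row["ci_low"], "ci_high": row["ci_high"]}
                    for name, row in rep.coef.iterrows()],
            }
        (out / "consistency_models.json").write_text(json.dumps(reports, indent=2))
        self.consistency_profiles.to_csv(out / "consistency_profiles.csv", index=False)
        (out / "manifest.json").write_text(self.manifest.to_json())
        return out


def process_individual(iid, track, depth, cfg: PipelineConfig, proj,
                       manifest: RunManifest):
    """Sensor streams of one individual -> (trips, labelled dives)."""
    corrected = dv.zero_offset_correct(depth, cfg.zoc_window_s, cfg.zoc_quantile)
    all_dives = dv.detect_dives(corrected, cfg.dive_threshold_m)

    n_fix = len(track)
    filtered = tk.speed_filter(track, cfg.speed_vmax_ms)
    manifest.record(f"speed_filter[{iid}]", n_fix, len(filtered),
                    {"speed_gt_vmax": n_fix - len(filtered)})
    interp = tk.interpolate_track(filtered, proj, cfg.interp_step_s)

    sites = [cfg.colony] + [tuple(s) for s in cfg.haulout_sites]
    trips = tk.segment_trips(interp, all_dives, cfg.colony, sites, corrected,
                             cfg.buffer_km, cfg.trip_min_hours,
                             cfg.haulout_min_dry_min * 60.0)
    used = {id(d) for tr in trips for d in tr.dives}
    manifest.record(f"segment_trips[{iid}]", len(all_dives),
                    len(used), {"outside_valid_trip": len(all_dives) - len(used)})
    for tr in trips:
        tk.trip_spatial_metrics(tr, cfg.colony)
    return trips


def run_pipeline(config: PipelineConfig, gps=None, depth=None, morph=None,
                 ) -> PipelineResult:
    """Run the full analysis.

    Inputs come from ``config.data_dir`` unless the in-memory ``gps`` /
    ``depth`` dicts and ``morph`` table are given.  Deterministic given
    config + seed.
    """
    cfg = config
    if gps is None or depth is None:
        gps, depth, morph_loaded = load_fixture_dir(cfg.data_dir)
        if morph is None:
            morph = morph_loaded
    proj = LocalProjection(*cfg.colony)
    manifest = RunManifest(cfg.hash(), cfg.overrides())

    all_trips: list[tk.Trip] = []
    for iid in sorted(gps):
        if iid not in depth:
            manifest.warn(f"{iid}: no depth record; individual skipped")
            continue
        trips = process_individual(iid, gps[iid], depth[iid], cfg, proj, manifest)
        # benthic classification is per individual, pooling its trips
        ind_dives = [d for tr in trips for d in tr.dives]
        if not ind_dives:
            manifest.warn(f"{iid}: no valid trips")
            continue
        if len(ind_dives) < cfg.min_dives_for_split:
            manifest.warn(f"{iid}: {len(ind_dives)} dives < "
                          f"{cfg.min_dives_for_split}; individual skipped")
            continue
        benthic.classify_dives(ind_dives, cfg.min_dives_for_split)
        capture = cfg.capture_model()
        for tr in trips:
            tr.dive_metrics = dv.trip_dive_summary(
                tr.dives, tr.duration_h, cfg.daylight_window, cfg.utc_offset_hours)
            all_trips.append(tr)
            try:
                idx = fx.trip_indices(tr.dives, capture, tr.duration_h)
                tr.ftsi, tr.ftei = idx.ftsi, idx.ftei
            except ValueError:
                tr.ftsi = tr.ftei = np.nan
                manifest.warn(f"{tr.trip_id}: no benthic dives; FTSI/FTEI missing")

    trips_df = _trips_table(all_trips, morph)
    n0 = len(trips_df)
    if n0:
        counts = trips_df.groupby("individual_id")["trip_id"].transform("size")
        kept = trips_df[counts >= cfg.min_trips_per_individual].reset_index(drop=True)
    else:
        kept = trips_df
    manifest.record("min_trips_filter", n0, len(kept),
                    {"individual_lt_min_trips": n0 - len(kept)})
    dives_df = _dives_table(all_trips, kept)

    fidelity_df = _fidelity_table(all_trips, kept, proj, cfg)
    if len(kept):
        repeat_df = _repeatability_table(kept, morph, cfg, manifest)
        profiles, reports = _consistency(kept, fidelity_df, manifest)
    else:
        manifest.warn("no trips survived filtering; statistical stages skipped")
        repeat_df = pd.DataFrame()
        profiles, reports = pd.DataFrame(), {}

    return PipelineResult(trips=kept, dives=dives_df, fidelity=fidelity_df,
                          repeatability=repeat_df, consistency_profiles=profiles,
                          consistency_models=reports, manifest=manifest)


def _trips_table(trips, morph) -> pd.DataFrame:
    rows = []
    for tr in trips:
        m = tr.dive_metrics
        horiz = tr.total_distance_km - sum(d.vertical_distance for d in tr.dives) / 1000.0
        rows.append({
            "trip_id": tr.trip_id, "individual_id": tr.individual_id,
            "start": iso8601([tr.start])[0], "end": iso8601([tr.end])[0],
            "duration_h": tr.duration_h,
            "total_distance_km": tr.total_distance_km,
            "horizontal_distance_km": horiz,
            "max_range_km": tr.max_range_km,
            "bearing_distal": tr.bearing_distal,
            "n_dives": m.n_dives, "prop_benthic": m.prop_benthic,
            "prop_daylight": m.prop_daylight, "dive_rate": m.dive_rate,
            "modal_depth": m.modal_depth,
            "ftsi": getattr(tr, "ftsi", np.nan), "ftei": getattr(tr, "ftei", np.nan),
        })
    columns = ["trip_id", "individual_id", "start", "end", "duration_h",
               "total_distance_km", "horizontal_distance_km", "max_range_km",
               "bearing_distal", "n_dives", "prop_benthic", "prop_daylight",
               "dive_rate", "modal_depth", "ftsi", "ftei"]
    df = pd.DataFrame(rows, columns=columns if not rows else None)
    if len(df) and morph is not None and len(morph):
        df = df.merge(morph, on="individual_id", how="left")
    return df


def _dives_table(trips, kept_trips: pd.DataFrame) -> pd.DataFrame:
    keep_ids = set(kept_trips["trip_id"]) if len(kept_trips) else set()
    rows = []
    for tr in trips:
        if tr.trip_id not in keep_ids:
            continue
        for d in tr.dives:
            rows.append({
                "individual_id": d.individual_id, "trip_id": tr.trip_id,
                "start": iso8601([d.start])[0], "duration_s": d.duration,
                "max_depth_m": d.max_depth, "bottom_time_s": d.bottom_time,
                "descent_rate_ms": d.descent_rate,
                "vertical_distance_m": d.vertical_distance,
                "is_daylight": d.is_daylight, "benthic_index": d.benthic_index,
                "is_benthic": d.is_benthic,
                "capture_probability": d.capture_probability,
            })
    return pd.DataFrame(rows)


def _fidelity_table(trips, kept: pd.DataFrame, proj, cfg) -> pd.DataFrame:
    keep_ids = set(kept["trip_id"]) if len(kept) else set()
    by_ind: dict[str, list] = {}
    for tr in trips:
        if tr.trip_id in keep_ids:
            by_ind.setdefault(tr.individual_id, []).append(tr)
    rows = []
    for iid, ind_trips in sorted(by_ind.items()):
        if len(ind_trips) < 2:
            continue
        res = fid.fsfi(ind_trips, proj, cfg.grid_cell_km * 1000.0, cfg.isopleth)
        rows.append({"individual_id": iid, "n_trips": len(ind_trips),
                     "fsfi": res.fsfi})
    return pd.DataFrame(rows, columns=["individual_id", "n_trips", "fsfi"])


def _repeatability_table(kept: pd.DataFrame, morph, cfg, manifest) -> pd.DataFrame:
    have_morph = morph is not None and len(morph) and \
        all(c in kept.columns for c in MORPH_COLUMNS)
    if have_morph:
        covars = rpt.screen_collinearity(
            kept[list(MORPH_COLUMNS)].drop_duplicates(), cfg.collinearity_r)
    else:
        covars = []
        manifest.warn("no morphometrics; unadjusted repeatability only")
    rows = []
    rng_seed = cfg.seed
    for beh, transform in GAUSSIAN_BEHAVIORS.items():
        res = rpt.repeatability_gaussian(
            kept, beh, covariates=covars, transform=transform,
            n_permutations=cfg.n_permutations, n_bootstrap=cfg.n_bootstrap,
            seed=rng_seed)
        rows.append(_rep_row(res))
        rng_seed += 1
    for beh in PROPORTION_BEHAVIORS:
        res = rpt.repeatability_proportion(kept, beh, denominator="n_dives",
                                           covariates=covars, seed=rng_seed)
        rows.append(_rep_row(res))
        rng_seed += 1
    return pd.DataFrame(rows)


def _rep_row(res) -> dict:
    return {"behavior": res.behavior, "kind": res.kind,
            "covariates": "+".join(res.covariates) or "1",
            "adjusted": res.adjusted, "sigma_alpha2": res.sigma_alpha2,
            "sigma_eps2": res.sigma_eps2, "r": res.r,
            "r_individual": res.r_individual, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p_perm": res.p_perm, "band": res.band,
            "n_obs": res.n_obs, "n_individuals": res.n_individuals}


def _consistency(kept: pd.DataFrame, fidelity_df: pd.DataFrame, manifest):
    profiles = []
    fsfi_map = dict(zip(fidelity_df.get("individual_id", []),
                        fidelity_df.get("fsfi", [])))
    for iid, sub in kept.groupby("individual_id"):
        if len(sub) < 3 or iid not in fsfi_map:
            continue
        profiles.append(consistency.consistency_profile(sub, fsfi_map[iid], iid))
    prof_df = pd.DataFrame(profiles)
    if len(prof_df) < 10:
        manifest.warn(f"{len(prof_df)} complete profiles < 10; "
                      "consistency models skipped")
        return prof_df, {}
    reports = consistency.fit_consistency_models(prof_df)
    return prof_df, reports
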