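"""Readers and writers for the fixture CSV schemas.

All timestamps on disk are ISO8601 UTC; in memory they are POSIX
seconds.  Readers validate columns, reject malformed rows with the
offending row number, sort by time and refuse duplicated timestamps.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dives import DepthSeries, infer_sample_interval
from .simulate import MORPH_COLUMNS
from .tracks import GpsTrack


def _parse_times(raw: pd.Series, path) -> np.ndarray:
    ts = pd.to_datetime(raw, errors="coerce", utc=True, format="ISO8601")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        raise ValueError(f"{path}: malformed timestamp at data row {bad[0] + 1}")
    return (ts.astype("int64") // 10 ** 9).to_numpy(dtype=float)


def _parse_numeric(raw: pd.Series, name: str, path) -> np.ndarray:
    vals = pd.to_numeric(raw, errors="coerce")
    bad = np.flatnonzero(vals.isna().to_numpy())
    if bad.size:
        raise ValueError(f"{path}: malformed {name} at data row {bad[0] + 1}")
    # re-parse via float() for a correctly-rounded (round-trip exact) result
    return raw.to_numpy(dtype="U32").astype(np.float64)


def _require(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_gps(path) -> GpsTrack:
    """Read one individual's GPS fixes."""
    df = pd.read_csv(path, dtype=str)
    _require(df, ("individual_id", "timestamp_iso8601", "lon", "lat"), path)
    t = _parse_times(df["timestamp_iso8601"], path)
    lon = _parse_numeric(df["lon"], "lon", path)
    lat = _parse_numeric(df["lat"], "lat", path)
    order = np.argsort(t, kind="stable")
    t, lon, lat = t[order], lon[order], lat[order]
    if np.any(np.diff(t) == 0):
        i = int(np.flatnonzero(np.diff(t) == 0)[0])
        raise ValueError(f"{path}: duplicated timestamp at data row {i + 1}")
    return GpsTrack(str(df["individual_id"].iloc[0]), t, lon, lat)


def read_depth(path) -> DepthSeries:
    """Read one individual's depth record; the 1 s or 5 s sampling
    interval is auto-detected from the median spacing."""
    df = pd.read_csv(path, dtype=str)
    _require(df, ("individual_id", "timestamp_iso8601", "depth_m"), path)
    t = _parse_times(df["timestamp_iso8601"], path)
    d = _parse_numeric(df["depth_m"], "depth_m", path)
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    if np.any(np.diff(t) == 0):
        i = int(np.flatnonzero(np.diff(t) == 0)[0])
        raise ValueError(f"{path}: duplicated timestamp at data row {i + 1}")
    return DepthSeries(str(df["individual_id"].iloc[0]), t, d,
                       infer_sample_interval(t))


def read_morphometrics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ("individual_id",) + MORPH_COLUMNS, path)
    return df


def load_fixture_dir(directory) -> tuple[dict, dict, pd.DataFrame]:
    """Load every gps_*/depth_* pair plus morphometrics from a directory."""
    directory = Path(directory)
    gps = {}
    depth = {}
    for p in sorted(directory.glob("gps_*.csv")):
        tr = read_gps(p)
        gps[tr.individual_id] = tr
    for p in sorted(directory.glob("depth_*.csv")):
        se = read_depth(p)
        depth[se.individual_id] = se
    morph_path = directory / "morphometrics.csv"
    morph = read_morphometrics(morph_path) if morph_path.exists() else pd.DataFrame(
        columns=["individual_id", *MORPH_COLUMNS])
    return gps, depth, morph


def iso8601(t) -> pd.Series:
    return pd.to_datetime(np.asarray(t).astype("int64"), unit="s", utc=True) \
        .strftime("%Y-%m-%dT%H:%M:%SZ")
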