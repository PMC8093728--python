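"""Pipeline configuration: every analysis threshold in one place.

Defaults are the method's standard constants (5 m dive threshold,
6 m s^-1 speed filter, 10 s interpolation, 1 km buffers and grid cells,
6 h minimum trip, 10 min haul-out rule, 07:00-18:00 local daylight,
95% isopleth, |r| > 0.7 collinearity cut, delta-AICc < 4).  Overrides
are recorded in the run manifest.  Configs serialize to flat YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .indices import CaptureModel


@dataclass
class PipelineConfig:
    data_dir: str = "fixtures"
    out_dir: str = "output"
    colony_lon: float = 146.30
    colony_lat: float = -39.155
    utc_offset_hours: float = 10.0

    dive_threshold_m: float = 5.0
    zoc_window_s: float = 1800.0
    zoc_quantile: float = 0.05
    bottom_phase_fraction: float = 0.8

    speed_vmax_ms: float = 6.0
    interp_step_s: float = 10.0
    buffer_km: float = 1.0
    trip_min_hours: float = 6.0
    haulout_min_dry_min: float = 10.0
    haulout_sites: list = field(default_factory=list)  # [[lon, lat], ...]

    daylight_start_h: float = 7.0
    daylight_end_h: float = 18.0

    grid_cell_km: float = 1.0
    isopleth: float = 0.95
    min_dives_for_split: int = 30

    capture_intercept: float = -1.0
    capture_coef_descent_rate: float = 1.2
    capture_coef_duration: float = 0.004

    collinearity_r: float = 0.7
    delta_aicc: float = 4.0
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    min_trips_per_individual: int = 3
    seed: int = 1

    @property
    def colony(self) -> tuple[float, float]:
        return (self.colony_lon, self.colony_lat)

    @property
    def daylight_window(self) -> tuple[float, float]:
        return (self.daylight_start_h, self.daylight_end_h)

    def capture_model(self) -> CaptureModel:
        return CaptureModel(self.capture_intercept,
                            self.capture_coef_descent_rate,
                            self.capture_coef_duration)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def overrides(self) -> dict:
        """Fields differing from the documented defaults."""
        ref = PipelineConfig()
        return {f.name: getattr(self, f.name) for f in fields(self)
                if getattr(self, f.name) != getattr(ref, f.name)}

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
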