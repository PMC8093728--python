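"""Benthic foraging success and efficiency indices.

A logistic model maps each benthic dive's descent rate and duration to a
prey-capture probability (the relationship is validated externally with
animal-borne video; the default coefficients shipped here are synthetic
placeholders and are flagged as such — supply calibrated coefficients
for real inference).  Per trip:

    FTSI = sum(p_i) / sum(benthic dive duration, h)      [h^-1]
    FTEI = sum(p_i) / benthic dive rate                  [per (m h^-1)]

where the benthic dive rate is the summed vertical distance of benthic
dives (2 x max depth each) divided by the time at sea.  Only benthic
dives enter either index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .dives import Dive


@dataclass
class CaptureModel:
    """Logistic prey-capture model: logit(p) = b0 + b_dr * descent_rate +
    b_dur * duration."""

    intercept: float = -1.0
    coef_descent_rate: float = 1.2   # per m s^-1
    coef_duration: float = 0.004     # per s
    provenance: str = "synthetic placeholder — not video-validated"


@dataclass
class TripIndices:
    ftsi: float
    ftei: float
    n_benthic: int
    sum_capture_prob: float


def capture_probability(dive: Dive, model: CaptureModel) -> float:
    """Predicted prey-capture probability for one *benthic* dive."""
    if dive.is_benthic is not True:
        raise ValueError("capture probability applies to benthic dives only")
    eta = (model.intercept
           + model.coef_descent_rate * dive.descent_rate
           + model.coef_duration * dive.duration)
    p = float(expit(eta))
    dive.capture_probability = p
    return p


def trip_indices(dives: list[Dive], model: CaptureModel,
                 time_at_sea_h: float) -> TripIndices:
    """FTSI and FTEI for one trip from its benthic dives."""
    benthic = [d for d in dives if d.is_benthic]
    if not benthic:
        raise ValueError("trip has no benthic dives")
    if time_at_sea_h <= 0:
        raise ValueError("non-positive time at sea")
    p = np.array([capture_probability(d, model) for d in benthic])
    dur_h = np.array([d.duration for d in benthic]) / 3600.0
    ftsi = float(p.sum() / dur_h.sum())
    benthic_dive_rate = float(sum(2.0 * d.max_depth for d in benthic) / time_at_sea_h)
    ftei = float(p.sum() / benthic_dive_rate)
    return TripIndices(ftsi=ftsi, ftei=ftei, n_benthic=len(benthic),
                       sum_capture_prob=float(p.sum()))
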