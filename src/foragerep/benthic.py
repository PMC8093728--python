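"""Benthic vs pelagic dive classification.

Each dive gets an index equal to its maximum depth weighted by the
proportion of the dive spent in the bottom phase:

    index = max_depth * bottom_time / duration

For a predominantly benthic diver over a fairly flat shelf the index is
bimodal: a deep, long-bottom mode (benthic, on/near the seafloor) and a
shallow, short-bottom mode (pelagic).  A Gaussian kernel density is
fitted to each individual's indices, the two highest local maxima are
taken as the modes, and the density minimum (nadir) between them splits
the dives: left of the nadir -> pelagic, right (and ties) -> benthic.
The fit is per individual because the modes are relative to the rest of
that individual's diving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .dives import Dive


@dataclass
class BenthicIndexModel:
    """Fitted density split of the bottom-weighted depth index."""

    bandwidth: float
    grid: np.ndarray          # index values the density was evaluated on
    density: np.ndarray
    peaks: tuple              # index values of the two selected modes (or one)
    nadir: float | None       # None when the density is unimodal
    unimodal_fallback: bool
    labels: np.ndarray        # True = benthic, aligned with the input indices


def benthic_index(dive: Dive) -> float:
    """Bottom-time-weighted maximum depth of one dive."""
    if dive.duration <= 0:
        raise ValueError("zero-duration dive")
    return dive.max_depth * (dive.bottom_time / dive.duration)


def fit_split(indices: np.ndarray, min_dives: int = 30,
              grid_size: int = 512, fallback_bottom_fraction: float | None = None,
              ) -> BenthicIndexModel:
    """Fit the per-individual kernel density and label dives by nadir side.

    Parameters
    ----------
    indices : array of the per-dive benthic index for one individual.
    min_dives : minimum sample size for a meaningful density fit.
    fallback_bottom_fraction : mean bottom-time fraction of the dives,
        used only if the density has no interior minimum: the single mode
        is then called benthic when this fraction is >= 0.4, else pelagic.

    Silverman's rule sets the bandwidth; with it, labels are exactly
    invariant to positive affine rescaling of the index.
    """
    x = np.asarray(indices, dtype=float)
    if x.size < min_dives:
        raise ValueError(f"need >= {min_dives} dives to fit the density split")
    if np.ptp(x) < 1e-12:
        return _fallback(x, fallback_bottom_fraction)
    kde = gaussian_kde(x, bw_method="silverman")
    bw = float(kde.factor * x.std(ddof=1))
    pad = 3.0 * bw
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    dens = kde(grid)
    interior = np.flatnonzero((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])) + 1
    if interior.size < 2:
        m = _fallback(x, fallback_bottom_fraction)
        m.bandwidth, m.grid, m.density = bw, grid, dens
        return m
    top2 = interior[np.argsort(dens[interior])][-2:]
    lo, hi = sorted(grid[top2])
    between = (grid > lo) & (grid < hi)
    nadir = float(grid[between][np.argmin(dens[between])])
    labels = x >= nadir  # ties -> benthic
    return BenthicIndexModel(bandwidth=bw, grid=grid, density=dens,
                             peaks=(float(lo), float(hi)), nadir=nadir,
                             unimodal_fallback=False, labels=labels)


def _fallback(x: np.ndarray, mean_bottom_fraction: float | None) -> BenthicIndexModel:
    """Unimodal/degenerate density: the split is undefined, so label the
    whole mode by its character — benthic when the dives are long-bottomed
    (mean bottom fraction >= 0.4), else pelagic."""
    benthic = bool(mean_bottom_fraction is not None and mean_bottom_fraction >= 0.4)
    return BenthicIndexModel(bandwidth=float("nan"), grid=np.empty(0),
                             density=np.empty(0), peaks=(float(np.median(x)),),
                             nadir=None, unimodal_fallback=True,
                             labels=np.full(x.size, benthic))


def classify_dives(dives: list[Dive], min_dives: int = 30) -> BenthicIndexModel:
    """Compute the index for, and label, one individual's dives in place."""
    idx = np.array([benthic_index(d) for d in dives])
    mbf = float(np.mean([d.bottom_time / d.duration for d in dives])) if dives else None
    model = fit_split(idx, min_dives=min_dives, fallback_bottom_fraction=mbf)
    for d, v, lab in zip(dives, idx, model.labels):
        d.benthic_index = float(v)
        d.is_benthic = bool(lab)
    return model
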