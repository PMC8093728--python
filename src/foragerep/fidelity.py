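"""Foraging site fidelity from dive-time utilization distributions.

For each trip, the time spent diving is accumulated on a 1 x 1 km grid
(shared by all trips and individuals, anchored at the colony), smoothed
with a bivariate Gaussian kernel (reference "href" bandwidth) into a
utilization distribution (UD), and truncated to the smallest set of
cells holding 95% of the mass.  Overlap between two trips is
Bhattacharyya's affinity BA = sum_cells sqrt(p_i * q_i) in [0, 1]; the
Foraging Site Fidelity Index (FSFI) of an individual is the mean BA over
all unordered pairs of its trips — 0 means no overlap between foraging
areas, 1 complete overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .tracks import Trip, join_dives_to_fixes
from .geo import LocalProjection


@dataclass
class UtilizationDistribution:
    """Discrete UD on the shared analysis grid.

    ``cells`` maps (ix, iy) grid indices (cell [ix*s, (ix+1)*s) x
    [iy*s, (iy+1)*s) in the projected plane, s = cell size) to cell
    probabilities, which sum to 1 after 95% truncation + renormalization.
    """

    cell_size_m: float
    cells: dict
    bandwidth_m: float

    def prob_array(self, keys):
        return np.array([self.cells.get(k, 0.0) for k in keys])


@dataclass
class FidelityResult:
    individual_id: str
    trip_ids: list
    ba: np.ndarray      # symmetric pairwise Bhattacharyya affinity, diag 1
    fsfi: float


def dive_time_grid(trip: Trip, proj: LocalProjection, cell_size_m: float = 1000.0) -> dict:
    """Seconds spent diving per grid cell: each dive's duration is added
    to the cell containing its joined (nearest-in-time) fix."""
    if not trip.dives:
        raise ValueError("trip has no dives")
    idx = join_dives_to_fixes(trip)
    x, y = proj.forward(trip.lon[idx], trip.lat[idx])
    ix = np.floor(np.atleast_1d(x) / cell_size_m).astype(int)
    iy = np.floor(np.atleast_1d(y) / cell_size_m).astype(int)
    out: dict = {}
    for d, i, j in zip(trip.dives, ix, iy):
        key = (int(i), int(j))
        out[key] = out.get(key, 0.0) + d.duration
    return out


def href_bandwidth(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted reference bandwidth: sigma_hat * n_eff^(-1/6) with
    sigma_hat = sqrt((var(x)+var(y))/2) (dive-time-weighted variances) and
    n_eff = (sum w)^2 / sum w^2."""
    w = w / w.sum()
    vx = float(np.sum(w * (x - np.sum(w * x)) ** 2))
    vy = float(np.sum(w * (y - np.sum(w * y)) ** 2))
    n_eff = 1.0 / float(np.sum(w ** 2))
    sigma = np.sqrt(0.5 * (vx + vy))
    return float(sigma * n_eff ** (-1.0 / 6.0))


def kde_ud(time_grid: dict, cell_size_m: float = 1000.0,
           isopleth: float = 0.95) -> UtilizationDistribution:
    """Kernel utilization distribution of dive time on the 1 km grid.

    A bivariate Gaussian kernel with the (weighted) href bandwidth is
    placed at each occupied cell centre, weighted by its dive time, and
    evaluated at cell centres over the occupied extent padded by three
    bandwidths.  The result is truncated to the smallest cell set holding
    >= ``isopleth`` of the mass and renormalized.
    """
    if not time_grid:
        raise ValueError("no dive time on the grid")
    keys = np.array(list(time_grid.keys()), dtype=int)
    w = np.array([time_grid[tuple(k)] for k in keys], dtype=float)
    if w.sum() <= 0:
        raise ValueError("zero total dive time")
    cx = (keys[:, 0] + 0.5) * cell_size_m
    cy = (keys[:, 1] + 0.5) * cell_size_m
    if len(keys) == 1:
        return UtilizationDistribution(cell_size_m, {tuple(keys[0]): 1.0}, 0.0)
    h = href_bandwidth(cx, cy, w)
    if h <= 0:
        # all mass effectively at one point
        top = tuple(keys[np.argmax(w)])
        return UtilizationDistribution(cell_size_m, {top: 1.0}, 0.0)
    pad = int(np.ceil(3.0 * h / cell_size_m)) + 1
    ix_range = np.arange(keys[:, 0].min() - pad, keys[:, 0].max() + pad + 1)
    iy_range = np.arange(keys[:, 1].min() - pad, keys[:, 1].max() + pad + 1)
    gx = (ix_range + 0.5) * cell_size_m
    gy = (iy_range + 0.5) * cell_size_m
    # density at cell centres: sum of isotropic Gaussians (separable per source)
    dx = (gx[None, :] - cx[:, None]) / h
    dy = (gy[None, :] - cy[:, None]) / h
    kx = np.exp(-0.5 * dx ** 2)
    ky = np.exp(-0.5 * dy ** 2)
    dens = np.einsum("s,sx,sy->xy", w, kx, ky)
    p = dens / dens.sum()
    # 95% truncation: smallest cell set reaching the isopleth mass
    flat = p.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    n_keep = int(np.searchsorted(csum, isopleth) + 1)
    keep = order[:n_keep]
    mass = flat[keep].sum()
    cells = {}
    nx, ny = p.shape
    for k in keep:
        i, j = divmod(int(k), ny)
        cells[(int(ix_range[i]), int(iy_range[j]))] = float(flat[k] / mass)
    return UtilizationDistribution(cell_size_m, cells, h)


def bhattacharyya(ud1: UtilizationDistribution, ud2: UtilizationDistribution,
                  atol: float = 1e-6) -> float:
    """Bhattacharyya affinity sum sqrt(p_i q_i) over the union of cells."""
    for ud in (ud1, ud2):
        total = sum(ud.cells.values())
        if abs(total - 1.0) > atol:
            raise ValueError(f"UD not normalized (mass {total:.6f})")
    common = set(ud1.cells) & set(ud2.cells)
    return float(sum(np.sqrt(ud1.cells[k] * ud2.cells[k]) for k in common))


def fsfi(trips: list[Trip], proj: LocalProjection, cell_size_m: float = 1000.0,
         isopleth: float = 0.95) -> FidelityResult:
    """Foraging Site Fidelity Index for one individual's trips.

    Builds each trip's dive-time UD, computes BA for every unordered trip
    pair and averages.  Requires at least two trips.
    """
    if len(trips) < 2:
        raise ValueError("FSFI needs at least two trips")
    uds = [kde_ud(dive_time_grid(tr, proj, cell_size_m), cell_size_m, isopleth)
           for tr in trips]
    n = len(uds)
    ba = np.eye(n)
    for i, j in combinations(range(n), 2):
        ba[i, j] = ba[j, i] = bhattacharyya(uds[i], uds[j])
    iu = np.triu_indices(n, 1)
    return FidelityResult(
        individual_id=trips[0].individual_id,
        trip_ids=[tr.trip_id for tr in trips],
        ba=ba,
        fsfi=float(ba[iu].mean()),
    )
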