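"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by the most direct method
available (linear scans, direct sums, closed forms) and never share code
with the implementation they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_dive_runs(depth: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """All maximal runs of depth >= threshold, as (start, end) index pairs,
    found by a plain linear scan."""
    runs = []
    start = None
    for i, d in enumerate(depth):
        if d >= threshold and start is None:
            start = i
        elif d < threshold and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(depth) - 1))
    return runs


def direct_bhattacharyya(p: dict, q: dict) -> float:
    """BA by direct summation over the union of keys."""
    total = 0.0
    for k in set(p) | set(q):
        total += np.sqrt(p.get(k, 0.0) * q.get(k, 0.0))
    return float(total)


def hand_cv(values) -> float:
    v = np.asarray(values, dtype=float)
    return float(np.sqrt(np.sum((v - v.mean()) ** 2) / (len(v) - 1)) / v.mean())


def hand_circular_sd_deg(bearings_deg) -> float:
    a = np.radians(np.asarray(bearings_deg, dtype=float))
    c = np.mean(np.cos(a))
    s = np.mean(np.sin(a))
    rbar = np.sqrt(c * c + s * s)
    return float(np.degrees(np.sqrt(-2.0 * np.log(min(rbar, 1.0)))))


def forward_speed_scan(t, lon, lat, vmax, dist_fn) -> list[int]:
    """Forward single-pass speed filter, kept as an explicit index loop."""
    keep = [0]
    for i in range(1, len(t)):
        j = keep[-1]
        if dist_fn(lon[j], lat[j], lon[i], lat[i]) / (t[i] - t[j]) <= vmax:
            keep.append(i)
    return keep


def trapezoid_depth_trace(max_depth: float, descent_s: float, bottom_s: float,
                          ascent_s: float, interval: float,
                          lead_s: float = 60.0, tail_s: float = 60.0,
                          t0: float = 0.0):
    """A single trapezoidal dive embedded in a surface trace."""
    total = lead_s + descent_s + bottom_s + ascent_s + tail_s
    t = t0 + np.arange(0.0, total + interval / 2, interval)
    knots_t = [t0, t0 + lead_s, t0 + lead_s + descent_s,
               t0 + lead_s + descent_s + bottom_s,
               t0 + lead_s + descent_s + bottom_s + ascent_s, t0 + total]
    knots_d = [0.0, 0.0, max_depth, max_depth, 0.0, 0.0]
    return t, np.interp(t, knots_t, knots_d)
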