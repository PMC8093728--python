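"""Quick-look plots for pipeline outputs (matplotlib, lazy-imported)."""

from __future__ import annotations

import numpy as np


def plot_trip(trip, proj, ax=None):
    """Trip track in projected km with dive positions marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    x, y = proj.forward(trip.lon, trip.lat)
    ax.plot(np.asarray(x) / 1000, np.asarray(y) / 1000, lw=0.7, color="0.4")
    if trip.dives:
        from .tracks import join_dives_to_fixes
        idx = join_dives_to_fixes(trip)
        dx, dy = proj.forward(trip.lon[idx], trip.lat[idx])
        ax.scatter(np.asarray(dx) / 1000, np.asarray(dy) / 1000, s=4,
                   color="tab:blue", label="dives")
    ax.plot(0, 0, "k^", ms=8, label="colony")
    ax.set_xlabel("east of colony (km)")
    ax.set_ylabel("north of colony (km)")
    ax.set_title(trip.trip_id)
    ax.set_aspect("equal")
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_ud(ud, ax=None):
    """Utilization distribution as a cell heat map (probability per cell)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    keys = np.array(list(ud.cells.keys()))
    vals = np.array(list(ud.cells.values()))
    s = ud.cell_size_m / 1000.0
    ax.scatter(keys[:, 0] * s, keys[:, 1] * s, c=vals, s=12, marker="s",
               cmap="viridis")
    ax.set_xlabel("east of colony (km)")
    ax.set_ylabel("north of colony (km)")
    ax.set_aspect("equal")
    return ax


def plot_repeatability(repeatability_df, ax=None):
    """Point estimates with bootstrap CIs, one row per behaviour."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    df = repeatability_df.reset_index(drop=True)
    y = np.arange(len(df))
    ax.scatter(df["r"], y, color="tab:blue", zorder=3)
    for i, row in df.iterrows():
        if row.get("ci_low") == row.get("ci_low"):  # not NaN
            ax.plot([row["ci_low"], row["ci_high"]], [i, i], color="0.5")
    ax.set_yticks(y, df["behavior"])
    ax.set_xlabel("repeatability R")
    ax.set_xlim(0, 1)
    ax.axvline(0.25, ls=":", color="0.8")
    ax.axvline(0.5, ls=":", color="0.8")
    ax.axvline(0.75, ls=":", color="0.8")
    return ax
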