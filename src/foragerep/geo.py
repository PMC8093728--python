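"""Spherical geometry helpers: great-circle distance/bearing and a local
azimuthal-equidistant projection.

All track processing is done in a local azimuthal-equidistant (AEQ) plane
centred on the breeding colony: distances from the centre are exact and
directions are preserved, which is what matters for buffer tests, linear
interpolation and the 1 km analysis grid within a few hundred km of the
colony.  Ranges and bearings reported to the user are computed on the
sphere directly.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres between WGS84 points (degrees)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2, degrees
    clockwise from true north in [0, 360)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    x = np.sin(dlon) * np.cos(lat2)
    y = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(x, y)) % 360.0


class LocalProjection:
    """Azimuthal-equidistant projection centred on (lon0, lat0), metres."""

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._lam0 = np.radians(self.lon0)
        self._phi0 = np.radians(self.lat0)

    def forward(self, lon, lat):
        """(lon, lat) degrees -> (x, y) metres; east/north of the centre."""
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        dlam = lam - self._lam0
        cos_c = np.sin(self._phi0) * np.sin(phi) + np.cos(self._phi0) * np.cos(phi) * np.cos(dlam)
        c = np.arccos(np.clip(cos_c, -1.0, 1.0))
        az_x = np.sin(dlam) * np.cos(phi)
        az_y = np.cos(self._phi0) * np.sin(phi) - np.sin(self._phi0) * np.cos(phi) * np.cos(dlam)
        az = np.arctan2(az_x, az_y)
        rho = EARTH_RADIUS_M * c
        return rho * np.sin(az), rho * np.cos(az)

    def inverse(self, x, y):
        """(x, y) metres -> (lon, lat) degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.hypot(x, y)
        c = rho / EARTH_RADIUS_M
        sin_c, cos_c = np.sin(c), np.cos(c)
        # avoid 0/0 at the projection centre
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.arcsin(np.clip(cos_c * np.sin(self._phi0) + np.where(rho > 0, y * sin_c * np.cos(self._phi0) / np.where(rho > 0, rho, 1.0), 0.0), -1.0, 1.0))
            lam = self._lam0 + np.arctan2(x * sin_c, rho * cos_c * np.cos(self._phi0) - y * sin_c * np.sin(self._phi0))
        lon = np.degrees(np.where(rho > 0, lam, self._lam0))
        lat = np.degrees(np.where(rho > 0, phi, self._phi0))
        return lon, lat
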