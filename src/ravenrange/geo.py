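"""Planar projection and geodesic distance helpers.

All spatial computation in this package happens on a local metric plane:
coordinates are projected with a spherical azimuthal-equidistant (AEQD)
projection centred on the data centroid.  At the scale of an Alpine study
area (tens of kilometres) the AEQD distortion is negligible relative to GPS
location error, and forward/inverse transforms are closed-form, which keeps
simulated ground-truth distances exact.

Distances between fixes (displacement metrics) use the haversine great-circle
formula on the same sphere, so projected and geodesic geometry agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Mean Earth radius (IUGG), metres.
EARTH_RADIUS_M = 6_371_008.8


@dataclass(frozen=True)
class LocalProjection:
    """Azimuthal-equidistant projection about a reference lon/lat (degrees)."""

    lon0: float
    lat0: float
    radius: float = EARTH_RADIUS_M

    def forward(self, lon, lat):
        """Project lon/lat degrees to local (x, y) metres."""
        lam0, phi0 = np.radians(self.lon0), np.radians(self.lat0)
        lam, phi = np.radians(np.asarray(lon, float)), np.radians(np.asarray(lat, float))
        dlam = lam - lam0
        cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        # k = c / sin(c), -> 1 as c -> 0
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = self.radius * k * np.cos(phi) * np.sin(dlam)
        y = self.radius * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam))
        return x, y

    def inverse(self, x, y):
        """Back-project local (x, y) metres to lon/lat degrees."""
        lam0, phi0 = np.radians(self.lon0), np.radians(self.lat0)
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        rho = np.hypot(x, y)
        c = rho / self.radius
        sin_c, cos_c = np.sin(c), np.cos(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            safe_rho = np.where(rho > 1e-12, rho, 1.0)
            phi = np.arcsin(np.clip(cos_c * np.sin(phi0) + y * sin_c * np.cos(phi0) / safe_rho, -1.0, 1.0))
            lam = lam0 + np.arctan2(x * sin_c, safe_rho * np.cos(phi0) * cos_c - y * np.sin(phi0) * sin_c)
        phi = np.where(rho > 1e-12, phi, phi0)
        lam = np.where(rho > 1e-12, lam, lam0)
        return np.degrees(lam), np.degrees(phi)


def projection_for(lon, lat) -> LocalProjection:
    """Projection centred on the centroid of the given coordinates."""
    return LocalProjection(float(np.mean(lon)), float(np.mean(lat)))


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres between WGS84 points (degrees)."""
    lam1, phi1, lam2, phi2 = (np.radians(np.asarray(a, float)) for a in (lon1, lat1, lon2, lat2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
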