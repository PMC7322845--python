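"""Great-circle geometry primitives shared by every stage.

All distances use a spherical Earth of radius 6371 km; the matching
flat-earth conversion constant is ``KM_PER_DEGREE`` = 111.19 km per degree
of latitude (2*pi*6371/360), used wherever the pipeline converts a distance
into a grid-cell size.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidPointError

EARTH_RADIUS_KM = 6371.0
KM_PER_DEGREE = 111.19


def _validate(lon, lat) -> None:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if not (np.all(np.isfinite(lon)) and np.all(np.isfinite(lat))):
        raise InvalidPointError("non-finite coordinate")
    if np.any(np.abs(lon) > 360.0) or np.any(np.abs(lat) > 90.0):
        raise InvalidPointError("coordinate out of range")


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between (lon1, lat1) and (lon2, lat2).

    Accepts scalars or broadcastable arrays of degrees.
    """
    _validate(lon1, lat1)
    _validate(lon2, lat2)
    lam1, phi1, lam2, phi2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    return float(d) if np.ndim(d) == 0 else d


def initial_bearing_rad(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2, radians from north."""
    lam1, phi1, lam2, phi2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlam = lam2 - lam1
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    b = np.arctan2(y, x)
    return float(b) if np.ndim(b) == 0 else b


def destination(lon, lat, bearing_rad, dist_km):
    """Point reached from (lon, lat) travelling dist_km on a great circle."""
    phi1 = np.radians(np.asarray(lat, dtype=float))
    lam1 = np.radians(np.asarray(lon, dtype=float))
    delta = np.asarray(dist_km, dtype=float) / EARTH_RADIUS_KM
    phi2 = np.arcsin(np.sin(phi1) * np.cos(delta)
                     + np.cos(phi1) * np.sin(delta) * np.cos(bearing_rad))
    lam2 = lam1 + np.arctan2(np.sin(bearing_rad) * np.sin(delta) * np.cos(phi1),
                             np.cos(delta) - np.sin(phi1) * np.sin(phi2))
    lon2 = (np.degrees(lam2) + 540.0) % 360.0 - 180.0
    lat2 = np.degrees(phi2)
    if np.ndim(lon2) == 0:
        return float(lon2), float(lat2)
    return lon2, lat2


def pairwise_degree_distance(lon, lat):
    """Isotropic Euclidean distance matrix in degrees (kriging convention)."""
    pts = np.column_stack([np.asarray(lon, float), np.asarray(lat, float)])
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))
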