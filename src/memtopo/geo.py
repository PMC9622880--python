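"""Great-circle geometry on a spherical Earth.

Memory locations are latitude/longitude pairs; every analysis that uses
"distance" means the geodesic distance from the memory's location to the
scanning site. A spherical (haversine) model with the IUGG mean Earth
radius is used throughout: at the precision of these analyses the
difference from an ellipsoidal geodesic (<0.5%) is negligible.
"""

from __future__ import annotations

import numpy as np

#: IUGG mean Earth radius, kilometres.
EARTH_RADIUS_KM: float = 6371.0088


def _check_coords(lat: np.ndarray, lon: np.ndarray) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError(f"latitude outside [-90, 90]: {lat[np.abs(lat) > 90]}")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError(f"longitude outside [-180, 180]: {lon[np.abs(lon) > 180]}")


def geodesic_km(lat1, lon1, lat2, lon2):
    """Haversine great-circle distance in kilometres.

    Accepts scalars or broadcastable arrays of coordinates in degrees.
    Symmetric, non-negative, and zero iff the two points coincide.
    """
    _check_coords(np.atleast_1d(lat1), np.atleast_1d(lon1))
    _check_coords(np.atleast_1d(lat2), np.atleast_1d(lon2))
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    if np.isscalar(lat1) and np.isscalar(lat2):
        return float(d)
    return d


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing (degrees clockwise from north) from
    point 1 toward point 2."""
    _check_coords(np.atleast_1d(lat1), np.atleast_1d(lon1))
    _check_coords(np.atleast_1d(lat2), np.atleast_1d(lon2))
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    if np.isscalar(lat1) and np.isscalar(lat2):
        return float(theta)
    return theta


def destination_point(lat, lon, bearing_deg, distance_km):
    """Point reached travelling ``distance_km`` along the great circle with
    the given initial bearing. Inverse of the haversine formula; used by the
    synthetic generator to place memories at controlled distances."""
    _check_coords(np.atleast_1d(lat), np.atleast_1d(lon))
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    theta = np.radians(bearing_deg)
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    lat2 = np.degrees(phi2)
    lon2 = (np.degrees(lam2) + 180.0) % 360.0 - 180.0
    if np.isscalar(lat) and np.isscalar(bearing_deg) and np.isscalar(distance_km):
        return float(lat2), float(lon2)
    return lat2, lon2
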