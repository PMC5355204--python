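"""Spherical geometry helpers: great-circle distance, turning angle, local projection.

All routines assume a spherical Earth of radius 6371.0 km and coordinates in
decimal degrees (WGS84 lon/lat treated as spherical).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def _check_lonlat(lon, lat) -> None:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lon) > 180.0) or np.any(np.abs(lat) > 90.0):
        raise ValueError("coordinates outside [-180,180] x [-90,90]")


def great_circle_km(lon1, lat1, lon2, lat2):
    """Great-circle (haversine) distance in km between points in degrees.

    Accepts scalars or broadcastable arrays. Symmetric, nonnegative, zero iff
    the points coincide.
    """
    _check_lonlat(lon1, lat1)
    _check_lonlat(lon2, lat2)
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    return d.item() if d.ndim == 0 else d


def _bearing_rad(lon1, lat1, lon2, lat2):
    """Initial bearing (radians, from north, clockwise) from point 1 to point 2."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.arctan2(y, x)


def turning_angle_deg(a, b, c):
    """Deviation at ``b`` from straight continuation of the leg a -> b, in degrees.

    Each point is a (lon, lat) pair in degrees. 0 means the track continues
    straight through ``b``; 180 means an exact back-track. Raises ValueError
    when ``a == b`` or ``b == c`` (the angle is undefined).
    """
    a = tuple(map(float, a))
    b = tuple(map(float, b))
    c = tuple(map(float, c))
    if a == b or b == c:
        raise ValueError("turning angle undefined for coincident points")
    brg_in = _bearing_rad(a[0], a[1], b[0], b[1])
    brg_out = _bearing_rad(b[0], b[1], c[0], c[1])
    diff = np.degrees(np.abs(brg_out - brg_in)) % 360.0
    return float(min(diff, 360.0 - diff))


def to_local_plane(lon, lat, lon0: float, lat0: float):
    """Project lon/lat (deg) to a local azimuthal-equidistant plane (km).

    The plane is centered at (lon0, lat0); x is east, y is north. Distances
    from the center are exact great-circle distances, which makes the
    projection suitable for km-scale bridge math on study areas spanning a
    few degrees.
    """
    _check_lonlat(lon, lat)
    lam, phi = np.radians(np.asarray(lon, float)), np.radians(np.asarray(lat, float))
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    cos_c = np.clip(cos_c, -1.0, 1.0)
    c = np.arccos(cos_c)
    # k = c / sin(c), with the removable singularity at c = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (np.cos(phi0) * np.sin(phi)
                               - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0))
    return x, y


def from_local_plane(x, y, lon0: float, lat0: float):
    """Inverse of :func:`to_local_plane` (km back to degrees)."""
    x = np.asarray(x, float) / EARTH_RADIUS_KM
    y = np.asarray(y, float) / EARTH_RADIUS_KM
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    c = np.hypot(x, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        safe_c = np.where(c > 1e-12, c, 1.0)
        phi = np.where(
            c > 1e-12,
            np.arcsin(np.clip(np.cos(safe_c) * np.sin(phi0)
                              + y * np.sin(safe_c) * np.cos(phi0) / safe_c, -1, 1)),
            phi0,
        )
        lam = np.where(
            c > 1e-12,
            lam0 + np.arctan2(x * np.sin(safe_c),
                              safe_c * np.cos(phi0) * np.cos(safe_c)
                              - y * np.sin(phi0) * np.sin(safe_c)),
            lam0,
        )
    return np.degrees(lam), np.degrees(phi)
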