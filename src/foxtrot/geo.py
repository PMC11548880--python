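"""Great-circle geometry on the sphere.

Distances, initial bearings, and destination points use a spherical Earth
with radius 6378.137 km (the WGS84 equatorial radius, matching the default
of the R ``geosphere`` routines these functions mirror). Ellipsoidal
geodesics differ by < 0.5 % at continental scales, which is negligible
relative to the day-to-day variation in the tracking data this package
analyses.

All functions accept scalars or numpy arrays (broadcast together);
coordinates are decimal degrees, latitudes in [-90, 90], longitudes in
[-180, 360).
"""

from __future__ import annotations

import numpy as np

#: Spherical Earth radius in kilometres.
EARTH_RADIUS_KM = 6378.137


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in kilometres between two points.

    Uses the haversine formula, which is numerically stable for small
    separations (unlike the spherical law of cosines).

    Parameters
    ----------
    lat1, lon1, lat2, lon2 : float or array_like
        Coordinates in decimal degrees.

    Returns
    -------
    float or ndarray
        Distance in km. Zero for coincident points.
    """
    phi1, lam1, phi2, lam2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    # clip guards tiny negative/overshoot from roundoff
    c = 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return EARTH_RADIUS_KM * c


def initial_bearing(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2.

    Parameters
    ----------
    lat1, lon1, lat2, lon2 : float or array_like
        Coordinates in decimal degrees.

    Returns
    -------
    float or ndarray
        Bearing in degrees clockwise from true north, in [0, 360).

    Raises
    ------
    ValueError
        If the two points coincide (scalar inputs only) — the bearing is
        undefined there.
    """
    if np.isscalar(lat1) and np.isscalar(lon1) and np.isscalar(lat2) and np.isscalar(lon2):
        if lat1 == lat2 and (lon1 - lon2) % 360.0 == 0.0:
            raise ValueError("initial bearing is undefined for coincident points")
    phi1, lam1, phi2, lam2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlam = lam2 - lam1
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    out = np.degrees(np.arctan2(y, x)) % 360.0
    # a tiny negative angle mod 360 rounds to exactly 360.0
    out = np.where(out == 360.0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def destination_point(lat, lon, bearing_deg, distance_km):
    """Destination reached travelling along a great circle.

    Parameters
    ----------
    lat, lon : float or array_like
        Start coordinates in decimal degrees.
    bearing_deg : float or array_like
        Initial bearing, degrees clockwise from north.
    distance_km : float or array_like
        Travel distance in km.

    Returns
    -------
    (lat, lon) : tuple of float or ndarray
        Destination coordinates in decimal degrees, longitude normalised
        to (-180, 180].
    """
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    theta = np.radians(bearing_deg)
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    sinphi2 = np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    phi2 = np.arcsin(np.clip(sinphi2, -1.0, 1.0))
    y = np.sin(theta) * np.sin(delta) * np.cos(phi1)
    x = np.cos(delta) - np.sin(phi1) * sinphi2
    lam2 = lam1 + np.arctan2(y, x)
    lon2 = (np.degrees(lam2) + 180.0) % 360.0 - 180.0
    lon2 = np.where(lon2 == -180.0, 180.0, lon2)
    out_lat = np.degrees(phi2)
    if np.isscalar(lat) and np.isscalar(distance_km) and np.isscalar(bearing_deg):
        return float(out_lat), float(lon2)
    return out_lat, lon2


def angular_difference(a_deg, b_deg):
    """Signed smallest rotation from direction ``a`` to direction ``b``.

    Returns degrees in (-180, 180]; positive means ``b`` lies clockwise of
    ``a``.
    """
    d = (np.asarray(b_deg, dtype=float) - np.asarray(a_deg, dtype=float)) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    if np.isscalar(a_deg) and np.isscalar(b_deg):
        return float(d)
    return d
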