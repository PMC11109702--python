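"""Great-circle geometry on household GPS coordinates.

All distances in the pipeline are straight-line (great-circle) displacements
between household coordinates, computed with the haversine formula on a
sphere of mean radius 6371.0088 km.  At HDSS scale (tens of kilometres) the
spherical approximation is within 0.5% of an ellipsoidal geodesic, which is
far below the 4 km short/long classification granularity.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def check_lonlat(lon, lat) -> None:
    """Raise ValueError if any coordinate is outside WGS84 bounds."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if not (np.all(np.isfinite(lon)) and np.all(np.isfinite(lat))):
        raise ValueError("non-finite coordinate")
    if np.any(np.abs(lon) > 180.0) or np.any(np.abs(lat) > 90.0):
        raise ValueError("coordinate outside WGS84 range")


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine distance in kilometres; accepts scalars or arrays.

    Symmetric, non-negative and exactly zero for identical points.
    """
    check_lonlat(lon1, lat1)
    check_lonlat(lon2, lat2)
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards rounding at antipodal/identical points
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def pairwise_km(lon, lat):
    """Dense n x n haversine matrix for small point sets."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
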