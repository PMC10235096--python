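"""Shared spherical-geometry helpers.

All distances use a spherical Earth of radius 6371 km; one degree of
latitude is then 111.1949 km. Longitude distances shrink with cos(lat).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0
EARTH_RADIUS_M = 6_371_000.0
#: metres per degree of latitude (and of longitude at the equator)
METERS_PER_DEGREE = np.pi * EARTH_RADIUS_M / 180.0

NAUTICAL_MILE_KM = 1.852


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def nautical_miles_to_km(nm: float) -> float:
    """Convert nautical miles to kilometres (1 nm = 1.852 km)."""
    return nm * NAUTICAL_MILE_KM
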