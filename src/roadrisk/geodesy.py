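"""Spherical geodesy primitives shared by the gridding and impact modules.

All distances, lengths and areas in this package are measured on a sphere of
authalic radius ``EARTH_RADIUS_KM`` (6371.0072 km, the radius whose sphere has
the same surface area as the WGS84 ellipsoid).  Polylines are interpreted as
straight lines in longitude/latitude space (the convention of the vector data
the pipeline ingests); their length is the great-circle length of a finely
densified version of that lon/lat path.
"""

from __future__ import annotations

import math

import numpy as np

#: Authalic Earth radius, km.
EARTH_RADIUS_KM = 6371.0072

#: Default densification step (degrees) when measuring lon/lat paths.
DENSIFY_STEP_DEG = 0.01


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or numpy arrays (broadcasting applies).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def densify_lonlat(coords: np.ndarray, max_step_deg: float = DENSIFY_STEP_DEG) -> np.ndarray:
    """Insert vertices along each lon/lat segment so no piece exceeds ``max_step_deg``.

    Interpolation is linear in lon/lat, matching the path convention above.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        return coords
    out = [coords[:1]]
    for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
        n = max(1, int(math.ceil(max(abs(x1 - x0), abs(y1 - y0)) / max_step_deg)))
        t = np.linspace(0.0, 1.0, n + 1)[1:]
        out.append(np.column_stack([x0 + t * (x1 - x0), y0 + t * (y1 - y0)]))
    return np.concatenate(out)


def path_length_km(coords, max_step_deg: float = DENSIFY_STEP_DEG) -> float:
    """Great-circle length (km) of a lon/lat polyline, densified before measuring."""
    c = densify_lonlat(np.asarray(coords, dtype=float), max_step_deg)
    if len(c) < 2:
        return 0.0
    d = haversine_km(c[:-1, 0], c[:-1, 1], c[1:, 0], c[1:, 1])
    return float(np.sum(d))


def spherical_band_area_km2(lat_south_deg: float, lat_north_deg: float, dlon_deg: float) -> float:
    """Area (km²) of the spherical quadrangle between two parallels over ``dlon_deg``.

    ``R² · Δλ · (sin φ_n − sin φ_s)`` — exact on the sphere.
    """
    dlam = math.radians(dlon_deg)
    return (
        EARTH_RADIUS_KM ** 2
        * dlam
        * (math.sin(math.radians(lat_north_deg)) - math.sin(math.radians(lat_south_deg)))
    )


# ---------------------------------------------------------------------------
# Local azimuthal equidistant projection (spherical), used for metric buffering.
# Distances from the projection center are exact; distortion elsewhere is
# second order in (distance / R), i.e. <0.1% within a few hundred km.
# ---------------------------------------------------------------------------


class AzimuthalEquidistant:
    """Spherical azimuthal equidistant projection centered at (lon0, lat0), km units."""

    def __init__(self, lon0_deg: float, lat0_deg: float):
        self.lon0 = math.radians(lon0_deg)
        self.lat0 = math.radians(lat0_deg)

    def forward(self, lon_deg, lat_deg):
        """Lon/lat degrees -> planar (x, y) km."""
        lon = np.radians(np.asarray(lon_deg, dtype=float))
        lat = np.radians(np.asarray(lat_deg, dtype=float))
        dlon = lon - self.lon0
        cos_c = np.sin(self.lat0) * np.sin(lat) + np.cos(self.lat0) * np.cos(lat) * np.cos(dlon)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        # k = c / sin(c), with the removable singularity at c = 0
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(dlon)
        y = EARTH_RADIUS_KM * k * (
            np.cos(self.lat0) * np.sin(lat) - np.sin(self.lat0) * np.cos(lat) * np.cos(dlon)
        )
        return x, y

    def inverse(self, x, y):
        """Planar (x, y) km -> lon/lat degrees."""
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        c = np.hypot(x, y)
        safe_c = np.where(c > 1e-12, c, 1.0)
        sin_c, cos_c = np.sin(c), np.cos(c)
        lat = np.arcsin(
            np.clip(cos_c * np.sin(self.lat0) + (y * sin_c * np.cos(self.lat0)) / safe_c, -1.0, 1.0)
        )
        lon = self.lon0 + np.arctan2(
            x * sin_c, safe_c * np.cos(self.lat0) * cos_c - y * np.sin(self.lat0) * sin_c
        )
        lon = np.where(c > 1e-12, lon, self.lon0)
        lat = np.where(c > 1e-12, lat, self.lat0)
        return np.degrees(lon), np.degrees(lat)


def crosses_antimeridian(coords) -> bool:
    """True if any lon/lat segment jumps more than 180° in longitude."""
    c = np.asarray(coords, dtype=float)
    if len(c) < 2:
        return False
    return bool(np.any(np.abs(np.diff(c[:, 0])) > 180.0))
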