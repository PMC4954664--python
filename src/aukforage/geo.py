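"""Spherical geometry helpers: great-circle distances, a local planar frame,
and minimal GeoJSON I/O.

All position data in this package travel as WGS84 longitude/latitude degrees.
Metric operations (speeds, kernel densities, polygon overlaps, distances to
ice) happen in a local azimuthal-equidistant frame centred on the breeding
colony, in kilometres.  At the ~150 km scale of a foraging range the spherical
azimuthal-equidistant projection distorts distances from the centre not at all
and other distances by well under 0.5%, which is ample for home-range work.
"""

from __future__ import annotations

import json
from typing import Iterable

import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2, radius: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


class LocalProjection:
    """Azimuthal-equidistant projection centred on (lon0, lat0), in km.

    ``forward`` maps lon/lat degrees to planar (x, y) km with x east and
    y north of the centre; ``inverse`` maps back.  Distances measured from
    the centre are exact great-circle distances by construction.
    """

    def __init__(self, lon0: float, lat0: float, radius: float = EARTH_RADIUS_KM):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self.radius = float(radius)
        self._lam0 = np.radians(self.lon0)
        self._phi0 = np.radians(self.lat0)

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        cos_c = (np.sin(self._phi0) * np.sin(phi)
                 + np.cos(self._phi0) * np.cos(phi) * np.cos(lam - self._lam0))
        c = np.arccos(np.clip(cos_c, -1.0, 1.0))
        # k = c / sin(c), with the removable singularity at the centre
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = self.radius * k * np.cos(phi) * np.sin(lam - self._lam0)
        y = self.radius * k * (np.cos(self._phi0) * np.sin(phi)
                               - np.sin(self._phi0) * np.cos(phi) * np.cos(lam - self._lam0))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / self.radius
        y = np.asarray(y, dtype=float) / self.radius
        c = np.hypot(x, y)
        safe_c = np.where(c > 1e-12, c, 1.0)
        sin_c, cos_c = np.sin(c), np.cos(c)
        phi = np.arcsin(np.clip(cos_c * np.sin(self._phi0)
                                + y * sin_c * np.cos(self._phi0) / safe_c, -1.0, 1.0))
        lam = self._lam0 + np.arctan2(x * sin_c,
                                      safe_c * np.cos(self._phi0) * cos_c
                                      - y * np.sin(self._phi0) * sin_c)
        lam = np.where(c > 1e-12, lam, self._lam0)
        phi = np.where(c > 1e-12, phi, self._phi0)
        return np.degrees(lam), np.degrees(phi)

    def project_geometry(self, geom: BaseGeometry) -> BaseGeometry:
        """Project a lon/lat shapely geometry vertex-wise into the local frame."""
        from shapely.ops import transform

        return transform(lambda lon, lat, z=None: self.forward(lon, lat), geom)

    def unproject_geometry(self, geom: BaseGeometry) -> BaseGeometry:
        from shapely.ops import transform

        return transform(lambda x, y, z=None: self.inverse(x, y), geom)


def read_geojson(path) -> list[tuple[BaseGeometry, dict]]:
    """Read a GeoJSON file; return a list of (geometry, properties) pairs."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        feats = gj["features"]
    elif gj.get("type") == "Feature":
        feats = [gj]
    else:  # bare geometry
        return [(shape(gj), {})]
    return [(shape(f["geometry"]), f.get("properties") or {}) for f in feats]


def write_geojson(path, geometries: Iterable[BaseGeometry],
                  properties: Iterable[dict] | None = None) -> None:
    geometries = list(geometries)
    if properties is None:
        properties = [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geometries, properties)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
        fh.write("\n")
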