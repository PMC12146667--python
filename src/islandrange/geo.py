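"""Local map projection and land geometry for island-scale receiver arrays.

Receiver arrays around a small island span a few tens of kilometres at
most, so all distance- and area-based analysis (kernel bandwidths in
metres, UD areas in km^2) is done in a local azimuthal-equidistant (AEQD)
frame centred on the island.  At this scale a spherical AEQD on the
Gaussian radius of curvature at the array centre is accurate to well
under 0.1% against ellipsoidal geodesics, which is far below any other
source of positional error in passive telemetry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import shape, mapping, Point
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as shapely_transform
from shapely.prepared import prep

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)


def gaussian_radius(lat_deg: float) -> float:
    """Gaussian mean radius of curvature sqrt(M*N) at a latitude (metres)."""
    phi = np.radians(lat_deg)
    e2 = WGS84_F * (2.0 - WGS84_F)
    s2 = np.sin(phi) ** 2
    n = WGS84_A / np.sqrt(1.0 - e2 * s2)          # prime-vertical radius
    m = WGS84_A * (1.0 - e2) / (1.0 - e2 * s2) ** 1.5  # meridional radius
    return float(np.sqrt(m * n))


def _geodesic_inverse(lon1, lat1, lon2, lat2, tol=1e-12, maxiter=100):
    """Vincenty inverse: distance (m) and forward azimuth (rad) on WGS84."""
    if lon1 == lon2 and lat1 == lat2:
        return 0.0, 0.0
    f = WGS84_F
    L = np.radians(lon2 - lon1)
    U1 = np.arctan((1 - f) * np.tan(np.radians(lat1)))
    U2 = np.arctan((1 - f) * np.tan(np.radians(lat2)))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)
    lam = L
    for _ in range(maxiter):
        sinlam, coslam = np.sin(lam), np.cos(lam)
        sin_sigma = np.sqrt(
            (cosU2 * sinlam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * coslam) ** 2
        )
        if sin_sigma == 0.0:
            return 0.0, 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * coslam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sinlam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        cos_2sm = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha if cos2_alpha > 0 else 0.0
        C = f / 16.0 * cos2_alpha * (4.0 + f * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * f * sin_alpha * (
            sigma + C * sin_sigma * (cos_2sm + C * cos_sigma * (-1.0 + 2.0 * cos_2sm**2))
        )
        if abs(lam - lam_prev) < tol:
            break
    u2 = cos2_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A_ = 1 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B_ = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    dsig = B_ * sin_sigma * (
        cos_2sm
        + B_ / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos_2sm**2)
            - B_ / 6.0 * cos_2sm * (-3.0 + 4.0 * sin_sigma**2) * (-3.0 + 4.0 * cos_2sm**2)
        )
    )
    s = WGS84_B * A_ * (sigma - dsig)
    az = np.arctan2(cosU2 * np.sin(lam), cosU1 * sinU2 - sinU1 * cosU2 * np.cos(lam))
    return float(s), float(az)


def _geodesic_direct(lon1, lat1, az, s, tol=1e-12, maxiter=100):
    """Vincenty direct: destination of a geodesic of length s (m), az (rad)."""
    if s == 0.0:
        return lon1, lat1
    f = WGS84_F
    U1 = np.arctan((1 - f) * np.tan(np.radians(lat1)))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sin_az, cos_az = np.sin(az), np.cos(az)
    sigma1 = np.arctan2(np.tan(U1), cos_az)
    sin_alpha = cosU1 * sin_az
    cos2_alpha = 1.0 - sin_alpha**2
    u2 = cos2_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A_ = 1 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B_ = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    sigma = s / (WGS84_B * A_)
    for _ in range(maxiter):
        two_sm = 2.0 * sigma1 + sigma
        cos_2sm = np.cos(two_sm)
        sin_s, cos_s = np.sin(sigma), np.cos(sigma)
        dsig = B_ * sin_s * (
            cos_2sm
            + B_ / 4.0 * (
                cos_s * (-1.0 + 2.0 * cos_2sm**2)
                - B_ / 6.0 * cos_2sm * (-3.0 + 4.0 * sin_s**2) * (-3.0 + 4.0 * cos_2sm**2)
            )
        )
        sigma_prev = sigma
        sigma = s / (WGS84_B * A_) + dsig
        if abs(sigma - sigma_prev) < tol:
            break
    sin_s, cos_s = np.sin(sigma), np.cos(sigma)
    cos_2sm = np.cos(2.0 * sigma1 + sigma)
    phi2 = np.arctan2(
        sinU1 * cos_s + cosU1 * sin_s * cos_az,
        (1 - f) * np.sqrt(sin_alpha**2 + (sinU1 * sin_s - cosU1 * cos_s * cos_az) ** 2),
    )
    lam = np.arctan2(sin_s * sin_az, cosU1 * cos_s - sinU1 * sin_s * cos_az)
    C = f / 16.0 * cos2_alpha * (4.0 + f * (4.0 - 3.0 * cos2_alpha))
    L = lam - (1.0 - C) * f * sin_alpha * (
        sigma + C * sin_s * (cos_2sm + C * cos_s * (-1.0 + 2.0 * cos_2sm**2))
    )
    return float(lon1 + np.degrees(L)), float(np.degrees(phi2))


@dataclass(frozen=True)
class LocalProjection:
    """Azimuthal-equidistant projection centred on (lon0, lat0), WGS84 degrees.

    Built directly on ellipsoidal geodesics (Vincenty): a point maps to
    (s sin a, s cos a) where s and a are the geodesic distance and azimuth
    from the centre.  Distances from the centre are exact and island-scale
    pairwise distances are accurate to well under 0.1%.
    """

    lon0: float
    lat0: float
    radius: float = field(default=0.0)

    def __post_init__(self):
        if self.radius == 0.0:
            object.__setattr__(self, "radius", gaussian_radius(self.lat0))

    def forward(self, lon, lat):
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        x = np.empty(lon.shape)
        y = np.empty(lon.shape)
        for i in np.ndindex(lon.shape):
            s, az = _geodesic_inverse(self.lon0, self.lat0, lon[i], lat[i])
            x[i] = s * np.sin(az)
            y[i] = s * np.cos(az)
        return x, y

    def inverse(self, x, y):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        lon = np.empty(x.shape)
        lat = np.empty(x.shape)
        for i in np.ndindex(x.shape):
            s = float(np.hypot(x[i], y[i]))
            az = float(np.arctan2(x[i], y[i]))
            lon[i], lat[i] = _geodesic_direct(self.lon0, self.lat0, az, s)
        return lon, lat


@dataclass
class LandMask:
    """Island/land geometry in both geographic and projected coordinates."""

    geographic: BaseGeometry  # WGS84 lon/lat
    projection: LocalProjection
    projected: BaseGeometry = None

    def __post_init__(self):
        if self.projected is None:
            self.projected = shapely_transform(
                lambda lon, lat: self.projection.forward(lon, lat), self.geographic
            )
        self._prepared = prep(self.projected)
        self._boundary = self.projected.boundary

    @classmethod
    def from_geojson(cls, path, projection: LocalProjection | None = None) -> "LandMask":
        with open(path) as fh:
            gj = json.load(fh)
        geom = _geojson_geometry(gj)
        if projection is None:
            c = geom.centroid
            projection = LocalProjection(c.x, c.y)
        return cls(geographic=geom, projection=projection)

    def to_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"type": "Feature", "properties": {}, "geometry": mapping(self.geographic)},
                fh,
            )

    def contains_xy(self, x, y) -> np.ndarray:
        """Vectorised point-in-land test in projected metres (boundary is water)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        return np.fromiter(
            (self._prepared.contains_properly(Point(xi, yi)) for xi, yi in zip(x, y)),
            dtype=bool,
            count=len(x),
        )

    def snap_to_shore_xy(self, x, y):
        """Move any point strictly inside land to the nearest boundary point."""
        x = np.array(np.atleast_1d(x), dtype=float)
        y = np.array(np.atleast_1d(y), dtype=float)
        inside = self.contains_xy(x, y)
        for i in np.nonzero(inside)[0]:
            p = Point(x[i], y[i])
            q = self._boundary.interpolate(self._boundary.project(p))
            x[i], y[i] = q.x, q.y
        return x, y


def _geojson_geometry(gj: dict) -> BaseGeometry:
    """Extract the (first) geometry from a GeoJSON object of any flavour."""
    t = gj.get("type")
    if t == "FeatureCollection":
        feats = gj.get("features", [])
        if not feats:
            raise ValueError("GeoJSON FeatureCollection contains no features")
        geoms = [shape(f["geometry"]) for f in feats]
        if len(geoms) == 1:
            return geoms[0]
        from shapely.ops import unary_union

        return unary_union(geoms)
    if t == "Feature":
        return shape(gj["geometry"])
    return shape(gj)
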