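"""Projection of 2-D sampling localities onto the 1-D coastal transect.

The cline model works in one dimension; field localities sampled in two
dimensions are assigned a transect coordinate as the shortest straight-line
distance to the coastline (a polyline of lat/lon vertices).  Distances are
computed on a local equirectangular projection centered at the query point
(x = R cos(lat0) dlon, y = R dlat), which is accurate to well under 0.5% at
the ~100 km extent of a hybrid-zone study region.  A longitude-only
fallback projection is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import asin, cos, radians, sin, sqrt

from shapely.geometry import LineString, Point

from .errors import ValidationError

__all__ = [
    "Locality",
    "distance_to_polyline",
    "great_circle_km",
    "longitude_distance_km",
    "project_to_transect",
    "EARTH_RADIUS_KM",
]

#: IUGG mean Earth radius.
EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class Locality:
    """A named sampling locality in decimal degrees."""

    id: str
    latitude: float
    longitude: float

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"locality {self.id!r}: |latitude| must be <= 90")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"locality {self.id!r}: |longitude| must be <= 180")


def _project_km(lat, lon, lat0, lon0):
    """Local equirectangular projection centered at (lat0, lon0), in km."""
    x = EARTH_RADIUS_KM * cos(radians(lat0)) * radians(lon - lon0)
    y = EARTH_RADIUS_KM * radians(lat - lat0)
    return x, y


def distance_to_polyline(point: Locality, coast) -> float:
    """Shortest straight-line distance (km) from a locality to a polyline.

    The polyline vertices and the point are projected onto a local
    equirectangular plane centered at the point, then the minimum
    point-to-segment distance is taken over all segments.
    """
    coast = list(coast)
    if len(coast) < 2:
        raise ValidationError("coastline polyline needs at least 2 vertices")
    coords = [_project_km(v.latitude, v.longitude, point.latitude, point.longitude) for v in coast]
    line = LineString(coords)
    if line.length == 0:
        raise ValidationError("coastline polyline is degenerate (zero length)")
    return float(line.distance(Point(0.0, 0.0)))


def great_circle_km(a: Locality, b: Locality) -> float:
    """Haversine great-circle distance in km."""
    la1, lo1, la2, lo2 = map(radians, (a.latitude, a.longitude, b.latitude, b.longitude))
    h = sin((la2 - la1) / 2) ** 2 + cos(la1) * cos(la2) * sin((lo2 - lo1) / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * asin(sqrt(h))


def longitude_distance_km(point: Locality, reference_longitude: float) -> float:
    """Fallback 1-D coordinate: east-west distance from a reference meridian,
    scaled by cos(latitude)."""
    x, _ = _project_km(point.latitude, point.longitude, point.latitude, reference_longitude)
    return abs(x)


def project_to_transect(localities, coast=None, *, reference_longitude=None) -> dict:
    """Transect coordinate (km) per locality id.

    Uses distance-to-coast when a coastline is given, otherwise the
    longitude-based fallback (``reference_longitude`` required).
    """
    localities = list(localities)
    if coast is not None:
        coast = list(coast)
        return {loc.id: distance_to_polyline(loc, coast) for loc in localities}
    if reference_longitude is None:
        raise ValidationError("provide either a coastline or a reference_longitude")
    return {loc.id: longitude_distance_km(loc, reference_longitude) for loc in localities}
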