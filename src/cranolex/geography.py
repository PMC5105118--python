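"""Land-based great-circle distances with continental waypoint routing.

Distances are computed on a sphere of radius 6373 km. Inter-continental
paths are constrained through fixed waypoints — Cairo between Africa and
Asia, Phnom Penh between Asia and Australia — so that oceans act as
barriers and routes approximate plausible overland dispersal corridors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cranolex.errors import InvalidParameterError, RoutingError

EARTH_RADIUS_KM = 6373.0

#: Waypoint coordinates as (lat, lon) in degrees.
CAIRO = (30.0, 31.0)
PHNOM_PENH = (11.5, 105.0)


@dataclass(frozen=True)
class GeoPoint:
    """A population anchor location.

    Parameters
    ----------
    lat, lon : float
        Latitude in [-90, 90] and longitude in (-180, 180], degrees.
    continent : str
        Continent label used for waypoint routing.
    """

    lat: float
    lon: float
    continent: str = ""

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise InvalidParameterError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 < self.lon <= 180.0):
            raise InvalidParameterError(f"longitude {self.lon} outside (-180, 180]")


def _default_routes() -> dict:
    return {
        ("Africa", "Asia"): [CAIRO],
        ("Asia", "Australia"): [PHNOM_PENH],
        ("Africa", "Australia"): [CAIRO, PHNOM_PENH],
    }


@dataclass
class WaypointTable:
    """Ordered waypoint lists per ordered continent pair.

    Routes are stored for one orientation; the reverse pair uses the
    reversed waypoint list automatically.
    """

    routes: dict = field(default_factory=_default_routes)
    radius_km: float = EARTH_RADIUS_KM

    def route(self, continent_a: str, continent_b: str) -> list[tuple[float, float]]:
        """Waypoints from ``continent_a`` to ``continent_b`` (possibly empty)."""
        if continent_a == continent_b:
            return []
        if (continent_a, continent_b) in self.routes:
            return list(self.routes[(continent_a, continent_b)])
        if (continent_b, continent_a) in self.routes:
            return list(reversed(self.routes[(continent_b, continent_a)]))
        raise RoutingError(f"no route defined between {continent_a!r} and {continent_b!r}")


def great_circle(a: GeoPoint, b: GeoPoint, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Haversine great-circle distance in km between two points."""
    lat1, lon1, lat2, lon2 = np.radians([a.lat, a.lon, b.lat, b.lon])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return float(2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def routed_distance(a: GeoPoint, b: GeoPoint, table: WaypointTable | None = None) -> float:
    """Great-circle distance constrained through continental waypoints.

    Same-continent pairs are routed directly; otherwise the distance is the
    sum of great-circle legs through the waypoints the table prescribes.
    """
    if table is None:
        table = WaypointTable()
    waypoints = table.route(a.continent, b.continent)
    legs = [a] + [GeoPoint(lat, lon, "") for lat, lon in waypoints] + [b]
    return sum(
        great_circle(p, q, table.radius_km) for p, q in zip(legs[:-1], legs[1:])
    )


def distance_matrix(
    points: dict[str, GeoPoint] | list[GeoPoint],
    table: WaypointTable | None = None,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Symmetric routed-distance matrix (km) over a set of populations.

    ``points`` may be a label->GeoPoint mapping or a list (with optional
    explicit ``labels``). Returns a labelled square DataFrame with zero
    diagonal.
    """
    if isinstance(points, dict):
        labels = list(points)
        pts = [points[k] for k in labels]
    else:
        pts = list(points)
        if labels is None:
            labels = [str(i) for i in range(len(pts))]
    if len(pts) < 2:
        raise InvalidParameterError("need at least 2 points")
    n = len(pts)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = routed_distance(pts[i], pts[j], table)
            values[i, j] = values[j, i] = d
    return pd.DataFrame(values, index=labels, columns=labels)


def read_coordinates_csv(path) -> dict[str, GeoPoint]:
    """Read a (population, lat, lon, continent) CSV into GeoPoints."""
    df = pd.read_csv(path)
    required = {"population", "lat", "lon", "continent"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(f"coordinate CSV needs columns {sorted(required)}")
    return {
        str(row.population): GeoPoint(float(row.lat), float(row.lon), str(row.continent))
        for row in df.itertuples()
    }


def write_coordinates_csv(points: dict[str, GeoPoint], path) -> None:
    pd.DataFrame(
        [
            {"population": k, "lat": p.lat, "lon": p.lon, "continent": p.continent}
            for k, p in points.items()
        ]
    ).to_csv(path, index=False)
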