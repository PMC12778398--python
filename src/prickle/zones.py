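"""Survey-zone geometry: polygons, point-in-zone assignment, GeoJSON I/O.

The park is partitioned into named survey zones (simple polygons in planar
metre coordinates).  Assignment of a point to a zone is boundary-inclusive
and deterministic: zones are tried in lexicographic name order, so a point
on a shared boundary goes to the lexicographically first zone; a point in
no zone is reported as ``"outside"``.

The true park zone boundaries are not published as data, so the package
ships :func:`synthetic_park`, a synthetic 166-ha rectangular stand-in with
seven zones whose areas are loosely proportioned like the real survey
zones (the zoo-grounds zone is 15 ha, as stated for the real park).  It
serves the simulator and tests; real analyses should load their own
GeoJSON polygons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from shapely.geometry import Polygon, box, mapping, shape
from shapely.prepared import prep

OUTSIDE = "outside"

#: tolerance for pairwise zone-interior overlap, in square metres
OVERLAP_TOL_M2 = 1e-6


@dataclass
class ZoneMap:
    """Named, non-overlapping simple polygons covering the surveyed park."""

    zones: dict[str, Polygon]

    def __post_init__(self) -> None:
        self._names = sorted(self.zones)
        self._prepared = None

    def validate(self) -> None:
        """Raise ValueError on self-intersecting or interior-overlapping zones."""
        for name in self._names:
            poly = self.zones[name]
            if not poly.is_valid or poly.is_empty:
                raise ValueError(f"zone {name!r} is not a valid simple polygon")
        for i, a in enumerate(self._names):
            for b in self._names[i + 1 :]:
                inter = self.zones[a].intersection(self.zones[b])
                if inter.area > OVERLAP_TOL_M2:
                    raise ValueError(
                        f"zones {a!r} and {b!r} overlap by {inter.area:.3g} m^2"
                    )

    def assign(self, easting_m: float, northing_m: float) -> str:
        """Zone containing the point (boundary counts as inside); ties break
        to the lexicographically first zone name; otherwise 'outside'."""
        if self._prepared is None:
            self._prepared = [(n, prep(self.zones[n])) for n in self._names]
        from shapely.geometry import Point

        pt = Point(easting_m, northing_m)
        for name, prepared in self._prepared:
            if prepared.intersects(pt):
                return name
        return OUTSIDE

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def bounds(self) -> tuple[float, float, float, float]:
        xs0, ys0, xs1, ys1 = zip(*(p.bounds for p in self.zones.values()))
        return (min(xs0), min(ys0), max(xs1), max(ys1))

    def total_area_ha(self) -> float:
        return sum(p.area for p in self.zones.values()) / 1e4

    # -- GeoJSON -----------------------------------------------------------

    @classmethod
    def from_geojson(cls, path: str | Path) -> "ZoneMap":
        """Load zones from a FeatureCollection of Polygons with a ``name``
        property per feature."""
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        zones: dict[str, Polygon] = {}
        for feature in data["features"]:
            name = feature["properties"]["name"]
            geom = shape(feature["geometry"])
            if geom.geom_type != "Polygon":
                raise ValueError(f"zone {name!r}: expected Polygon, got {geom.geom_type}")
            zones[name] = geom
        return cls(zones)

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"name": name},
                "geometry": mapping(self.zones[name]),
            }
            for name in self._names
        ]
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features}, indent=1),
            encoding="utf-8",
        )


# synthetic 7-zone rectangular park, 1660 m x 1000 m = 166 ha.
# Bottom row (south): zones 1, 2, 5; top row (north): zones 3, 4, 6 and the
# 15-ha zoo grounds (zone 7) in the north-east corner.
_ORIGIN_E = 530000.0
_ORIGIN_N = 182000.0


def synthetic_park() -> ZoneMap:
    """Synthetic seven-zone rectangular park geometry (166 ha total)."""
    e, n = _ORIGIN_E, _ORIGIN_N

    def z(x0: float, y0: float, x1: float, y1: float) -> Polygon:
        return box(e + x0, n + y0, e + x1, n + y1)

    zones = {
        "zone1": z(0, 0, 600, 500),        # 30 ha, south-west
        "zone2": z(600, 0, 1200, 500),     # 30 ha, south-centre
        "zone5": z(1200, 0, 1660, 500),    # 23 ha, south-east
        "zone3": z(0, 500, 500, 1000),     # 25 ha, north-west
        "zone4": z(500, 500, 1000, 1000),  # 25 ha, north-centre
        "zone6": z(1000, 500, 1360, 1000), # 18 ha
        "zone7": z(1360, 500, 1660, 1000), # 15 ha, zoo grounds
    }
    zm = ZoneMap(zones)
    zm.validate()
    return zm
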