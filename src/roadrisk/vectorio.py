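"""GeoJSON vector I/O.

Geographic coordinates (lon/lat, WGS84) in, geographic out.  Features are
(geometry, properties) pairs; attribute field naming is up to the caller.
"""

from __future__ import annotations

import json
from pathlib import Path

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


def read_features(path) -> list[tuple[BaseGeometry, dict]]:
    """Read a GeoJSON FeatureCollection (or single Feature/geometry)."""
    with open(path) as fh:
        obj = json.load(fh)
    t = obj.get("type")
    if t == "FeatureCollection":
        return [(shape(f["geometry"]), dict(f.get("properties") or {})) for f in obj["features"]]
    if t == "Feature":
        return [(shape(obj["geometry"]), dict(obj.get("properties") or {}))]
    return [(shape(obj), {})]


def write_features(path, features: list[tuple[BaseGeometry, dict]]) -> None:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    collection = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    Path(path).write_text(json.dumps(collection, indent=1, sort_keys=True))


def read_geometries(path) -> list[BaseGeometry]:
    return [g for g, _ in read_features(path)]
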