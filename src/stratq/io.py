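"""Light-weight readers/writers for the pipeline's interchange formats."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

__all__ = ["write_geojson_points", "read_geojson_points"]


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v


def write_geojson_points(df: pd.DataFrame, path, lon: str = "lon", lat: str = "lat") -> None:
    """Write a table with lon/lat columns as a GeoJSON FeatureCollection of
    points; every other column becomes a feature property."""
    props = [c for c in df.columns if c not in (lon, lat)]
    features = []
    for _, row in df.iterrows():
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(row[lon]), float(row[lat])]},
            "properties": {c: _jsonable(row[c]) for c in props},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh,
                  indent=1, sort_keys=True)
        fh.write("\n")


def read_geojson_points(path) -> pd.DataFrame:
    with open(path) as fh:
        gj = json.load(fh)
    rows = []
    for feat in gj["features"]:
        lon, lat = feat["geometry"]["coordinates"]
        rows.append({"lon": lon, "lat": lat, **feat["properties"]})
    return pd.DataFrame(rows)
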