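"""Plain-text IO: GeoJSON vectors, telemetry CSV, well-registry CSV."""

from __future__ import annotations

import json

import pandas as pd
from shapely.geometry import mapping, shape


def write_geojson(path, geometries, properties=None) -> None:
    """Write geometries (with optional per-feature property dicts) as GeoJSON."""
    geometries = list(geometries)
    properties = list(properties) if properties is not None else [{}] * len(geometries)
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geometries, properties)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path):
    """Read a GeoJSON FeatureCollection -> (geometries, properties)."""
    with open(path) as fh:
        data = json.load(fh)
    geoms = [shape(f["geometry"]) for f in data["features"]]
    props = [f.get("properties", {}) for f in data["features"]]
    return geoms, props


def write_telemetry(path, telemetry: pd.DataFrame) -> None:
    out = telemetry.copy()
    out["datetime"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out[["bird_id", "datetime", "x", "y"]].to_csv(path, index=False)


def read_telemetry(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["datetime"])
    return df[["bird_id", "timestamp", "x", "y"]]


def write_wells(path, wells: pd.DataFrame) -> None:
    wells.to_csv(path, index=False)


def read_wells(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("spud", "completion", "first_production", "last_production", "expiration"):
        if c in df.columns:
            df[c] = pd.to_datetime(df[c])
    return df
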