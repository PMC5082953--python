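"""Containers for the landscape stack and energy-development layers.

The landscape stack bundles the categorical vegetation raster, elevation (ft),
NDVI, the stream network, irrigated-agriculture polygons and the study-area
extent on one shared projected grid.  Energy layers carry the well registry
(points with activity dates and status), classified roads and field outlines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon

from .grid import Raster

#: canonical vegetation class codes used throughout the package
CLASS_CODES: dict[int, str] = {
    1: "sagebrush",
    2: "grassland",
    3: "sagebrush_grassland",
    4: "riparian",
    5: "agriculture",
    6: "other",
}

PROPORTION_VARS = ["agriculture", "grassland", "sagebrush", "sagebrush_grassland", "riparian"]
HABITAT_VARS = PROPORTION_VARS + [
    "elevation",
    "ndvi",
    "dist_water",
    "water_density",
    "dist_sagebrush",
    "dist_agriculture",
]
ENERGY_VARS = ["dist_oil_roads", "dist_wells", "energy_index"]

#: reserved group id for the shared availability sample in mixed-model fits
AVAILABLE_GROUP = "_available_"

WELL_COLUMNS = [
    "well_id",
    "x",
    "y",
    "status",
    "spud",
    "completion",
    "first_production",
    "last_production",
    "expiration",
]


@dataclass
class LandscapeStack:
    """All static habitat layers on one projected meter grid."""

    vegetation: Raster  # integer class codes (CLASS_CODES)
    elevation: Raster  # feet
    ndvi: Raster  # unitless, within [-1, 1]
    streams: list[LineString]
    agriculture: list[Polygon]
    extent: Polygon
    class_table: dict[int, str] = field(default_factory=lambda: dict(CLASS_CODES))

    def validate(self) -> None:
        if not (self.vegetation.same_grid(self.elevation) and self.vegetation.same_grid(self.ndvi)):
            raise ValueError("vegetation, elevation and ndvi must share one grid")
        if np.any(self.ndvi.values < -1) or np.any(self.ndvi.values > 1):
            raise ValueError("ndvi outside [-1, 1]")
        codes = np.unique(self.vegetation.values)
        unknown = set(codes.tolist()) - set(self.class_table)
        if unknown:
            raise ValueError(f"vegetation codes without a class-table entry: {sorted(unknown)}")

    def code_of(self, name: str) -> int:
        for code, cname in self.class_table.items():
            if cname == name:
                return code
        raise KeyError(name)


@dataclass
class EnergyLayers:
    """Energy-development infrastructure: wells, roads, field outlines, index."""

    wells: pd.DataFrame  # WELL_COLUMNS
    roads: pd.DataFrame  # columns: geometry (LineString), road_class, tag
    fields_polygons: list[Polygon]
    dev_index: Raster | None = None

    @property
    def oil_roads(self) -> list[LineString]:
        if len(self.roads) == 0:
            return []
        return list(self.roads.loc[self.roads["tag"] == "oil_gas", "geometry"])
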