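"""Buffer-level covariate extraction and energy-development engineering.

Every used or available location is summarized over a disc of the season's
movement radius: vegetation-class proportions (exact cell-disc overlap areas),
area-weighted means of continuous rasters, distances to habitat classes and
vector features (zero whenever the feature occurs inside the buffer), stream
density, and the energy-development covariates (distance to oil/gas roads and
active well pads, and a combined development-intensity index over a 1 km^2
window).

Two code paths produce identical numbers: a per-point extractor for arbitrary
buffer centers (training data) and a moving-window raster builder for
grid-aligned centers (prediction maps), which shares the same disc kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from .grid import Raster, disc_cell_weights, disc_kernel, disc_polygon
from .layers import CLASS_CODES, ENERGY_VARS, HABITAT_VARS, EnergyLayers, LandscapeStack

PROTECTED_ROAD_CLASSES = frozenset({"highway", "county", "local"})


# ---------------------------------------------------------------------------
# elementary buffer summaries
# ---------------------------------------------------------------------------

def class_proportions(x: float, y: float, radius_m: float, vegetation: Raster,
                      class_table: dict[int, str] | None = None) -> dict[str, float]:
    """Proportion of buffer area in each vegetation class.

    Proportions are overlap areas of the disc with cells of each class divided
    by the disc area inside the raster; they sum to 1 over all classes.
    """
    class_table = class_table or CLASS_CODES
    rows, cols, w = disc_cell_weights(vegetation, x, y, radius_m)
    codes = vegetation.values[rows, cols].astype(int)
    total = w.sum()
    out = {name: 0.0 for name in class_table.values()}
    for code in np.unique(codes):
        out[class_table[int(code)]] = float(w[codes == code].sum() / total)
    return out


def mean_within_buffer(x: float, y: float, radius_m: float, raster: Raster) -> float:
    """Area-weighted mean of a continuous raster over the disc."""
    rows, cols, w = disc_cell_weights(raster, x, y, radius_m)
    vals = raster.values[rows, cols]
    ok = vals != raster.nodata
    if not np.any(ok):
        raise ValueError("all cells under the buffer are missing")
    return float(np.average(vals[ok], weights=w[ok]))


def distance_to_class(x: float, y: float, radius_m: float, vegetation: Raster,
                      code: int, tree: cKDTree | None = None) -> float:
    """Distance (km) from the point to the nearest cell of a raster class.

    Zero whenever the class has positive overlap with the buffer; otherwise the
    Euclidean distance from the buffer centroid to the nearest class-cell
    center.
    """
    if tree is None:
        tree = class_tree(vegetation, code)
    if tree is None:
        raise ValueError(f"vegetation class {code} is empty on this raster")
    rows, cols, w = disc_cell_weights(vegetation, x, y, radius_m)
    if np.any(vegetation.values[rows, cols].astype(int) == code):
        return 0.0
    d, _ = tree.query([x, y])
    return float(d) / 1000.0


def class_tree(vegetation: Raster, code: int) -> cKDTree | None:
    """KD-tree over the centers of all cells of one class (None if empty)."""
    rows, cols = np.nonzero(vegetation.values.astype(int) == code)
    if rows.size == 0:
        return None
    cx, cy = vegetation.cell_center(rows, cols)
    return cKDTree(np.column_stack([cx, cy]))


def distance_to_features(x: float, y: float, radius_m: float, geoms) -> float:
    """Distance (km) to the nearest vector feature; 0 if any feature is within
    the buffer radius of the point."""
    union = geoms if isinstance(geoms, shapely.Geometry) else shapely.union_all(list(geoms))
    if union.is_empty:
        raise ValueError("feature layer is empty")
    d = shapely.distance(Point(x, y), union)
    return 0.0 if d <= radius_m else float(d) / 1000.0


def line_density(window: Polygon, lines) -> float:
    """Total clipped line length (km) per window area (km^2)."""
    area_km2 = window.area / 1e6
    if area_km2 <= 0:
        raise ValueError("window area must be positive")
    union = lines if isinstance(lines, shapely.Geometry) else shapely.union_all(list(lines))
    if union.is_empty:
        return 0.0
    return (shapely.intersection(union, window).length / 1000.0) / area_km2


# ---------------------------------------------------------------------------
# rare-class filtering
# ---------------------------------------------------------------------------

def filter_rare_classes(tables: dict[str, pd.DataFrame], threshold: float = 0.001,
                        class_names=None) -> dict[str, tuple[list[str], list[dict]]]:
    """Drop vegetation classes that are rare or absent from presence buffers.

    A class is dropped in a season when its share of the land surface within
    all that season's buffers (the mean proportion over used + available rows)
    is strictly below ``threshold``; classes present in the availability sample
    but absent from every used buffer are additionally dropped as a guard
    against complete separation.  Returns, per season, the retained class list
    and an audit log of drops with reasons.
    """
    from .layers import PROPORTION_VARS

    class_names = list(class_names) if class_names is not None else list(PROPORTION_VARS)
    out: dict[str, tuple[list[str], list[dict]]] = {}
    for season, tab in tables.items():
        retained, audit = [], []
        used = tab[tab["response"] == 1] if "response" in tab else tab
        for name in class_names:
            if name not in tab.columns:
                continue
            share = float(tab[name].mean())
            if share < threshold:
                audit.append({"season": season, "class": name, "share": share, "reason": "rare"})
            elif len(used) and float(used[name].max()) == 0.0:
                audit.append({"season": season, "class": name, "share": share,
                              "reason": "separation guard"})
            else:
                retained.append(name)
        out[season] = (retained, audit)
    return out


# ---------------------------------------------------------------------------
# energy infrastructure
# ---------------------------------------------------------------------------

def classify_roads(roads: pd.DataFrame, wells: pd.DataFrame, fields_polygons,
                   protected_classes=PROTECTED_ROAD_CLASSES, snap_m: float = 100.0
                   ) -> pd.DataFrame:
    """Tag each road ``oil_gas`` or ``other``.

    A road is tagged oil_gas iff it terminates within ``snap_m`` of a well pad
    or intersects an oil/gas field polygon, unless its road class is protected
    (highway / county / local roads keep their civil classification).
    """
    roads = roads.copy()
    well_pts = shapely.points(np.column_stack([wells["x"], wells["y"]])) if len(wells) else np.array([])
    fields_union = shapely.union_all(list(fields_polygons)) if len(list(fields_polygons)) else None
    tags = []
    for _, row in roads.iterrows():
        geom = row["geometry"]
        if str(row.get("road_class", "unclassified")) in protected_classes:
            tags.append("other")
            continue
        hit = False
        if fields_union is not None and not fields_union.is_empty and geom.intersects(fields_union):
            hit = True
        if not hit and len(well_pts):
            coords = geom.coords
            for end in (Point(coords[0]), Point(coords[-1])):
                if np.min(shapely.distance(well_pts, end)) <= snap_m:
                    hit = True
                    break
        tags.append("oil_gas" if hit else "other")
    roads["tag"] = tags
    return roads


def active_wells(wells: pd.DataFrame, study_interval: tuple) -> pd.DataFrame:
    """Wells with active status whose activity interval overlaps the study.

    The activity interval starts at the first recorded milestone (spud,
    completion or first production) and ends at the last production or
    expiration date (open-ended if neither is recorded).  Wells missing every
    start date are excluded with a warning.
    """
    start, end = pd.Timestamp(study_interval[0]), pd.Timestamp(study_interval[1])
    keep = []
    n_missing = 0
    for idx, row in wells.iterrows():
        if str(row.get("status", "")).lower() != "active":
            continue
        begins = [pd.Timestamp(row[c]) for c in ("spud", "completion", "first_production")
                  if pd.notna(row.get(c))]
        if not begins:
            n_missing += 1
            continue
        w_start = min(begins)
        ends = [pd.Timestamp(row[c]) for c in ("last_production", "expiration")
                if pd.notna(row.get(c))]
        w_end = max(ends) if ends else pd.Timestamp.max
        if w_start <= end and w_end >= start:
            keep.append(idx)
    if n_missing:
        warnings.warn(f"{n_missing} active wells excluded for missing activity dates")
    return wells.loc[keep]


@dataclass
class EnergyIndex:
    """Energy-development index: rescaled well density + rescaled oil-road density.

    Raw densities are evaluated over a fixed 1 km^2 axis-aligned square window
    centered on the query point; each component is min-max rescaled to [0, 1]
    over the study grid, so the index lies in [0, 2] with 0 meaning no
    development and 2 the cell attaining both maxima.  Windows extending past
    the study extent count the outside as development-free.
    """

    template: Raster
    wells_xy: np.ndarray  # (n, 2) active well coordinates
    oil_roads_union: shapely.Geometry
    window_km2: float = 1.0
    well_density: Raster = None
    road_density: Raster = None
    index: Raster = None
    wd_range: tuple[float, float] = (0.0, 0.0)
    rd_range: tuple[float, float] = (0.0, 0.0)

    @classmethod
    def build(cls, template: Raster, wells: pd.DataFrame, oil_roads,
              window_km2: float = 1.0) -> "EnergyIndex":
        wells_xy = (np.column_stack([wells["x"], wells["y"]]).astype(float)
                    if len(wells) else np.empty((0, 2)))
        union = shapely.union_all(list(oil_roads)) if len(list(oil_roads)) else shapely.GeometryCollection()
        self = cls(template=template, wells_xy=wells_xy, oil_roads_union=union,
                   window_km2=window_km2)
        half = np.sqrt(window_km2) * 1000.0 / 2.0
        cx, cy = template.cell_centers()
        # well counts per window via rectangular accumulation
        counts = np.zeros(template.values.shape)
        for wx, wy in wells_xy:
            hit = (np.abs(cx - wx) <= half) & (np.abs(cy - wy) <= half)
            counts[hit] += 1.0
        wd = counts / window_km2
        # oil-road length per window
        if union.is_empty:
            rd = np.zeros(template.values.shape)
        else:
            boxes = shapely.box(cx.ravel() - half, cy.ravel() - half,
                                cx.ravel() + half, cy.ravel() + half)
            lengths = shapely.length(shapely.intersection(boxes, union))
            rd = (lengths.reshape(cx.shape) / 1000.0) / window_km2
        self.well_density = template.copy_with(wd)
        self.road_density = template.copy_with(rd)
        self.wd_range = (float(wd.min()), float(wd.max()))
        self.rd_range = (float(rd.min()), float(rd.max()))
        self.index = template.copy_with(self._rescale(wd, self.wd_range)
                                        + self._rescale(rd, self.rd_range))
        return self

    @staticmethod
    def _rescale(raw, rng):
        lo, hi = rng
        if hi <= lo:
            return np.zeros_like(np.asarray(raw, dtype=float))
        return (np.asarray(raw, dtype=float) - lo) / (hi - lo)

    def raw_densities_at(self, x: float, y: float) -> tuple[float, float]:
        """(well density, oil-road density) over the 1 km^2 window at (x, y)."""
        half = np.sqrt(self.window_km2) * 1000.0 / 2.0
        if len(self.wells_xy):
            hit = (np.abs(self.wells_xy[:, 0] - x) <= half) & (np.abs(self.wells_xy[:, 1] - y) <= half)
            wd = float(hit.sum()) / self.window_km2
        else:
            wd = 0.0
        if self.oil_roads_union.is_empty:
            rd = 0.0
        else:
            box = shapely.box(x - half, y - half, x + half, y + half)
            rd = (shapely.intersection(self.oil_roads_union, box).length / 1000.0) / self.window_km2
        return wd, rd

    def at(self, x: float, y: float) -> float:
        wd, rd = self.raw_densities_at(x, y)
        return float(self._rescale(wd, self.wd_range) + self._rescale(rd, self.rd_range))


def energy_development_index(x: float, y: float, index: EnergyIndex) -> float:
    """Index value at a point (see :class:`EnergyIndex`)."""
    return index.at(x, y)


# ---------------------------------------------------------------------------
# table extraction (per-point path)
# ---------------------------------------------------------------------------

def extract_covariates(points: pd.DataFrame, radius_m: float, landscape: LandscapeStack,
                       energy: EnergyLayers | None = None,
                       energy_index: EnergyIndex | None = None,
                       study_interval: tuple | None = None) -> pd.DataFrame:
    """Summarize all covariates over a disc around each point.

    ``points`` needs columns x, y; all other columns pass through.  Energy
    covariates are added when energy layers are supplied (active wells are
    filtered to ``study_interval`` when given, otherwise the registry is taken
    as already filtered).
    """
    veg = landscape.vegetation
    streams_union = shapely.union_all(list(landscape.streams)) if landscape.streams else shapely.GeometryCollection()
    trees = {name: class_tree(veg, code) for code, name in landscape.class_table.items()}
    class_names = list(landscape.class_table.values())
    code_by_name = {v: k for k, v in landscape.class_table.items()}

    if energy is not None:
        wells = energy.wells
        if study_interval is not None:
            wells = active_wells(wells, study_interval)
        wells_xy = np.column_stack([wells["x"], wells["y"]]).astype(float) if len(wells) else np.empty((0, 2))
        well_tree = cKDTree(wells_xy) if len(wells_xy) else None
        oil_union = shapely.union_all(energy.oil_roads) if energy.oil_roads else shapely.GeometryCollection()
        if energy_index is None:
            energy_index = EnergyIndex.build(veg, wells, energy.oil_roads)

    recs = []
    for x, y in zip(points["x"].to_numpy(float), points["y"].to_numpy(float)):
        rows, cols, w = disc_cell_weights(veg, x, y, radius_m)
        codes = veg.values[rows, cols].astype(int)
        total = w.sum()
        rec = {name: 0.0 for name in class_names}
        for code in np.unique(codes):
            rec[landscape.class_table[int(code)]] = float(w[codes == code].sum() / total)
        rec["elevation"] = float(np.average(landscape.elevation.values[rows, cols], weights=w))
        rec["ndvi"] = float(np.average(landscape.ndvi.values[rows, cols], weights=w))
        if streams_union.is_empty:
            raise ValueError("stream layer is empty")
        d_water = shapely.distance(Point(x, y), streams_union)
        rec["dist_water"] = 0.0 if d_water <= radius_m else float(d_water) / 1000.0
        rec["water_density"] = line_density(disc_polygon(x, y, radius_m), streams_union)
        for cname in ("sagebrush", "agriculture"):
            key = "dist_" + ("sagebrush" if cname == "sagebrush" else "agriculture")
            if rec[cname] > 0:
                rec[key] = 0.0
            else:
                tree = trees[cname]
                if tree is None:
                    raise ValueError(f"class '{cname}' is empty on this landscape")
                d, _ = tree.query([x, y])
                rec[key] = float(d) / 1000.0
        if energy is not None:
            if oil_union.is_empty:
                rec["dist_oil_roads"] = np.nan
            else:
                d = shapely.distance(Point(x, y), oil_union)
                rec["dist_oil_roads"] = 0.0 if d <= radius_m else float(d) / 1000.0
            if well_tree is None:
                rec["dist_wells"] = np.nan
            else:
                d, _ = well_tree.query([x, y])
                rec["dist_wells"] = 0.0 if d <= radius_m else float(d) / 1000.0
            rec["energy_index"] = energy_index.at(x, y)
        recs.append(rec)
    cov = pd.DataFrame(recs, index=points.index)
    return pd.concat([points, cov], axis=1)


# ---------------------------------------------------------------------------
# moving-window raster path (prediction surfaces, simulation truth)
# ---------------------------------------------------------------------------

def covariate_grid(landscape: LandscapeStack, radius_m: float,
                   energy: EnergyLayers | None = None,
                   energy_index: EnergyIndex | None = None,
                   study_interval: tuple | None = None) -> dict[str, Raster]:
    """Moving-window covariate rasters at every cell center.

    Uses the same disc geometry as :func:`extract_covariates`, so values at a
    cell center equal the per-point extraction at that center.
    """
    veg = landscape.vegetation
    kern = disc_kernel(veg.cell, radius_m)
    K = kern.weights

    def conv(a):
        return ndimage.convolve(np.asarray(a, dtype=float), K, mode="constant", cval=0.0)

    denom = conv(np.ones(veg.values.shape))
    out: dict[str, Raster] = {}
    code_arr = veg.values.astype(int)
    for code, name in landscape.class_table.items():
        out[name] = veg.copy_with(conv(code_arr == code) / denom)
    out["elevation"] = veg.copy_with(conv(landscape.elevation.values) / denom)
    out["ndvi"] = veg.copy_with(conv(landscape.ndvi.values) / denom)

    cx, cy = veg.cell_centers()
    pts = shapely.points(np.column_stack([cx.ravel(), cy.ravel()]))
    streams_union = shapely.union_all(list(landscape.streams)) if landscape.streams else shapely.GeometryCollection()
    if streams_union.is_empty:
        raise ValueError("stream layer is empty")
    d = shapely.distance(pts, streams_union).reshape(cx.shape)
    out["dist_water"] = veg.copy_with(np.where(d <= radius_m, 0.0, d / 1000.0))

    discs = shapely.buffer(pts, radius_m, quad_segs=8)
    lens = shapely.length(shapely.intersection(discs, streams_union)).reshape(cx.shape)
    areas = shapely.area(discs).reshape(cx.shape)
    out["water_density"] = veg.copy_with((lens / 1000.0) / (areas / 1e6))

    for cname in ("sagebrush", "agriculture"):
        code = landscape.code_of(cname)
        mask = code_arr == code
        if not mask.any():
            raise ValueError(f"class '{cname}' is empty on this landscape")
        edt = ndimage.distance_transform_edt(~mask, sampling=veg.cell) / 1000.0
        edt = np.where(out[cname].values > 0, 0.0, edt)
        out["dist_" + cname] = veg.copy_with(edt)

    if energy is not None:
        wells = energy.wells
        if study_interval is not None:
            wells = active_wells(wells, study_interval)
        if len(wells):
            wtree = cKDTree(np.column_stack([wells["x"], wells["y"]]).astype(float))
            dw, _ = wtree.query(np.column_stack([cx.ravel(), cy.ravel()]))
            dw = dw.reshape(cx.shape)
            out["dist_wells"] = veg.copy_with(np.where(dw <= radius_m, 0.0, dw / 1000.0))
        oil_union = shapely.union_all(energy.oil_roads) if energy.oil_roads else shapely.GeometryCollection()
        if not oil_union.is_empty:
            dr = shapely.distance(pts, oil_union).reshape(cx.shape)
            out["dist_oil_roads"] = veg.copy_with(np.where(dr <= radius_m, 0.0, dr / 1000.0))
        if energy_index is None:
            energy_index = EnergyIndex.build(veg, wells, energy.oil_roads)
        out["energy_index"] = energy_index.index
    return out
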