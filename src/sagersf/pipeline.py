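"""End-to-end orchestration: simulate -> design -> covariates -> fit -> map ->
validate -> energy, with per-stage seeds, plain-file artifacts and a checksum
manifest; or, entering at the fitting stage, ingestion of a seasonal covariate
workbook (breeding / summer / winter / available tabs).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .covariates import extract_covariates, filter_rare_classes
from .design import DEFAULT_SEASONS, SeasonDefinition, build_design
from .energy import augment_and_compare, local_subset
from .fitting import (assign_available_groups, fit_all_subsets, fit_mixed_logit,
                      pearson_screen)
from .layers import AVAILABLE_GROUP, ENERGY_VARS
from .surfaces import model_averaged_surface
from .synthetic import (STUDY_INTERVAL, LandscapeConfig, TruthModel,
                        generate_energy_field, generate_landscape,
                        simulate_telemetry)
from .validation import cross_validate

#: availability sample sizes at which the sensitivity analysis converged
DEFAULT_N_AVAILABLE = {"breeding": 7000, "summer": 6000, "winter": 7000}

#: default candidate covariates offered to screening/all-subsets (kept small
#: enough that the 2^p model set stays tractable in routine runs)
DEFAULT_CANDIDATES = ["sagebrush", "grassland", "sagebrush_grassland",
                      "dist_agriculture", "dist_water", "ndvi", "agriculture"]

DEFAULT_PRIORITY = ["sagebrush", "grassland", "sagebrush_grassland", "riparian",
                    "dist_sagebrush", "elevation", "dist_agriculture", "dist_water",
                    "water_density", "ndvi", "agriculture"]


@dataclass
class RunConfig:
    out_dir: str = "run"
    seeds: dict = field(default_factory=lambda: {
        "landscape": 1, "energy": 2, "telemetry": 3, "available": 4, "folds": 5})
    landscape: dict = field(default_factory=dict)      # LandscapeConfig overrides
    n_wells: int = 24
    n_clusters: int = 2
    n_birds: int = 30
    relocations_per_bird: int = 50
    truth_coefficients: dict = field(default_factory=lambda: {
        "sagebrush": 3.161, "grassland": 1.456, "sagebrush_grassland": 2.775,
        "dist_agriculture": 0.167, "dist_water": -0.435})
    truth_sigma_b: float = 0.5
    seasons: list = field(default_factory=lambda: [
        {"name": s.name, "start": list(s.start), "end": list(s.end),
         "buffer_radius_m": s.buffer_radius_m} for s in DEFAULT_SEASONS])
    n_available: dict = field(default_factory=lambda: {"breeding": 2000, "summer": 1500,
                                                       "winter": 2000})
    candidates: list = field(default_factory=lambda: list(DEFAULT_CANDIDATES))
    priority: list = field(default_factory=lambda: list(DEFAULT_PRIORITY))
    screen_threshold: float = 0.65
    confidence_mass: float = 0.95
    kfold_k: int = 5
    kfold_holdout: float = 0.2
    energy_radius_km: float = 2.0
    rare_class_threshold: float = 0.001
    s1_path: str | None = None                          # entry-point routing
    s1_n_available: dict = field(default_factory=lambda: dict(DEFAULT_N_AVAILABLE))
    available_grouping: str = "random_bird"             # or 'pooled' (sensitivity only)

    def __post_init__(self):
        # canonical YAML-stable form
        if "shape" in self.landscape:
            self.landscape["shape"] = list(self.landscape["shape"])

    def season_defs(self) -> list[SeasonDefinition]:
        return [SeasonDefinition(s["name"], tuple(s["start"]), tuple(s["end"]),
                                 s["buffer_radius_m"]) for s in self.seasons]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# workbook ingestion
# ---------------------------------------------------------------------------

S1_REQUIRED = ["agriculture", "grassland", "sagebrush", "sagebrush_grassland",
               "riparian", "elevation", "dist_water", "water_density",
               "dist_sagebrush", "dist_agriculture", "dist_oil_roads",
               "dist_wells", "energy_index"]

_S1_ALIASES = {
    "bird": "bird",
    "proportion of irrigated agriculture": "agriculture",
    "irrigated agriculture": "agriculture",
    "proportion of grassland": "grassland",
    "proportion of sagebrush": "sagebrush",
    "proportion of sagebrush/grassland mix": "sagebrush_grassland",
    "sagebrush/grassland": "sagebrush_grassland",
    "proportion of riparian": "riparian",
    "elevation (m)": "elevation",
    "elevation (ft)": "elevation",
    "distance to water (km)": "dist_water",
    "distance to water": "dist_water",
    "water density (km/km2)": "water_density",
    "water density": "water_density",
    "distance to sagebrush (km)": "dist_sagebrush",
    "distance to sagebrush": "dist_sagebrush",
    "distance to agriculture (km)": "dist_agriculture",
    "distance to agriculture": "dist_agriculture",
    "distance to oil/gas roads (km)": "dist_oil_roads",
    "distance to oil/gas roads": "dist_oil_roads",
    "distance to oil roads": "dist_oil_roads",
    "distance to well pads (km)": "dist_wells",
    "distance to well pads": "dist_wells",
    "energy development index": "energy_index",
}


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    ren = {}
    for col in df.columns:
        key = str(col).strip().lower()
        ren[col] = _S1_ALIASES.get(key, key)
    return df.rename(columns=ren)


def ingest_s1(path, n_available: dict | None = None, grouping: str = "random_bird",
              seed: int = 0) -> dict[str, pd.DataFrame]:
    """Read a seasonal covariate workbook into fit-ready tables.

    Expects tabs breeding / summer / winter / available with the documented
    column list.  Returns one table per season: used rows (response 1, group =
    bird id) stacked on the availability rows (response 0, the reserved
    pseudo-group), availability truncated to the per-season sample size.
    """
    n_available = dict(n_available or DEFAULT_N_AVAILABLE)
    sheets = pd.read_excel(path, sheet_name=None)
    sheets = {str(k).strip().lower(): _normalize_columns(v) for k, v in sheets.items()}
    for tab in ("breeding", "summer", "winter", "available"):
        if tab not in sheets:
            raise ValueError(f"workbook is missing tab '{tab}'")
        missing = [c for c in S1_REQUIRED if c not in sheets[tab].columns]
        if missing:
            raise ValueError(f"tab '{tab}' is missing columns: {missing}")
        if tab != "available" and "bird" not in sheets[tab].columns:
            raise ValueError(f"tab '{tab}' is missing the bird column")
    avail = sheets["available"]
    out = {}
    for si, season in enumerate(("breeding", "summer", "winter")):
        used = sheets[season].copy()
        used["response"] = 1
        n_av = min(int(n_available.get(season, len(avail))), len(avail))
        av = avail.iloc[:n_av].copy()
        av["response"] = 0
        av["bird"] = AVAILABLE_GROUP
        tab = pd.concat([used, av], ignore_index=True)
        tab["season"] = season
        tab = assign_available_groups(tab, mode=grouping, seed=seed * 4 + si, bird="bird")
        tab["bird_id"] = tab["bird"]
        out[season] = tab[["season", "bird", "bird_id", "group", "response"] + S1_REQUIRED]
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns (and writes) the run manifest.

    Every artifact is a plain file with a recorded sha256, and all randomness
    flows from the named per-stage seeds, so a rerun with the same config
    reproduces the manifest bit-for-bit.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "artifacts": {}, "numbers": {}}

    def record(name: str, path: Path):
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    def stage(name):
        manifest["stages"][name] = "completed"

    try:
        if config.s1_path:
            tables = ingest_s1(config.s1_path, config.s1_n_available)
            stage("ingest_s1")
            season_tables = tables
            seasons = [s for s in config.season_defs() if s.name in tables]
            landscape = energy = None
        else:
            cfg = LandscapeConfig(**config.landscape)
            landscape = generate_landscape(cfg, seed=config.seeds["landscape"])
            energy = generate_energy_field(landscape, config.n_wells, config.n_clusters,
                                           seed=config.seeds["energy"])
            truth = TruthModel(coefficients=dict(config.truth_coefficients),
                               random_intercept_sd=config.truth_sigma_b,
                               season_windows=config.season_defs())
            telemetry = simulate_telemetry(landscape, energy, truth, config.n_birds,
                                           config.relocations_per_bird,
                                           seed=config.seeds["telemetry"])
            landscape.vegetation.to_ascii(out / "vegetation.asc")
            landscape.elevation.to_ascii(out / "elevation.asc")
            landscape.ndvi.to_ascii(out / "ndvi.asc")
            sio.write_geojson(out / "streams.geojson", landscape.streams)
            sio.write_geojson(out / "roads.geojson", energy.roads["geometry"],
                              energy.roads[["road_class", "tag"]].to_dict("records"))
            sio.write_wells(out / "wells.csv", energy.wells)
            sio.write_telemetry(out / "telemetry.csv", telemetry)
            for n in ("vegetation.asc", "elevation.asc", "ndvi.asc", "streams.geojson",
                      "roads.geojson", "wells.csv", "telemetry.csv"):
                record(n, out / n)
            stage("simulate")

            seasons = config.season_defs()
            design, report = build_design(telemetry, landscape.extent, seasons=seasons,
                                          n_available=config.n_available,
                                          seed=config.seeds["available"])
            design.to_csv(out / "design.csv", index=False)
            record("design.csv", out / "design.csv")
            manifest["numbers"]["design"] = {
                "dropped_in_gaps": report["dropped_in_gaps"],
                "radii_m": report["radii_m"],
            }
            stage("design")

            season_tables = {}
            for s in seasons:
                sub = design[design["season"] == s.name].reset_index(drop=True)
                tab = extract_covariates(sub, s.buffer_radius_m, landscape, energy=energy,
                                         study_interval=STUDY_INTERVAL)
                tab = assign_available_groups(tab, mode=config.available_grouping,
                                              seed=config.seeds["available"])
                season_tables[s.name] = tab
            covars = pd.concat(season_tables.values(), ignore_index=True)
            covars.to_csv(out / "covariates.csv", index=False)
            record("covariates.csv", out / "covariates.csv")
            rare = filter_rare_classes(season_tables, config.rare_class_threshold)
            manifest["numbers"]["rare_class_filter"] = {
                s: {"retained": r, "dropped": [a["class"] for a in audit]}
                for s, (r, audit) in rare.items()}
            stage("covariates")

        fit_rows, surf_paths, val_rows, energy_rows = [], [], [], []
        top_models = {}
        for s in seasons:
            tab = season_tables[s.name]
            candidates = [c for c in config.candidates if c in tab.columns]
            if not config.s1_path:
                retained_classes = manifest["numbers"]["rare_class_filter"][s.name]["retained"]
                from .layers import PROPORTION_VARS
                candidates = [c for c in candidates
                              if c not in PROPORTION_VARS or c in retained_classes]
            scr = pearson_screen(tab, candidates, threshold=config.screen_threshold,
                                 priority=config.priority)
            model_set = fit_all_subsets(tab, scr.retained, season=s.name)
            model_set.table.to_csv(out / f"models_{s.name}.csv", index=False)
            record(f"models_{s.name}.csv", out / f"models_{s.name}.csv")
            top = model_set.top
            top_models[s.name] = top
            top.summary().to_csv(out / f"top_model_{s.name}.csv")
            record(f"top_model_{s.name}.csv", out / f"top_model_{s.name}.csv")
            fit_rows.append({"season": s.name, "screened": "+".join(scr.retained),
                             "top_formula": top.formula, "top_aicc": top.aicc,
                             "sigma_b": top.sigma_b})

            if landscape is not None:
                surf = model_averaged_surface(model_set, landscape, s.buffer_radius_m,
                                              energy=energy)
                surf.grid.to_ascii(out / f"surface_{s.name}.asc")
                with open(out / f"surface_{s.name}.json", "w") as fh:
                    json.dump({"season": s.name, "radius_m": s.buffer_radius_m,
                               "models": surf.provenance}, fh)
                record(f"surface_{s.name}.asc", out / f"surface_{s.name}.asc")
                surf_paths.append(str(out / f"surface_{s.name}.asc"))

            val = cross_validate(tab, top.covariates, k=config.kfold_k,
                                 holdout_fraction=config.kfold_holdout,
                                 seed=config.seeds["folds"])
            val_rows.append({"season": s.name, "average_rs": val.average_rs,
                             "average_auc": val.average_auc, "full_auc": val.full_auc})

            energy_ok = all(v in tab.columns and tab[v].notna().all() for v in ENERGY_VARS)
            if energy_ok:
                cmp_land = augment_and_compare(top.covariates, tab, scale="landscape",
                                               season=s.name)
                energy_rows.append(cmp_land.report_row())
                if landscape is not None and len(energy.wells):
                    from .covariates import active_wells
                    act = active_wells(energy.wells, STUDY_INTERVAL)
                    local = local_subset(tab, act, energy.fields_polygons,
                                         radius_km=config.energy_radius_km)
                    n_used_local = int((local["response"] == 1).sum())
                    if n_used_local >= 30:
                        cmp_local = augment_and_compare(top.covariates, local,
                                                        scale="local", season=s.name)
                        energy_rows.append(cmp_local.report_row())
                    else:
                        manifest["numbers"].setdefault("energy_notes", []).append(
                            f"{s.name}: only {n_used_local} used rows near wells; "
                            "local scale skipped")
        stage("fit")
        if surf_paths:
            stage("map")
        pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)
        record("fits.csv", out / "fits.csv")
        pd.DataFrame(val_rows).to_csv(out / "validation.csv", index=False)
        record("validation.csv", out / "validation.csv")
        stage("validate")
        if energy_rows:
            pd.DataFrame(energy_rows).to_csv(out / "energy_comparison.csv", index=False)
            record("energy_comparison.csv", out / "energy_comparison.csv")
            stage("energy")
        manifest["numbers"]["fits"] = fit_rows
        manifest["numbers"]["validation"] = val_rows
        manifest["numbers"]["energy"] = energy_rows
    except Exception as exc:
        manifest["error"] = {"stage": "after " + (list(manifest["stages"])[-1]
                                                  if manifest["stages"] else "start"),
                             "message": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
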