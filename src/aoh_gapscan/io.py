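"""Readers and writers for the package's file interfaces.

Rasters are written as single-band TIFF (value 1 = suitable habitat,
0 = unsuitable) via tifffile, with a JSON sidecar carrying the affine frame
and identifiers; vector layers are written as GeoJSON; tables as CSV; and a
scenario manifest (JSON) records the full configuration and seed so a run
can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile

from .frames import Frame
from .geometry_prep import SiteSet
from .overlap_engine import SpeciesMap
from .synthetic_data import RawSite, ScenarioConfig


def write_species_map(smap: SpeciesMap, path: str | Path) -> Path:
    """Single-band TIFF + ``<path>.json`` sidecar with frame metadata."""
    path = Path(path)
    tifffile.imwrite(path, smap.to_raster())
    sidecar = {
        "map_id": smap.map_id,
        "species_id": smap.species_id,
        "season": smap.season,
        "cell_km": smap.cell_km,
        "frame": smap.frame.to_dict(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_species_map(path: str | Path) -> SpeciesMap:
    path = Path(path)
    grid = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return SpeciesMap.from_raster(
        meta["map_id"], meta["species_id"], meta["season"],
        np.asarray(grid), meta["cell_km"], Frame.from_dict(meta["frame"]))


def write_sites_geojson(sites: list[RawSite], path: str | Path) -> Path:
    """Raw site records as a GeoJSON FeatureCollection (null geometry allowed)."""
    features = []
    for s in sites:
        features.append({
            "type": "Feature",
            "geometry": None if s.geometry is None
            else json.loads(shapely.to_geojson(s.geometry)),
            "properties": {
                "site_id": s.site_id, "name": s.name, "country": s.country,
                "region": s.region, "iba_flag": s.iba_flag,
            },
        })
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def read_sites_geojson(path: str | Path) -> list[RawSite]:
    data = json.loads(Path(path).read_text())
    out = []
    for feat in data["features"]:
        props = feat["properties"]
        geom = feat.get("geometry")
        out.append(RawSite(
            site_id=props["site_id"], name=props.get("name"),
            country=props.get("country"), region=props.get("region"),
            iba_flag=bool(props.get("iba_flag")),
            geometry=None if geom is None else shapely.from_geojson(json.dumps(feat)),
        ))
    return out


def write_siteset(siteset: SiteSet, records_path: str | Path,
                  ledger_path: str | Path) -> None:
    """Repaired records as GeoJSON and the dropped ledger as CSV."""
    recs = []
    for rec in siteset.records.itertuples():
        recs.append({
            "type": "Feature",
            "geometry": json.loads(shapely.to_geojson(rec.geometry)),
            "properties": {"site_id": rec.site_id, "name": rec.name,
                           "country": rec.country, "region": rec.region,
                           "iba_flag": rec.iba_flag, "extent_km2": rec.extent_km2},
        })
    Path(records_path).write_text(json.dumps({"type": "FeatureCollection", "features": recs}))
    siteset.ledger.to_csv(ledger_path, index=False)


def write_manifest(config: ScenarioConfig, path: str | Path,
                   extra: dict | None = None) -> Path:
    payload = {"config": dataclasses.asdict(config)}
    if extra:
        payload.update(extra)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1, default=str))
    return path


def read_manifest(path: str | Path) -> ScenarioConfig:
    raw = json.loads(Path(path).read_text())["config"]
    for key in ("redlist_probs", "habitat_probs"):
        raw[key] = tuple(tuple(x) for x in raw[key])
    raw["island_size_cells"] = tuple(raw["island_size_cells"])
    return ScenarioConfig(**raw)


def write_grid_tiff(arr: np.ndarray, path: str | Path, grid_meta: dict | None = None) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(arr))
    if grid_meta:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(grid_meta, indent=1))
    return path


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
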