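"""Text-format persistence for layouts, meteorology, samples and models.

Vector layers are GeoJSON; the NDVI raster is an ESRI ASCII grid (.asc); the
meteorology and sample tables are CSV; truth/fitted models are YAML.  These
are the plain-text equivalents of the shapefile/GeoTIFF stack and round-trip
exactly for the generator's geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .layout import CityLayout, Raster


def write_geojson(df: pd.DataFrame, path: Path, properties: list[str]) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(row["geometry"]),
            "properties": {k: row[k] for k in properties},
        }
        for _, row in df.iterrows()
    ]
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_geojson(path: Path) -> pd.DataFrame:
    data = json.loads(Path(path).read_text())
    rows = []
    for feat in data["features"]:
        row = dict(feat["properties"])
        row["geometry"] = shape(feat["geometry"])
        rows.append(row)
    return pd.DataFrame(rows)


def write_ascii_grid(raster: Raster, path: Path, nodata: float = -9999.0) -> None:
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.x_min}\n"
        f"yllcorner {raster.y_min}\n"
        f"cellsize {raster.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in raster.values)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: Path) -> Raster:
    lines = Path(path).read_text().splitlines()
    meta = {}
    for line in lines[:6]:
        k, v = line.split()
        meta[k.lower()] = float(v)
    values = np.loadtxt(lines[6:])
    values = np.atleast_2d(values)
    return Raster(
        values=values,
        x_min=meta["xllcorner"],
        y_min=meta["yllcorner"],
        cell_size=meta["cellsize"],
    )


def write_layout(layout: CityLayout, out_dir: Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_geojson(layout.roads, out / "roads.geojson", ["road_class"])
    write_geojson(layout.landuse, out / "landuse.geojson", ["landuse_class"])
    write_geojson(layout.pois, out / "pois.geojson", ["kind"])
    write_geojson(layout.eas, out / "eas.geojson", ["ea_id", "population", "biomass_share", "ses"])
    write_ascii_grid(layout.ndvi, out / "ndvi.asc")
    (out / "extent.json").write_text(json.dumps({"extent": list(layout.extent)}))


def read_layout(in_dir: Path) -> CityLayout:
    d = Path(in_dir)
    extent = tuple(json.loads((d / "extent.json").read_text())["extent"])
    return CityLayout(
        extent=extent,
        roads=read_geojson(d / "roads.geojson"),
        landuse=read_geojson(d / "landuse.geojson"),
        ndvi=read_ascii_grid(d / "ndvi.asc"),
        pois=read_geojson(d / "pois.geojson"),
        eas=read_geojson(d / "eas.geojson"),
    )


def write_yaml(obj: dict, path: Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path: Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
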