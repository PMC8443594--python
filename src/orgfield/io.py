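"""Plain-text I/O: GeoJSON feature collections and ESRI ASCII grids.

Spatial tables are pandas DataFrames with a shapely ``geometry`` column;
GeoJSON round-trips properties + geometry, the ASCII grid round-trips the
soil raster.  Coordinates are planar meters throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping, shape

from orgfield.synthetic import StorieSurface

NODATA = -9999.0


def write_geojson(df: pd.DataFrame, path: str | Path) -> None:
    features = []
    for _, row in df.iterrows():
        props = {k: v for k, v in row.items() if k != "geometry"}
        props = {k: (v.item() if isinstance(v, np.generic) else v) for k, v in props.items()}
        features.append({
            "type": "Feature",
            "properties": props,
            "geometry": mapping(row["geometry"]),
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_geojson(path: str | Path) -> pd.DataFrame:
    payload = json.loads(Path(path).read_text())
    rows = []
    for feat in payload["features"]:
        row = dict(feat["properties"])
        row["geometry"] = shape(feat["geometry"])
        rows.append(row)
    return pd.DataFrame(rows)


def write_asc(surface: StorieSurface, path: str | Path) -> None:
    """ESRI ASCII grid; row order is top-down as the format requires."""
    vals = np.where(np.isnan(surface.values), NODATA, surface.values)
    nrows, ncols = vals.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {surface.x0}\nyllcorner {surface.y0}\n"
        f"cellsize {surface.cell}\nNODATA_value {NODATA}\n"
    )
    body = "\n".join(" ".join(f"{v:g}" for v in row) for row in vals[::-1])
    Path(path).write_text(header + body + "\n")


def read_asc(path: str | Path) -> StorieSurface:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
        k, v = lines[i].split()
        hdr[k.lower()] = float(v)
        i += 1
    vals = np.array([[float(v) for v in line.split()] for line in lines[i:] if line.strip()])
    vals = vals[::-1]
    vals[vals == hdr.get("nodata_value", NODATA)] = np.nan
    return StorieSurface(x0=hdr["xllcorner"], y0=hdr["yllcorner"],
                         cell=hdr["cellsize"], values=vals)


def read_fields(path: str | Path) -> pd.DataFrame:
    """Read fields.csv, rebuilding rectangle geometries from corner columns."""
    df = pd.read_csv(path)
    if {"x0", "y0", "x1", "y1"}.issubset(df.columns):
        df["geometry"] = [box(a, b, c, d) for a, b, c, d in
                          zip(df.x0, df.y0, df.x1, df.y1)]
    return df
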